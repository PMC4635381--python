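"""Reference-spectrum (MSP) construction from replicate peak lists.

A strain's main spectrum is built from 10–24 replicate acquisitions.
Replicates whose proportion of reproducible peaks is not higher than 0.6
are rejected; the survivors' peaks are clustered across replicates within
the matching tolerance, and each cluster becomes a reference peak carrying
its mean m/z, mean intensity, and replicate frequency.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import ConfigError, InputError, QCError
from .preprocess import Peak, PeakList

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchTolerance:
    """Peak-matching tolerance: relative ppm with an absolute floor.

    Two peaks are pairable when their m/z difference is at most
    ``max(floor_da, ppm * 1e-6 * mz)``.  The default 600 ppm with a 2 Da
    floor spans roughly 2–12 Da over the 2–20 kDa window, matching
    linear-mode mass accuracy.
    """

    ppm: float = 600.0
    floor_da: float = 2.0

    def __post_init__(self) -> None:
        if self.ppm <= 0 or self.floor_da <= 0:
            raise ConfigError("tolerances must be > 0")

    def window(self, mz: float) -> float:
        return max(self.floor_da, self.ppm * 1e-6 * mz)


@dataclass(frozen=True)
class MspBuildConfig:
    """Parameters for reference-spectrum construction.

    ``min_reproducible_proportion`` is the replicate QC gate (strictly
    greater-than); ``min_peak_frequency`` is the fraction of accepted
    replicates a peak cluster must appear in to enter the reference;
    ``max_ref_peaks`` caps the reference size.
    """

    match_tol_ppm: float = 600.0
    match_tol_floor_da: float = 2.0
    min_reproducible_proportion: float = 0.6
    min_peak_frequency: float = 0.25
    max_ref_peaks: int = 70
    min_replicates: int = 10
    max_replicates: int = 24
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if self.match_tol_ppm <= 0 or self.match_tol_floor_da <= 0:
            raise ConfigError("matching tolerances must be > 0")
        if not 0 <= self.min_peak_frequency <= 1:
            raise ConfigError("min_peak_frequency must lie in [0, 1]")
        if not 0 <= self.min_reproducible_proportion <= 1:
            raise ConfigError("min_reproducible_proportion must lie in [0, 1]")
        if self.max_ref_peaks < 1:
            raise ConfigError("max_ref_peaks must be >= 1")
        if self.aggregate not in ("mean", "median"):
            raise ConfigError(f"unknown aggregate {self.aggregate!r}")

    @property
    def tolerance(self) -> MatchTolerance:
        return MatchTolerance(ppm=self.match_tol_ppm, floor_da=self.match_tol_floor_da)


@dataclass(frozen=True)
class MspPeak:
    """One reference peak: mean m/z, mean intensity, replicate frequency."""

    mz: float
    intensity: float
    frequency: float

    def __post_init__(self) -> None:
        if not 0 < self.frequency <= 1:
            raise InputError("peak frequency must lie in (0, 1]")


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Per-strain consensus peak list (a main spectrum / MSP)."""

    strain_id: str
    peaks: tuple
    n_replicates_used: int
    build_params: dict | None = None

    def __post_init__(self) -> None:
        peaks = tuple(self.peaks)
        object.__setattr__(self, "peaks", peaks)
        mzs = [p.mz for p in peaks]
        if mzs != sorted(mzs):
            raise InputError("MSP peaks must be sorted by m/z")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[MspPeak]:
        return iter(self.peaks)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks])

    def to_peak_list(self) -> PeakList:
        """View the reference as a candidate-style peak list."""
        return PeakList(
            peaks=tuple(
                Peak(mz=p.mz, intensity=p.intensity, snr=float("inf"))
                for p in self.peaks
            ),
            strain_id=self.strain_id,
            replicate_id="msp",
        )


@dataclass(frozen=True)
class MspBuildReport:
    """Quality-control trace of one MSP build."""

    proportions: dict
    accepted: tuple
    rejected: tuple
    n_clusters_prefilter: int


# ---------------------------------------------------------------------------
# matching primitive
# ---------------------------------------------------------------------------

def match_mz(
    a: np.ndarray, b: np.ndarray, tol: MatchTolerance
) -> list[tuple[int, int]]:
    """One-to-one greedy nearest-m/z pairing of two sorted m/z arrays.

    Peaks a[i], b[j] are pairable iff |a[i] - b[j]| <= tol.window(a[i]).
    Candidate pairs are taken greedily by ascending m/z distance, each peak
    used at most once.  Ties broken by (i, j) for determinism.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cands: list[tuple[float, int, int]] = []
    for i, m in enumerate(a):
        w = tol.window(float(m))
        lo = int(np.searchsorted(b, m - w, side="left"))
        hi = int(np.searchsorted(b, m + w, side="right"))
        for j in range(lo, hi):
            cands.append((abs(float(m) - float(b[j])), i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    pairs.sort()
    return pairs


def match_peaks(
    a: PeakList, b: PeakList, tol: MatchTolerance | None = None
) -> list[tuple[int, int]]:
    """Greedy one-to-one pairing of two peak lists (see :func:`match_mz`)."""
    tol = tol or MatchTolerance()
    return match_mz(a.mz, b.mz, tol)


# ---------------------------------------------------------------------------
# cross-replicate clustering
# ---------------------------------------------------------------------------

def _cluster_peaks(
    replicates: Sequence[PeakList], tol: MatchTolerance
) -> list[list[tuple[int, Peak]]]:
    """Single-linkage 1-D clustering of pooled peaks within the tolerance.

    Pooled peaks are sorted by m/z and split wherever the gap between
    consecutive peaks exceeds the tolerance window at the left peak.
    Returns clusters of (replicate_index, Peak).
    """
    pool: list[tuple[float, int, Peak]] = []
    for r, rep in enumerate(replicates):
        for p in rep:
            pool.append((p.mz, r, p))
    pool.sort(key=lambda t: (t[0], t[1]))
    clusters: list[list[tuple[int, Peak]]] = []
    current: list[tuple[int, Peak]] = []
    prev_mz: float | None = None
    for mz, r, p in pool:
        if prev_mz is not None and mz - prev_mz > tol.window(prev_mz):
            clusters.append(current)
            current = []
        current.append((r, p))
        prev_mz = mz
    if current:
        clusters.append(current)
    return clusters


def _consensus_positions(
    cohort: Sequence[PeakList], tol: MatchTolerance, min_presence: float = 0.5
) -> np.ndarray:
    """m/z positions present in at least *min_presence* of the cohort."""
    clusters = _cluster_peaks(cohort, tol)
    out = []
    n = len(cohort)
    for cl in clusters:
        reps = {r for r, _ in cl}
        if len(reps) / n >= min_presence:
            out.append(float(np.mean([p.mz for _, p in cl])))
    return np.array(sorted(out))


def reproducible_proportion(
    replicate: PeakList,
    cohort: Sequence[PeakList],
    cfg: MspBuildConfig | None = None,
) -> float:
    """Fraction of a replicate's peaks found in the cohort consensus.

    The provisional consensus is the set of peak positions present in at
    least half of the other replicates; the proportion is the fraction of
    this replicate's peaks with a match (within tolerance) in that
    consensus.
    """
    cfg = cfg or MspBuildConfig()
    if not cohort:
        raise InputError("cohort must contain at least one replicate")
    if len(replicate) == 0:
        warnings.warn("empty replicate has reproducible proportion 0 by definition")
        return 0.0
    consensus = _consensus_positions(cohort, cfg.tolerance)
    if consensus.size == 0:
        return 0.0
    pairs = match_mz(replicate.mz, consensus, cfg.tolerance)
    return len(pairs) / len(replicate)


def build_msp(
    replicates: Sequence[PeakList],
    strain_id: str,
    cfg: MspBuildConfig | None = None,
) -> tuple[ReferenceSpectrum, MspBuildReport]:
    """Build a reference spectrum from replicate peak lists.

    Replicates failing the reproducibility gate (proportion must be
    strictly higher than ``min_reproducible_proportion``) are rejected.
    Survivors' peaks are clustered across replicates; each cluster yields a
    reference peak with mean m/z, mean intensity over the replicates
    containing it, and frequency = containing / accepted.  Clusters below
    ``min_peak_frequency`` are dropped, and the result is trimmed to
    ``max_ref_peaks`` by (frequency desc, intensity desc).

    The build is permutation-invariant in replicate order.
    """
    cfg = cfg or MspBuildConfig()
    replicates = list(replicates)
    if len(replicates) < 2:
        raise InputError("building an MSP requires at least 2 replicates")
    if len(replicates) < cfg.min_replicates:
        warnings.warn(
            f"{strain_id}: only {len(replicates)} replicates "
            f"(recommended at least {cfg.min_replicates})"
        )
    if len(replicates) > cfg.max_replicates:
        warnings.warn(
            f"{strain_id}: {len(replicates)} replicates exceed the "
            f"recommended maximum of {cfg.max_replicates}; all are used"
        )

    proportions: dict = {}
    accepted: list[PeakList] = []
    accepted_ids: list[str] = []
    rejected_ids: list[str] = []
    for k, rep in enumerate(replicates):
        cohort = replicates[:k] + replicates[k + 1 :]
        prop = reproducible_proportion(rep, cohort, cfg)
        rid = rep.replicate_id
        proportions[rid] = prop
        if prop > cfg.min_reproducible_proportion:
            accepted.append(rep)
            accepted_ids.append(rid)
        else:
            rejected_ids.append(rid)
            logger.info(
                "%s: replicate %s rejected (reproducible proportion %.3f <= %.2f)",
                strain_id, rid, prop, cfg.min_reproducible_proportion,
            )

    if not accepted:
        raise QCError(
            f"{strain_id}: all {len(replicates)} replicates failed the "
            f"reproducibility gate (proportion must exceed "
            f"{cfg.min_reproducible_proportion})"
        )

    clusters = _cluster_peaks(accepted, cfg.tolerance)
    n_acc = len(accepted)
    agg = np.median if cfg.aggregate == "median" else np.mean
    ref_peaks: list[MspPeak] = []
    for cl in clusters:
        reps = {r for r, _ in cl}
        freq = len(reps) / n_acc
        if freq < cfg.min_peak_frequency:
            continue
        mzs = [p.mz for _, p in cl]
        intens = [p.intensity for _, p in cl]
        ref_peaks.append(
            MspPeak(mz=float(agg(mzs)), intensity=float(agg(intens)), frequency=freq)
        )
    ref_peaks.sort(key=lambda p: (-p.frequency, -p.intensity, p.mz))
    ref_peaks = ref_peaks[: cfg.max_ref_peaks]
    ref_peaks.sort(key=lambda p: p.mz)

    msp = ReferenceSpectrum(
        strain_id=strain_id,
        peaks=tuple(ref_peaks),
        n_replicates_used=n_acc,
        build_params=asdict(cfg),
    )
    report = MspBuildReport(
        proportions=proportions,
        accepted=tuple(sorted(accepted_ids)),
        rejected=tuple(sorted(rejected_ids)),
        n_clusters_prefilter=len(clusters),
    )
    return msp, report
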
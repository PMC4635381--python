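"""Ground-truthed synthetic linear-mode MALDI spectra.

Each strain is a fixed fingerprint of 5–100 protein peaks in the 2–20 kDa
window.  A replicate acquisition renders the surviving (non-dropped) peaks
as Gaussians on a uniform m/z grid with per-replicate mass jitter and
log-normal intensity variability, adds Poisson-rate spurious peaks, an
exponentially decaying chemical baseline, and white detector noise.
Panels plant a genus/species/strain hierarchy by sharing configurable
fractions of peaks, so clustering and identification behaviour can be
checked against known taxonomy.

Everything is a pure function of (model, config, seed): the same inputs
give a bit-identical spectrum.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InputError
from .io import AcquisitionConfig, RawSpectrum


@dataclass(frozen=True)
class SimulationConfig:
    """Replicate-level variability of the synthetic instrument.

    Defaults: 300 ppm mass jitter (half the default 600 ppm matching
    tolerance, so default pipelines match reliably), 25% intensity CV, 10%
    peak dropout, 2 spurious peaks per spectrum, an exponential baseline
    decaying over 3 kDa, white noise of sd 20 against planted amplitudes
    log-uniform over 100–10,000 (true S/N 5–500), a 1 Da grid, and Gaussian
    peaks of sigma 2.5 Da.
    """

    mz_jitter_ppm: float = 300.0
    intensity_cv: float = 0.25
    dropout_prob: float = 0.1
    spurious_peak_rate: float = 2.0
    baseline_amplitude: float = 300.0
    baseline_scale: float = 3000.0
    noise_sd: float = 20.0
    grid_step: float = 1.0
    peak_sigma: float = 2.5
    mz_min: float = 2000.0
    mz_max: float = 20000.0
    intensity_min: float = 100.0
    intensity_max: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mz_jitter_ppm", "intensity_cv", "spurious_peak_rate",
                     "baseline_amplitude", "baseline_scale", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigError("dropout_prob must lie in [0, 1]")
        if self.grid_step <= 0 or self.peak_sigma <= 0:
            raise ConfigError("grid_step and peak_sigma must be > 0")
        if not self.mz_min < self.mz_max:
            raise ConfigError("mz_min must be < mz_max")
        if not 0 < self.intensity_min <= self.intensity_max:
            raise ConfigError("require 0 < intensity_min <= intensity_max")


@dataclass(frozen=True)
class StrainModel:
    """A strain's true fingerprint: peak positions, base intensities, taxonomy."""

    strain_id: str
    true_peaks: np.ndarray  # shape (n, 2): columns (mz, base intensity)
    taxonomy: tuple = ("genus", "species")

    def __post_init__(self) -> None:
        pk = np.asarray(self.true_peaks, dtype=float)
        object.__setattr__(self, "true_peaks", pk)
        if pk.ndim != 2 or pk.shape[1] != 2:
            raise InputError("true_peaks must be an (n, 2) array of (mz, intensity)")
        if not 5 <= pk.shape[0] <= 100:
            raise InputError("a strain model needs between 5 and 100 peaks")
        if np.any(np.diff(pk[:, 0]) <= 0):
            raise InputError("true peak positions must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return int(self.true_peaks.shape[0])


@dataclass(frozen=True)
class PanelSpec:
    """A planted taxonomy: genera x species x strains with peak sharing.

    Sharing fractions give the expected fraction of a strain's peaks shared
    with another strain of the same species (0.9), the same genus (0.6),
    or any strain at all (background, 0.1); they must decrease from species
    to background.
    """

    n_genera: int = 2
    species_per_genus: int = 2
    strains_per_species: int = 2
    within_species: float = 0.9
    within_genus: float = 0.6
    background: float = 0.1
    n_peaks: int = 30
    n_replicates: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genera, self.species_per_genus, self.strains_per_species) < 1:
            raise ConfigError("panel dimensions must be >= 1")
        if not 0 <= self.background < self.within_genus < self.within_species <= 1:
            raise ConfigError(
                "sharing fractions must satisfy "
                "0 <= background < within_genus < within_species <= 1"
            )
        if not 5 <= self.n_peaks <= 100:
            raise ConfigError("n_peaks must lie in [5, 100]")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")


@dataclass(frozen=True)
class GroundTruth:
    """What one simulated replicate actually contains.

    ``planted`` holds the rendered true peaks (post-dropout) as rows of
    (jittered mz, realized amplitude); ``spurious`` likewise for the
    artifact peaks.  Together they define every signal a detector should
    find, sufficient to recompute recall and false-discovery rates.
    """

    strain_id: str
    replicate_id: str
    planted: np.ndarray
    spurious: np.ndarray
    config: SimulationConfig


def _rng_for(cfg_seed: int, *labels: str) -> np.random.Generator:
    """Deterministic per-(seed, labels) generator; labels hashed stably."""
    entropy = [cfg_seed & 0x7FFFFFFF]
    entropy += [zlib.crc32(lab.encode()) & 0x7FFFFFFF for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def _spaced_positions(
    rng: np.random.Generator, n: int, lo: float, hi: float, min_spacing: float
) -> np.ndarray:
    """Draw n positions in [lo, hi] with pairwise spacing >= min_spacing."""
    if n * min_spacing > 0.5 * (hi - lo):
        raise InputError(
            f"cannot place {n} peaks with spacing {min_spacing} in "
            f"[{lo}, {hi}] (window too crowded)"
        )
    positions: list[float] = []
    for _ in range(200 * n):
        x = float(rng.uniform(lo, hi))
        if all(abs(x - p) >= min_spacing for p in positions):
            positions.append(x)
            if len(positions) == n:
                return np.array(sorted(positions))
    raise InputError("rejection sampling failed to place all peaks")


def make_strain(
    seed: int,
    n_peaks: int = 30,
    taxonomy: tuple = ("genus", "species"),
    strain_id: str | None = None,
    cfg: SimulationConfig | None = None,
) -> StrainModel:
    """Draw a reproducible random strain fingerprint.

    Peak positions keep a minimum spacing of 4 x peak_sigma (10 Da at
    defaults) inside the margin-trimmed acquisition window; base
    intensities are log-uniform over two decades.
    """
    if not 5 <= n_peaks <= 100:
        raise InputError("n_peaks must lie in [5, 100]")
    cfg = cfg or SimulationConfig()
    rng = _rng_for(seed, "strain", strain_id or "anon")
    margin = 6 * cfg.peak_sigma
    pos = _spaced_positions(
        rng, n_peaks, cfg.mz_min + margin, cfg.mz_max - margin, 4 * cfg.peak_sigma
    )
    log_lo, log_hi = np.log10(cfg.intensity_min), np.log10(cfg.intensity_max)
    inten = 10.0 ** rng.uniform(log_lo, log_hi, size=n_peaks)
    return StrainModel(
        strain_id=strain_id or f"sim-{seed}",
        true_peaks=np.column_stack([pos, inten]),
        taxonomy=taxonomy,
    )


def _render(
    grid: np.ndarray, peaks: np.ndarray, sigma: float
) -> np.ndarray:
    """Sum of Gaussians over the full grid.

    Evaluated without range truncation: a cut-off tail leaves a tiny
    discontinuity that smoothing turns into detectable ripples in the
    noiseless limit.  Far tails underflow to exactly 0 on their own.
    """
    y = np.zeros_like(grid)
    for mz, amp in peaks:
        y += amp * np.exp(-0.5 * ((grid - mz) / sigma) ** 2)
    return y


def simulate_replicate(
    model: StrainModel,
    cfg: SimulationConfig | None = None,
    replicate_id: str = "r1",
) -> tuple[RawSpectrum, GroundTruth]:
    """Render one replicate acquisition of a strain.

    Each true peak survives with probability 1 - dropout_prob, gets
    relative mass jitter (Gaussian, sd = mz_jitter_ppm) and a log-normal
    intensity factor with the configured CV.  Spurious peaks arrive at a
    Poisson rate with low (one-decade) intensities.  An exponential
    baseline, a constant detector offset of 6 x noise_sd, and white
    Gaussian noise complete the profile.  The offset keeps the trace
    non-negative (as detector counts are) without clamping, which would
    skew the background distribution; baseline correction removes a
    constant exactly, so downstream results are unaffected.
    """
    cfg = cfg or SimulationConfig()
    rng = _rng_for(cfg.seed, "replicate", model.strain_id, replicate_id)
    grid = np.arange(cfg.mz_min, cfg.mz_max + cfg.grid_step / 2, cfg.grid_step)

    keep = rng.random(model.n_peaks) >= cfg.dropout_prob
    surviving = model.true_peaks[keep].copy()
    if surviving.size:
        jitter = rng.normal(0.0, cfg.mz_jitter_ppm * 1e-6, size=surviving.shape[0])
        surviving[:, 0] *= 1.0 + jitter
        if cfg.intensity_cv > 0:
            sigma_ln = float(np.sqrt(np.log1p(cfg.intensity_cv**2)))
            factors = np.exp(rng.normal(0.0, sigma_ln, size=surviving.shape[0]))
            surviving[:, 1] *= factors

    n_spur = int(rng.poisson(cfg.spurious_peak_rate))
    if n_spur:
        spur_mz = rng.uniform(cfg.mz_min, cfg.mz_max, size=n_spur)
        spur_amp = 10.0 ** rng.uniform(
            np.log10(cfg.intensity_min), np.log10(cfg.intensity_min) + 1, size=n_spur
        )
        spurious = np.column_stack([spur_mz, spur_amp])
    else:
        spurious = np.empty((0, 2))

    y = _render(grid, surviving, cfg.peak_sigma)
    y += _render(grid, spurious, cfg.peak_sigma)
    if cfg.baseline_amplitude > 0:
        y += cfg.baseline_amplitude * np.exp(-(grid - cfg.mz_min) / cfg.baseline_scale)
    if cfg.noise_sd > 0:
        y += 6.0 * cfg.noise_sd
        y += rng.normal(0.0, cfg.noise_sd, size=grid.size)

    spectrum = RawSpectrum(
        mz=grid, intensity=y,
        strain_id=model.strain_id, replicate_id=replicate_id,
        acquisition=AcquisitionConfig(mz_min=cfg.mz_min, mz_max=cfg.mz_max),
    )
    truth = GroundTruth(
        strain_id=model.strain_id, replicate_id=replicate_id,
        planted=surviving[np.argsort(surviving[:, 0])] if surviving.size
        else np.empty((0, 2)),
        spurious=spurious[np.argsort(spurious[:, 0])] if spurious.size
        else np.empty((0, 2)),
        config=cfg,
    )
    return spectrum, truth


@dataclass(frozen=True)
class PanelGroundTruth:
    """Per-panel taxonomy plus per-replicate ground truths."""

    spec: PanelSpec
    taxonomy: dict  # strain_id -> (genus, species)
    replicate_truths: dict = field(default_factory=dict)


def make_panel(
    spec: PanelSpec, cfg: SimulationConfig | None = None
) -> tuple[list[StrainModel], dict, PanelGroundTruth]:
    """Build a planted-taxonomy panel with replicate spectra per strain.

    Every strain's fingerprint is assembled from four pools drawn from one
    globally well-spaced position set (so distinct pools can never
    cross-match): a background pool shared by all strains, a per-genus
    pool, a per-species pool, and strain-private peaks, sized to hit the
    configured sharing fractions.  Shared peaks keep a shared base
    intensity, as conserved proteins do.

    Returns (models, {strain_id: [RawSpectrum, ...]}, ground truth).
    """
    cfg = cfg or SimulationConfig()
    rng = _rng_for(spec.seed, "panel")

    n_bg = max(int(round(spec.n_peaks * spec.background)), 0)
    n_gen = max(int(round(spec.n_peaks * (spec.within_genus - spec.background))), 1)
    n_spe = max(int(round(spec.n_peaks * (spec.within_species - spec.within_genus))), 1)
    n_own = spec.n_peaks - n_bg - n_gen - n_spe
    if n_own < 1:
        raise ConfigError("sharing fractions leave no strain-private peaks")

    n_strains = spec.n_genera * spec.species_per_genus * spec.strains_per_species
    total = (
        n_bg
        + spec.n_genera * n_gen
        + spec.n_genera * spec.species_per_genus * n_spe
        + n_strains * n_own
    )
    # 25 Da spacing: wider than the 600 ppm tolerance anywhere in the
    # window, so peaks from different pools never collide into one cluster
    margin = 6 * cfg.peak_sigma
    positions = _spaced_positions(
        rng, total, cfg.mz_min + margin, cfg.mz_max - margin, 25.0
    )
    rng.shuffle(positions)
    log_lo, log_hi = np.log10(cfg.intensity_min), np.log10(cfg.intensity_max)
    intensities = 10.0 ** rng.uniform(log_lo, log_hi, size=total)
    pool = np.column_stack([positions, intensities])

    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = pool[cursor : cursor + k]
        cursor += k
        return out

    bg = take(n_bg)
    models: list[StrainModel] = []
    taxonomy: dict = {}
    for g in range(spec.n_genera):
        genus_peaks = take(n_gen)
        genus = f"G{g + 1}"
        for s in range(spec.species_per_genus):
            species_peaks = take(n_spe)
            species = f"{genus}.sp{s + 1}"
            for t in range(spec.strains_per_species):
                own = take(n_own)
                sid = f"{species}.st{t + 1}"
                peaks = np.vstack([bg, genus_peaks, species_peaks, own])
                peaks = peaks[np.argsort(peaks[:, 0])]
                models.append(
                    StrainModel(strain_id=sid, true_peaks=peaks,
                                taxonomy=(genus, species))
                )
                taxonomy[sid] = (genus, species)

    spectra: dict = {}
    truths: dict = {}
    for model in models:
        reps = []
        for r in range(spec.n_replicates):
            rid = f"r{r + 1:02d}"
            spec_r, truth = simulate_replicate(model, cfg, rid)
            reps.append(spec_r)
            truths[(model.strain_id, rid)] = truth
        spectra[model.strain_id] = reps

    return models, spectra, PanelGroundTruth(
        spec=spec, taxonomy=taxonomy, replicate_truths=truths
    )
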
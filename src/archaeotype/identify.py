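"""Three-value log-score identification against a reference library.

A candidate peak list is compared with a reference spectrum through three
values: the fraction of reference peaks with a matching partner in the
candidate (v1), the fraction of candidate peaks with a matching partner in
the reference (v2), and the intensity symmetry of the matched pairs (v3) —
high-intensity signals matching high-intensity signals and low matching
low.  The three values are multiplied, the product normalized to 1000, and
the score is the common (decadic) logarithm of the result: at most
3 (= log 1000).  Scores of 2.30–3.00 are read as highly probable species
identification, 2.00–2.29 as secure genus / probable species.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import InputError
from .msp import MatchTolerance, ReferenceSpectrum, match_mz
from .preprocess import PeakList

logger = logging.getLogger(__name__)

#: Interpretation bands on the log score.
BAND_SPECIES = "highly probable species"
BAND_GENUS = "secure genus / probable species"
BAND_UNRELIABLE = "not reliable"

SPECIES_THRESHOLD = 2.30
GENUS_THRESHOLD = 2.00

#: Products at or below this floor map to score 0 rather than -inf,
#: keeping scores inside [0, 3] as the banding presupposes.
_PRODUCT_FLOOR = 1e-3


@dataclass(frozen=True)
class IdentificationResult:
    """The three match values, their product, log score, and band."""

    strain_id: str
    v1: float
    v2: float
    v3: float
    product: float
    normalized: float
    score: float
    band: str
    n_matched: int

    def as_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "v1": self.v1,
            "v2": self.v2,
            "v3": self.v3,
            "product": self.product,
            "normalized": self.normalized,
            "score": self.score,
            "band": self.band,
            "n_matched": self.n_matched,
        }


@dataclass(frozen=True)
class ReIdentificationSummary:
    """Replicate re-identification scores with mean and sample sd."""

    strain_id: str
    scores: tuple
    mean: float
    sd: float

    def formatted(self) -> str:
        """Render as ``mean ± sd`` to 3 decimals."""
        return f"{self.mean:.3f} ± {self.sd:.3f}"


def band(score: float) -> str:
    """Interpretation band for a log score in [0, 3]."""
    if not 0.0 <= score <= 3.0:
        raise InputError(f"score {score} outside [0, 3]")
    if score >= SPECIES_THRESHOLD:
        return BAND_SPECIES
    if score >= GENUS_THRESHOLD:
        return BAND_GENUS
    return BAND_UNRELIABLE


def _intensity_symmetry(ref_int: np.ndarray, cand_int: np.ndarray) -> float:
    """Rank correlation of matched-pair intensities, mapped to [0, 1].

    Fewer than 3 matched pairs gives 0 (the correlation is unstable).
    Constant intensities on both sides count as perfect symmetry; constant
    on one side only as none.  Negative correlations clamp to 0.
    """
    if ref_int.size < 3:
        logger.info("fewer than 3 matched pairs; intensity symmetry set to 0")
        return 0.0
    ra = rankdata(ref_int)
    rb = rankdata(cand_int)
    const_a = np.all(ra == ra[0])
    const_b = np.all(rb == rb[0])
    if const_a and const_b:
        return 1.0
    if const_a or const_b:
        return 0.0
    if np.array_equal(ra, rb):
        return 1.0
    rho = float(np.corrcoef(ra, rb)[0, 1])
    return min(max(rho, 0.0), 1.0)


def score(
    candidate: PeakList,
    reference: ReferenceSpectrum,
    tol: MatchTolerance | None = None,
) -> IdentificationResult:
    """Score a candidate peak list against one reference spectrum.

    v1 = matched reference peaks / reference peaks; v2 = matched candidate
    peaks / candidate peaks; v3 = intensity symmetry of the matched pairs.
    score = log10(1000 * v1 * v2 * v3), floored at 0 when the product is at
    most 1e-3.  The score is invariant to rescaling candidate intensities.
    """
    tol = tol or MatchTolerance()
    if len(candidate) == 0:
        raise InputError("cannot score an empty candidate peak list")
    if len(reference) == 0:
        raise InputError("cannot score against an empty reference spectrum")
    pairs = match_mz(reference.mz, candidate.mz, tol)
    n = len(pairs)
    v1 = n / len(reference)
    v2 = n / len(candidate)
    if n:
        ri = np.array([reference.peaks[i].intensity for i, _ in pairs])
        ci = np.array([candidate.peaks[j].intensity for _, j in pairs])
        v3 = _intensity_symmetry(ri, ci)
    else:
        v3 = 0.0
    product = v1 * v2 * v3
    normalized = product * 1000.0
    s = math.log10(normalized) if product > _PRODUCT_FLOOR else 0.0
    return IdentificationResult(
        strain_id=reference.strain_id,
        v1=v1, v2=v2, v3=v3,
        product=product, normalized=normalized,
        score=s, band=band(s), n_matched=n,
    )


def identify(
    candidate: PeakList,
    library: Sequence[ReferenceSpectrum],
    tol: MatchTolerance | None = None,
) -> list[IdentificationResult]:
    """Score a candidate against every library entry, best first.

    Results are sorted by score descending, ties broken by strain_id; the
    top hit is the identification call.
    """
    if not library:
        raise InputError("identification requires a non-empty library")
    results = [score(candidate, ref, tol) for ref in library]
    results.sort(key=lambda r: (-r.score, r.strain_id))
    return results


def reidentify(
    replicates: Sequence[PeakList],
    reference: ReferenceSpectrum,
    tol: MatchTolerance | None = None,
) -> ReIdentificationSummary:
    """Score replicate peak lists (normally 3) against one reference.

    Reports per-replicate scores, their mean, and the sample standard
    deviation, rendered as ``mean ± sd``.
    """
    if len(replicates) < 2:
        raise InputError("re-identification needs at least 2 replicates for an sd")
    scores = tuple(score(rep, reference, tol).score for rep in replicates)
    return ReIdentificationSummary(
        strain_id=reference.strain_id,
        scores=scores,
        mean=statistics.fmean(scores),
        sd=statistics.stdev(scores),
    )
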
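"""Protein-mass biomarker assignment.

Observed linear-mode MALDI masses (singly charged, so m/z ~ molecular mass)
are matched to proteins by average molecular mass: the isotope-averaged
residue-mass sum plus one water, the convention of the standard pI/Mw
calculators.  A database search returns every protein within a relative
mass window (1% by default, the usual setting for intact-mass taxonomic
assignment), and a truncation scan locates the terminal fragment of a known
protein whose mass explains an observed signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

from .errors import ConfigError, InputError
from .io import CANONICAL_AA, ProteinRecord

# Isotope-averaged residue masses (Da) of the 20 canonical amino acids, as
# used by the standard ExPASy-style pI/Mw computation.
AVERAGE_RESIDUE_MASSES: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
AVERAGE_WATER_MASS = 18.01524

# Monoisotopic variant, for completeness (linear-mode work uses averages).
MONOISOTOPIC_RESIDUE_MASSES: dict[str, float] = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "E": 129.04259, "Q": 128.05858, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "W": 186.07931, "Y": 163.06333, "V": 99.06841,
}
MONOISOTOPIC_WATER_MASS = 18.010565


@dataclass(frozen=True)
class MassTable:
    """Residue masses plus the water constant added once per chain."""

    residues: dict = field(default_factory=lambda: dict(AVERAGE_RESIDUE_MASSES))
    water: float = AVERAGE_WATER_MASS

    def __post_init__(self) -> None:
        missing = CANONICAL_AA - set(self.residues)
        if missing:
            raise ConfigError(f"mass table missing residues: {sorted(missing)}")
        if any(m <= 0 for m in self.residues.values()) or self.water <= 0:
            raise ConfigError("all masses must be > 0")

    @classmethod
    def monoisotopic(cls) -> "MassTable":
        return cls(residues=dict(MONOISOTOPIC_RESIDUE_MASSES),
                   water=MONOISOTOPIC_WATER_MASS)


@dataclass(frozen=True)
class BiomarkerMatch:
    """A protein (or terminal fragment) assigned to an observed mass.

    ``fragment`` gives 1-based inclusive residue bounds when the match is a
    truncation of the full sequence; its mass equals ``predicted_mass``.
    """

    protein: ProteinRecord
    predicted_mass: float
    observed_mass: float
    error_percent: float
    fragment: tuple | None = None

    def __post_init__(self) -> None:
        if self.error_percent < 0:
            raise InputError("error_percent must be >= 0")


def average_mass(sequence: str, table: MassTable | None = None) -> float:
    """Average molecular mass of a protein: residue-mass sum plus one water.

    The empty sequence returns the water mass.  Raises on non-canonical
    letters, naming the position.
    """
    table = table or MassTable()
    total = table.water
    for pos, letter in enumerate(sequence, start=1):
        try:
            total += table.residues[letter]
        except KeyError:
            raise InputError(
                f"non-canonical residue {letter!r} at position {pos}"
            ) from None
    return total


def mass_error_percent(
    predicted: float, observed: float, denominator: str = "predicted"
) -> float:
    """Relative mass error in percent: 100 * |observed - predicted| / predicted.

    Full precision is returned; use :func:`round_half_up` for the
    2-decimal display convention.  ``denominator="observed"`` switches the
    reference mass.
    """
    if predicted <= 0:
        raise InputError("predicted mass must be > 0")
    if denominator == "predicted":
        denom = predicted
    elif denominator == "observed":
        if observed <= 0:
            raise InputError("observed mass must be > 0")
        denom = observed
    else:
        raise ConfigError(f"unknown denominator {denominator!r}")
    return 100.0 * abs(observed - predicted) / denom


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half up (the display convention for printed error columns)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def tagident_search(
    observed: float,
    db: Sequence[ProteinRecord],
    window_percent: float = 1.0,
    table: MassTable | None = None,
) -> list[BiomarkerMatch]:
    """Find every database protein within a relative mass window.

    Returns the records whose average mass lies within ``window_percent``
    of the observed mass, sorted by ascending mass error (accession breaks
    ties), so the closest predicted mass ranks first.
    """
    if not db:
        raise InputError("protein database is empty")
    if window_percent <= 0:
        raise ConfigError("window_percent must be > 0")
    table = table or MassTable()
    hits = []
    for rec in db:
        pred = average_mass(rec.sequence, table)
        err = mass_error_percent(pred, observed)
        if err <= window_percent:
            hits.append(
                BiomarkerMatch(
                    protein=rec, predicted_mass=pred,
                    observed_mass=observed, error_percent=err,
                )
            )
    hits.sort(key=lambda h: (h.error_percent, h.protein.id))
    return hits


def truncation_scan(
    full: ProteinRecord,
    observed: float,
    tol_percent: float = 0.1,
    mode: str = "both",
    table: MassTable | None = None,
) -> list[BiomarkerMatch]:
    """Find terminal fragments of a protein matching an observed mass.

    Enumerates prefixes (``mode="nterm"``: fragments retaining the
    N-terminus), suffixes (``mode="cterm"``), or both, and returns those
    whose average mass is within ``tol_percent`` of the observed mass,
    sorted by ascending error.  Fragment bounds are 1-based inclusive.

    ``mode="internal"`` additionally scans every contiguous substring —
    an O(L^2) enumeration, noticeably slower on long sequences.
    """
    if len(full.sequence) < 2:
        raise InputError("truncation scan needs a sequence of length >= 2")
    if mode not in ("nterm", "cterm", "both", "internal"):
        raise ConfigError(f"unknown truncation mode {mode!r}")
    table = table or MassTable()
    seq = full.sequence
    n = len(seq)
    # cumulative residue-mass sums: cum[i] = mass of residues seq[:i]
    cum = [0.0] * (n + 1)
    for i, letter in enumerate(seq):
        try:
            cum[i + 1] = cum[i] + table.residues[letter]
        except KeyError:
            raise InputError(
                f"non-canonical residue {letter!r} at position {i + 1}"
            ) from None

    def frag_mass(start: int, end: int) -> float:  # 1-based inclusive
        return cum[end] - cum[start - 1] + table.water

    bounds: list[tuple[int, int]] = []
    if mode in ("nterm", "both"):
        bounds.extend((1, e) for e in range(1, n + 1))
    if mode in ("cterm", "both"):
        bounds.extend((s, n) for s in range(1, n + 1))
    if mode == "internal":
        bounds.extend(
            (s, e) for s in range(1, n + 1) for e in range(s, n + 1)
        )

    hits = []
    seen: set[tuple[int, int]] = set()
    for start, end in bounds:
        if (start, end) in seen:
            continue
        seen.add((start, end))
        pred = frag_mass(start, end)
        err = mass_error_percent(pred, observed)
        if err <= tol_percent:
            hits.append(
                BiomarkerMatch(
                    protein=full, predicted_mass=pred,
                    observed_mass=observed, error_percent=err,
                    fragment=(start, end),
                )
            )
    hits.sort(key=lambda h: (h.error_percent, h.fragment))
    return hits
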
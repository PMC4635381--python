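"""Readers and writers for every on-disk artifact.

Profile spectra travel as two-column (m/z, intensity) text — whitespace- or
comma-delimited, ``#`` comment lines ignored.  Peak lists are CSV with
columns ``mz,intensity,snr``.  Reference-spectrum (MSP) libraries are
versioned JSON.  Protein databases are standard FASTA, parsed with
Biopython.

Readers never reorder, drop, or invent data beyond two documented rules:
rows sharing an m/z value are merged by summing their intensities (the
downstream pipeline treats a spectrum as a function of m/z), and negative
raw intensities — small detector-baseline artifacts — are clamped to zero
with the count reported through logging.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .errors import InputError, SpectrumParseError

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid letters accepted in protein sequences.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

MSP_FORMAT_NAME = "archaeotype-msp"
MSP_FORMAT_VERSION = 1


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition window and mode of a linear-mode MALDI-TOF run.

    Defaults cover intact peptides/proteins from m/z 2,000 to 20,000 in
    linear positive mode, the standard window for whole-cell microbial
    fingerprinting.
    """

    mz_min: float = 2000.0
    mz_max: float = 20000.0
    mode: str = "linear positive"

    def __post_init__(self) -> None:
        if not self.mz_min < self.mz_max:
            raise InputError(
                f"acquisition window requires mz_min < mz_max, got "
                f"[{self.mz_min}, {self.mz_max}]"
            )


@dataclass(frozen=True)
class RawSpectrum:
    """A profile-mode trace: paired m/z and intensity arrays.

    ``mz`` is strictly increasing and at least two points long.  Ions are
    assumed singly charged, so m/z approximates molecular mass in daltons.
    Intensities are arbitrary detector units; readers clamp raw negatives
    to zero, while intermediate processing stages may carry small negative
    values (e.g. straight out of a smoothing filter).
    """

    mz: np.ndarray
    intensity: np.ndarray
    strain_id: str = "unknown"
    replicate_id: str = "r1"
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)
        if mz.ndim != 1 or inten.ndim != 1 or mz.shape != inten.shape:
            raise InputError("mz and intensity must be 1-D arrays of equal length")
        if mz.size < 2:
            raise InputError("a spectrum needs at least 2 points")
        if not np.all(np.diff(mz) > 0):
            raise InputError("mz must be strictly increasing")

    def __len__(self) -> int:
        return int(self.mz.size)

    def with_intensity(self, intensity: np.ndarray) -> "RawSpectrum":
        """Return a copy carrying a new intensity array on the same grid."""
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass(frozen=True)
class ProteinRecord:
    """One FASTA entry: accession, free-text description, canonical sequence."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise InputError(
                f"record {self.id!r}: non-canonical residue letter(s) "
                f"{sorted(bad)!r}; only the 20 standard amino acids are accepted"
            )

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# profile spectra
# ---------------------------------------------------------------------------

def _coerce_spectrum_arrays(
    mz: np.ndarray, intensity: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sort by m/z, merge duplicate m/z rows by intensity sum, clamp negatives."""
    order = np.argsort(mz, kind="stable")
    mz, intensity = mz[order], intensity[order]
    uniq, inverse = np.unique(mz, return_inverse=True)
    if uniq.size != mz.size:
        summed = np.zeros(uniq.size)
        np.add.at(summed, inverse, intensity)
        mz, intensity = uniq, summed
    n_neg = int(np.count_nonzero(intensity < 0))
    if n_neg:
        logger.info("clamped %d negative raw intensities to 0", n_neg)
        intensity = np.clip(intensity, 0.0, None)
    return mz, intensity


def _sidecar_metadata(path: Path) -> dict:
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def read_spectrum(
    path: str | Path,
    fmt: str = "auto",
    strain_id: str | None = None,
    replicate_id: str | None = None,
    acquisition: AcquisitionConfig | None = None,
) -> RawSpectrum:
    """Read a two-column (m/z, intensity) profile spectrum.

    ``fmt`` is ``"xy_text"`` (whitespace-delimited), ``"csv"``, or
    ``"auto"`` to accept either.  A single header line is tolerated in CSV
    files.  Strain and replicate identity come from the explicit arguments
    or from a ``<name>.meta.json`` sidecar — never from filename guessing,
    so provenance stays explicit.
    """
    path = Path(path)
    if fmt not in ("auto", "xy_text", "csv"):
        raise InputError(f"unknown spectrum format {fmt!r}")
    if not path.exists():
        raise InputError(f"no such file: {path}")
    mzs: list[float] = []
    intens: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.split(",") if ("," in text and fmt != "xy_text") else text.split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError:
                # one leading header line is tolerated before any data row
                if not mzs and not header_seen and fmt in ("csv", "auto"):
                    header_seen = True
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric value in {text!r}"
                ) from None
    if not mzs:
        raise SpectrumParseError(f"{path}: no data rows")
    mz, intensity = _coerce_spectrum_arrays(np.array(mzs), np.array(intens))
    if mz.size < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 distinct m/z values")
    meta = _sidecar_metadata(path)
    return RawSpectrum(
        mz=mz,
        intensity=intensity,
        strain_id=strain_id or meta.get("strain_id", "unknown"),
        replicate_id=replicate_id or meta.get("replicate_id", "r1"),
        acquisition=acquisition or AcquisitionConfig(),
    )


def write_spectrum(spectrum: RawSpectrum, path: str | Path, fmt: str = "xy_text") -> None:
    """Write a profile spectrum as two-column text plus a metadata sidecar."""
    path = Path(path)
    sep = "," if fmt == "csv" else " "
    with open(path, "w") as fh:
        if fmt == "csv":
            fh.write("mz,intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.10g}{sep}{i:.10g}\n")
    sidecar = path.with_name(path.name + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {"strain_id": spectrum.strain_id, "replicate_id": spectrum.replicate_id},
            indent=1,
        )
    )


# ---------------------------------------------------------------------------
# MSP libraries (JSON)
# ---------------------------------------------------------------------------

def write_msp_library(path: str | Path, msps: Sequence) -> None:
    """Serialize reference spectra to a self-describing, versioned JSON file."""
    entries = []
    for msp in msps:
        entries.append(
            {
                "strain_id": msp.strain_id,
                "n_replicates_used": msp.n_replicates_used,
                "build_params": msp.build_params,
                "peaks": [[p.mz, p.intensity, p.frequency] for p in msp.peaks],
            }
        )
    doc = {
        "format": MSP_FORMAT_NAME,
        "version": MSP_FORMAT_VERSION,
        "entries": entries,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_msp_library(path: str | Path) -> list:
    """Read an MSP library written by :func:`write_msp_library`."""
    from .msp import MspPeak, ReferenceSpectrum

    doc = json.loads(Path(path).read_text())
    if doc.get("format") != MSP_FORMAT_NAME:
        raise InputError(f"{path}: not an {MSP_FORMAT_NAME} library")
    if doc.get("version") != MSP_FORMAT_VERSION:
        raise InputError(
            f"{path}: unsupported library version {doc.get('version')!r} "
            f"(this build reads version {MSP_FORMAT_VERSION})"
        )
    msps = []
    for entry in doc["entries"]:
        peaks = [MspPeak(mz=p[0], intensity=p[1], frequency=p[2]) for p in entry["peaks"]]
        msps.append(
            ReferenceSpectrum(
                strain_id=entry["strain_id"],
                peaks=peaks,
                n_replicates_used=entry["n_replicates_used"],
                build_params=entry.get("build_params"),
            )
        )
    return msps


# ---------------------------------------------------------------------------
# peak-list CSV
# ---------------------------------------------------------------------------

def write_peak_list(peaks, path: str | Path) -> None:
    """Write a peak list as CSV with columns mz, intensity, snr."""
    with open(path, "w") as fh:
        fh.write("mz,intensity,snr\n")
        for p in peaks.peaks:
            fh.write(f"{p.mz:.10g},{p.intensity:.10g},{p.snr:.10g}\n")


def read_peak_list(
    path: str | Path, strain_id: str = "unknown", replicate_id: str = "r1"
):
    """Read a CSV peak list (``mz,intensity,snr``; snr column optional)."""
    from .preprocess import Peak, PeakList

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = [p.strip() for p in text.split(",")]
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric value in {text!r}"
                ) from None
            if len(vals) == 2:
                vals.append(float("inf"))
            if len(vals) != 3:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(vals)}"
                )
            peaks.append(Peak(mz=vals[0], intensity=vals[1], snr=vals[2]))
    peaks.sort(key=lambda p: p.mz)
    return PeakList(peaks=peaks, strain_id=strain_id, replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into validated :class:`ProteinRecord` objects.

    Wrapped lines and internal whitespace are allowed and removed;
    sequences are uppercased.  Ambiguity codes (B/J/O/U/X/Z) are rejected
    with an error naming the record and the offending character.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split()).upper()
        if not seq:
            raise InputError(f"record {rec.id!r}: empty sequence")
        for pos, letter in enumerate(seq, start=1):
            if letter not in CANONICAL_AA:
                raise InputError(
                    f"record {rec.id!r}: non-canonical letter {letter!r} "
                    f"at position {pos}"
                )
        records.append(
            ProteinRecord(id=rec.id, description=rec.description, sequence=seq)
        )
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    return records
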
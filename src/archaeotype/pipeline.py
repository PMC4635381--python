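"""End-to-end workflow steps behind the command-line interface.

Each function here is one pipeline subcommand as a plain Python call:
convert/validate spectra, preprocess a directory of profiles into peak
lists, build an MSP library, identify and re-identify candidates, draw the
dendrogram and gel view, search biomarkers, and simulate synthetic panels.
Every result document embeds a provenance block (package version, config
hash, input hashes); reruns with identical inputs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from .biomarker import round_half_up, tagident_search
from .cluster import build_dendrogram, gel_view_matrix, write_newick
from .identify import identify as _score_library
from .identify import reidentify as _score_replicates
from .config import RunConfig, provenance_block
from .errors import InputError
from .io import (
    read_fasta,
    read_peak_list,
    read_spectrum,
    read_msp_library,
    write_msp_library,
    write_peak_list,
    write_spectrum,
)
from .msp import build_msp
from .preprocess import preprocess
from .simulate import PanelSpec, SimulationConfig, make_panel

logger = logging.getLogger(__name__)


def _write_json(path: str | Path, doc: dict) -> None:
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")


def convert_spectrum(
    in_path: str | Path,
    out_path: str | Path,
    fmt: str = "xy_text",
    strain_id: str | None = None,
    replicate_id: str | None = None,
) -> None:
    """Read a profile spectrum in any accepted dialect and rewrite it."""
    spec = read_spectrum(in_path, strain_id=strain_id, replicate_id=replicate_id)
    write_spectrum(spec, out_path, fmt=fmt)


def validate_spectrum(in_path: str | Path) -> dict:
    """Check a profile file against the RawSpectrum contract; return a summary."""
    spec = read_spectrum(in_path)
    return {
        "path": str(in_path),
        "n_points": len(spec),
        "mz_min": float(spec.mz[0]),
        "mz_max": float(spec.mz[-1]),
        "strain_id": spec.strain_id,
        "replicate_id": spec.replicate_id,
        "valid": True,
    }


def preprocess_file(
    in_path: str | Path, out_path: str | Path, config: RunConfig
) -> dict:
    """Profile spectrum -> peak-list CSV, plus a small JSON summary."""
    spec = read_spectrum(in_path)
    peaks = preprocess(spec, config.preprocess)
    write_peak_list(peaks, out_path)
    return {
        "n_peaks": len(peaks),
        "provenance": provenance_block(config, {"spectrum": in_path}),
    }


def _replicate_files(replicates_dir: str | Path) -> list[Path]:
    d = Path(replicates_dir)
    files = sorted(
        p for p in d.glob("*")
        if p.suffix in (".txt", ".xy", ".csv") and not p.name.endswith(".meta.json")
    )
    if not files:
        raise InputError(f"no spectrum files (*.txt, *.xy, *.csv) in {d}")
    return files


def build_msp_from_dir(
    replicates_dir: str | Path,
    strain_id: str,
    out_path: str | Path,
    config: RunConfig,
    report_path: str | Path | None = None,
) -> dict:
    """Preprocess every replicate spectrum in a directory and build one MSP."""
    peak_lists = []
    for k, f in enumerate(_replicate_files(replicates_dir)):
        spec = read_spectrum(f, strain_id=strain_id, replicate_id=f"r{k + 1:02d}")
        peak_lists.append(preprocess(spec, config.preprocess))
    msp, report = build_msp(peak_lists, strain_id, config.msp)
    write_msp_library(out_path, [msp])
    doc = {
        "strain_id": strain_id,
        "n_replicates_in": len(peak_lists),
        "n_replicates_used": msp.n_replicates_used,
        "accepted": list(report.accepted),
        "rejected": list(report.rejected),
        "proportions": report.proportions,
        "n_reference_peaks": len(msp),
        "provenance": provenance_block(config),
    }
    if report_path:
        _write_json(report_path, doc)
    return doc


def identify_file(
    candidate_path: str | Path,
    library_path: str | Path,
    config: RunConfig,
    out_path: str | Path | None = None,
) -> dict:
    """Score a peak-list CSV against an MSP library; results best first."""
    candidate = read_peak_list(candidate_path)
    library = read_msp_library(library_path)
    results = _score_library(candidate, library, config.tolerance)
    doc = {
        "results": [r.as_dict() for r in results],
        "top_hit": results[0].strain_id,
        "provenance": provenance_block(
            config, {"candidate": candidate_path, "library": library_path}
        ),
    }
    if out_path:
        _write_json(out_path, doc)
    return doc


def reidentify_files(
    replicate_paths: list,
    library_path: str | Path,
    strain_id: str,
    config: RunConfig,
    out_path: str | Path | None = None,
) -> dict:
    """Score replicate peak lists against one library entry; mean ± sd."""
    library = {m.strain_id: m for m in read_msp_library(library_path)}
    if strain_id not in library:
        raise InputError(f"strain {strain_id!r} not in library")
    reps = [read_peak_list(p) for p in replicate_paths]
    summary = _score_replicates(reps, library[strain_id], config.tolerance)
    doc = {
        "strain_id": summary.strain_id,
        "scores": list(summary.scores),
        "mean": summary.mean,
        "sd": summary.sd,
        "formatted": summary.formatted(),
        "provenance": provenance_block(config, {"library": library_path}),
    }
    if out_path:
        _write_json(out_path, doc)
    return doc


def dendrogram_from_library(
    library_path: str | Path,
    out_newick: str | Path,
    config: RunConfig,
    gel_view_path: str | Path | None = None,
) -> dict:
    """Build the MSP dendrogram (and optionally the gel-view CSV)."""
    library = read_msp_library(library_path)
    tree = build_dendrogram(
        library, config.tolerance, method=config.clustering.linkage
    )
    write_newick(tree, out_newick)
    if gel_view_path:
        gel = gel_view_matrix(
            library, bin_width=config.clustering.gel_bin_width, tree=tree
        )
        gel.to_csv(gel_view_path)
    return {"leaf_order": tree.leaf_order()}


def biomarker_report(
    observed: float,
    db_path: str | Path,
    config: RunConfig,
    out_path: str | Path | None = None,
) -> dict:
    """Database mass search within the configured window; CSV-ready rows."""
    db = read_fasta(db_path)
    hits = tagident_search(
        observed, db, window_percent=config.biomarker_window_percent
    )
    rows = [
        {
            "accession": h.protein.id,
            "description": h.protein.description,
            "predicted_mass": round(h.predicted_mass, 2),
            "observed_mass": h.observed_mass,
            "error_percent": round_half_up(h.error_percent),
        }
        for h in hits
    ]
    doc = {
        "observed_mass": observed,
        "window_percent": config.biomarker_window_percent,
        "n_hits": len(rows),
        "hits": rows,
        "provenance": provenance_block(config, {"database": db_path}),
    }
    if out_path:
        _write_json(out_path, doc)
    return doc


def simulate_panel_to_dir(
    panel: PanelSpec,
    sim: SimulationConfig,
    out_dir: str | Path,
) -> dict:
    """Write a synthetic panel as XY-text spectra plus ground-truth JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    models, spectra, truth = make_panel(panel, sim)
    manifest: dict = {"strains": {}, "panel_seed": panel.seed}
    for model in models:
        sdir = out_dir / model.strain_id
        sdir.mkdir(exist_ok=True)
        files = []
        for spec in spectra[model.strain_id]:
            f = sdir / f"{spec.replicate_id}.txt"
            write_spectrum(spec, f)
            files.append(str(f))
        manifest["strains"][model.strain_id] = {
            "taxonomy": list(model.taxonomy),
            "true_peaks": model.true_peaks.tolist(),
            "files": files,
        }
    _write_json(out_dir / "ground_truth.json", manifest)
    return manifest
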
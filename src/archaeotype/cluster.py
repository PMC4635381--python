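"""MSP dendrograms and gel-view matrices.

The pairwise dissimilarity between two reference spectra is derived from
the same three match values as the identification score: each spectrum is
scored with the other as candidate, the two products are combined by
geometric mean into a similarity s in [0, 1], and the distance level is
(1 - s) * 1000.  Agglomerative average-linkage clustering over this matrix
produces the MSP dendrogram; the gel view renders the library as a
strains-by-m/z-bin intensity matrix ordered by the dendrogram leaves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import ConfigError, InputError
from .identify import score
from .msp import MatchTolerance, ReferenceSpectrum

MAX_DISTANCE = 1000.0


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of distance levels in [0, 1000] with strain labels."""

    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(self.labels)
        if d.shape != (n, n):
            raise InputError("distance matrix shape must match label count")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
            raise InputError("distance matrix must be symmetric with zero diagonal")
        if d.min() < -1e-9 or d.max() > MAX_DISTANCE + 1e-9:
            raise InputError("distance levels must lie in [0, 1000]")


@dataclass(frozen=True)
class Dendrogram:
    """Rooted binary merge tree: leaf labels plus a SciPy linkage matrix."""

    labels: tuple
    linkage_matrix: np.ndarray
    method: str = "average"

    def leaf_order(self) -> list[str]:
        """Leaf labels in dendrogram display order."""
        return [self.labels[i] for i in leaves_list(self.linkage_matrix)]

    def root_bipartition(self) -> tuple[frozenset, frozenset]:
        """The two leaf-label sets separated by the root merge."""
        tree = to_tree(self.linkage_matrix)
        left = frozenset(self.labels[i] for i in tree.get_left().pre_order())
        right = frozenset(self.labels[i] for i in tree.get_right().pre_order())
        return left, right

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()


def msp_distance(
    a: ReferenceSpectrum,
    b: ReferenceSpectrum,
    tol: MatchTolerance | None = None,
) -> float:
    """Distance level between two reference spectra on the 0–1000 scale.

    s = geometric mean of the two directed three-value products (a scored
    as reference with b as candidate, and vice versa); distance =
    (1 - s) * 1000.  Symmetric by construction; zero for identical MSPs,
    1000 when no peaks match.
    """
    tol = tol or MatchTolerance()
    p_ab = score(b.to_peak_list(), a, tol).product
    p_ba = score(a.to_peak_list(), b, tol).product
    s = math.sqrt(p_ab * p_ba)
    return (1.0 - s) * MAX_DISTANCE


def distance_matrix(
    library: Sequence[ReferenceSpectrum], tol: MatchTolerance | None = None
) -> DistanceMatrix:
    """All-pairs distance levels for a library, labels sorted by strain_id."""
    refs = sorted(library, key=lambda m: m.strain_id)
    n = len(refs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = msp_distance(refs[i], refs[j], tol)
    return DistanceMatrix(labels=tuple(m.strain_id for m in refs), d=d)


def build_dendrogram(
    library: Sequence[ReferenceSpectrum],
    tol: MatchTolerance | None = None,
    method: str = "average",
) -> Dendrogram:
    """Agglomerative clustering of a library into an MSP dendrogram.

    Average linkage by default (single and complete available).  Input
    order does not matter: entries are sorted by strain_id before
    clustering, which also fixes tie-breaking.
    """
    if len(library) < 2:
        raise InputError("a dendrogram needs at least 2 reference spectra")
    if method not in ("average", "single", "complete"):
        raise ConfigError(f"unsupported linkage method {method!r}")
    dm = distance_matrix(library, tol)
    z = linkage(squareform(dm.d, checks=False), method=method)
    return Dendrogram(labels=dm.labels, linkage_matrix=z, method=method)


# ---------------------------------------------------------------------------
# Newick export
# ---------------------------------------------------------------------------

def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]:;,'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _newick_node(node, labels: Sequence[str], parent_height: float) -> str:
    # ultrametric convention: depth from a merge at height h to its leaves
    # is h/2, so the branch to a child at height hc has length (h - hc)/2
    length = (parent_height - node.dist) / 2.0
    if node.is_leaf():
        return f"{_quote_label(labels[node.id])}:{length:g}"
    left = _newick_node(node.get_left(), labels, node.dist)
    right = _newick_node(node.get_right(), labels, node.dist)
    return f"({left},{right}):{length:g}"


def to_newick(tree: Dendrogram) -> str:
    """Render a dendrogram as a Newick string with ultrametric branch lengths."""
    root = to_tree(tree.linkage_matrix)
    left = _newick_node(root.get_left(), tree.labels, root.dist)
    right = _newick_node(root.get_right(), tree.labels, root.dist)
    return f"({left},{right});"


def write_newick(tree: Dendrogram, path: str | Path) -> None:
    """Write a dendrogram to a Newick file."""
    Path(path).write_text(to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# gel view
# ---------------------------------------------------------------------------

def gel_view_matrix(
    library: Sequence[ReferenceSpectrum],
    bin_width: float = 10.0,
    mz_min: float = 2000.0,
    mz_max: float = 20000.0,
    tree: Dendrogram | None = None,
) -> pd.DataFrame:
    """Strains-by-m/z-bin intensity matrix (a pseudo-gel view).

    Rows follow the dendrogram leaf order (the supplied tree, or one built
    on the fly when the library has at least 2 entries); columns are bin
    left edges; cells carry the summed binned peak intensity, 0 where no
    peak falls.
    """
    if not library:
        raise InputError("gel view requires a non-empty library")
    if bin_width <= 0:
        raise ConfigError("bin_width must be > 0")
    if tree is None and len(library) >= 2:
        tree = build_dendrogram(library)
    order = tree.leaf_order() if tree else [m.strain_id for m in library]
    by_id = {m.strain_id: m for m in library}
    edges = np.arange(mz_min, mz_max + bin_width, bin_width)
    n_bins = edges.size - 1
    rows = np.zeros((len(order), n_bins))
    for r, sid in enumerate(order):
        msp = by_id[sid]
        for p in msp.peaks:
            k = int(np.searchsorted(edges, p.mz, side="right")) - 1
            if 0 <= k < n_bins:
                rows[r, k] += p.intensity
    return pd.DataFrame(rows, index=order, columns=edges[:-1])
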
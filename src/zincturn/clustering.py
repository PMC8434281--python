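"""RMSD clustering of motifs: Kabsch superposition, pairwise matrix, and the
greedy neighbour-count (GROMOS/g_cluster style) partition.

Each pairwise RMSD is computed after an optimal rigid-body superposition of
a fixed, ordered atom subset.  The default subset has 18 atoms: backbone N,
CA, C of the five motif residues, plus Cys S-gamma, the His binding nitrogen
(N-delta-1) and the zinc.  The subset is configurable because the exact set
used in the original survey was published only in supplementary material.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circmean, circstd

__all__ = [
    "AtomSubsetSpec",
    "DEFAULT_SUBSET",
    "MotifClustering",
    "kabsch_superpose",
    "motif_subset_coordinates",
    "pairwise_rmsd",
    "gromos_cluster",
    "cluster_summary",
]


@dataclass(frozen=True)
class AtomSubsetSpec:
    """Ordered (relative residue position 0..4, atom name) entries, with an
    optional zinc atom appended."""

    entries: tuple[tuple[int, str], ...]
    include_zinc: bool = True
    name: str = "custom"

    def __len__(self) -> int:
        return len(self.entries) + (1 if self.include_zinc else 0)


#: 15 backbone atoms + Cys SG + His ND1 + Zn = 18 atoms.
DEFAULT_SUBSET = AtomSubsetSpec(
    entries=tuple(
        [(k, a) for k in range(5) for a in ("N", "CA", "C")]
        + [(0, "SG"), (3, "ND1")]
    ),
    include_zinc=True,
    name="default18",
)


def kabsch_superpose(x: np.ndarray, y: np.ndarray):
    """Least-squares rigid superposition of ``y`` onto ``x``.

    Returns ``(rotation, translation, rmsd)`` with a proper rotation
    (det = +1) such that ``y @ R.T + t`` best fits ``x``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
        raise ValueError("point sets must be matched (n>=3, 3) arrays")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = yc.T @ xc
    u, sv, vt = np.linalg.svd(h)
    if sv[1] < 1e-12:
        raise ValueError("degenerate (rank-deficient) point sets")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    t = x.mean(axis=0) - rot @ y.mean(axis=0)
    diff = (y @ rot.T + t) - x
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
    return rot, t, rmsd


def motif_subset_coordinates(motif, s, subset: AtomSubsetSpec = DEFAULT_SUBSET) -> np.ndarray:
    """Coordinates of the subset atoms of one motif, in subset order."""
    residues = motif.window_residues(s)
    coords = []
    for pos, name in subset.entries:
        res = residues[pos]
        if name == "ND1" and not res.has_atom("ND1") and res.has_atom("NE2"):
            name = "NE2"  # epsilon-tautomer binders still contribute a ring N
        try:
            coords.append(res.atom(name).position)
        except KeyError as exc:
            raise ValueError(
                f"motif {motif.key}: cannot resolve subset atom {name} at position {pos}"
            ) from exc
    if subset.include_zinc:
        coords.append(motif.site.zinc_position)
    return np.array(coords)


def pairwise_rmsd(coord_sets: list[np.ndarray]) -> np.ndarray:
    """Symmetric matrix of pair-fitted RMSDs (A) between coordinate sets."""
    n = len(coord_sets)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, rmsd = kabsch_superpose(coord_sets[i], coord_sets[j])
            mat[i, j] = mat[j, i] = rmsd
    return mat


@dataclass
class MotifClustering:
    """Partition of motif indices into clusters (centroid, members) plus
    singleton outliers; clusters ordered by decreasing size."""

    clusters: list[tuple[int, list[int]]] = field(default_factory=list)
    outliers: list[int] = field(default_factory=list)
    cutoff: float = 0.4

    @property
    def sizes(self) -> list[int]:
        return [1 + len(m) for _, m in self.clusters]

    def labels(self, n: int) -> np.ndarray:
        """Cluster index per item (outliers get -1)."""
        lab = np.full(n, -1, dtype=int)
        for ci, (centroid, members) in enumerate(self.clusters):
            lab[centroid] = ci
            for m in members:
                lab[m] = ci
        return lab


def gromos_cluster(matrix: np.ndarray, cutoff: float = 0.4) -> MotifClustering:
    """Greedy neighbour-count clustering.

    Repeatedly pick the element with the most remaining neighbours within
    ``cutoff`` (ties broken by lowest input index), form a cluster of it and
    its neighbours, remove them, and continue.  Singleton clusters are
    reported as outliers.
    """
    matrix = np.asarray(matrix, float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or not np.allclose(matrix, matrix.T, atol=1e-9):
        raise ValueError("matrix must be square and symmetric")
    remaining = list(range(n))
    clustering = MotifClustering(cutoff=cutoff)
    raw: list[tuple[int, list[int]]] = []
    while remaining:
        counts = {
            i: sum(1 for j in remaining if j != i and matrix[i, j] <= cutoff)
            for i in remaining
        }
        center = min(remaining, key=lambda i: (-counts[i], i))
        members = [j for j in remaining if j != center and matrix[center, j] <= cutoff]
        raw.append((center, members))
        taken = {center, *members}
        remaining = [i for i in remaining if i not in taken]
    for center, members in raw:
        if members:
            clustering.clusters.append((center, sorted(members)))
        else:
            clustering.outliers.append(center)
    clustering.clusters.sort(key=lambda c: (-(1 + len(c[1])), c[0]))
    clustering.outliers.sort()
    return clustering


_ANGLE_KEYS = ("phi1", "psi1", "phi2", "psi2", "phi3", "psi3", "chi1_cys", "chi1_his")


def _circular_mean_sd(values) -> tuple[float, float]:
    arr = np.asarray(values, float)
    mean = float(circmean(arr, high=180.0, low=-180.0))
    sd = float(circstd(arr, high=180.0, low=-180.0))
    if mean <= -180.0:
        mean += 360.0
    return mean, sd


def cluster_summary(clustering: MotifClustering, profiles: list) -> list[dict]:
    """Per-cluster circular means and SDs of the eight motif torsions.

    ``profiles[i]`` is the TorsionProfile of input item ``i``.  Outliers are
    included as size-1 rows after the clusters.
    """
    rows = []
    groups = [
        ("cluster", [centroid] + members)
        for centroid, members in clustering.clusters
    ] + [("outlier", [i]) for i in clustering.outliers]
    for idx, (kind, members) in enumerate(groups, start=1):
        row: dict = {"cluster": idx, "kind": kind, "size": len(members),
                     "members": list(members)}
        for key in _ANGLE_KEYS:
            vals = [getattr(profiles[i], key) for i in members]
            mean, sd = _circular_mean_sd(vals)
            row[f"{key}_mean"] = mean
            row[f"{key}_sd"] = sd
        rows.append(row)
    return rows
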
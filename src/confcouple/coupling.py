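"""Coupling between aromatic-pair geometry and collective motions.

Centroid-to-centroid distance time series for designated residue
pairs, their Pearson correlation with principal-component projections,
two-dimensional free-energy surfaces over collective coordinates, and
detection of metastable basins on those surfaces.

A "center-to-center" distance is between unweighted centroids of the
ring heavy atoms.  Default ring definitions:

* Phe / Tyr: CG, CD1, CD2, CE1, CE2, CZ (six-membered ring)
* Trp: CD2, CE2, CE3, CZ2, CZ3, CH2 (six-membered ring)
* His: CG, ND1, CD2, CE1, NE2 (imidazole)

The free-energy surface is ``F = −k_B·T·ln(count / max_count)`` in
kcal/mol over a 2D histogram of the two coordinates, so the most
occupied bin sits at exactly F = 0 and empty bins are masked (+inf).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .essential_dynamics import PcaResult
from .trajio import StructureModel, Trajectory

__all__ = [
    "KB_KCAL",
    "DEFAULT_RING_ATOMS",
    "ClusterMember",
    "ClusterSpec",
    "DistanceSeries",
    "CorrelationMatrix",
    "FesGrid",
    "Basin",
    "ring_centroid",
    "pair_distance_series",
    "distance_pc_correlation",
    "free_energy_surface",
    "find_basins",
    "compensation_score",
]

#: Boltzmann constant in kcal·mol⁻¹·K⁻¹
KB_KCAL = 0.0019872041

DEFAULT_RING_ATOMS: dict[str, frozenset[str]] = {
    "PHE": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TYR": frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),
    "TRP": frozenset({"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    "HIS": frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),
}


class ClusterMember(NamedTuple):
    """One aromatic residue of a cluster, in author numbering."""

    chain_id: str
    residue_number: int
    residue_name: str

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.residue_number}"


@dataclass
class ClusterSpec:
    """A set of aromatic residues plus the rule defining their ring atoms."""

    members: list[ClusterMember]
    ring_rule: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_RING_ATOMS)
    )

    def __post_init__(self):
        if len(self.members) < 2:
            raise ValueError("a cluster needs at least 2 members")
        for m in self.members:
            if m.residue_name not in self.ring_rule:
                raise KeyError(
                    f"no ring rule for residue name {m.residue_name!r} "
                    f"(member {m.label})"
                )

    def pair_label(self, a: ClusterMember, b: ClusterMember) -> str:
        if a.chain_id == b.chain_id:
            return f"PRO{a.chain_id}:{a.residue_number}-{b.residue_number}"
        return f"{a.label}-{b.label}"


@dataclass
class DistanceSeries:
    """Per-frame centroid-to-centroid distance for one residue pair (Å)."""

    label: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite distances in series {self.label!r}")

    def __len__(self) -> int:
        return len(self.values)


def _member_ring_indices(
    topology: StructureModel,
    member: ClusterMember,
    ring_rule: Mapping[str, frozenset[str]],
) -> np.ndarray:
    try:
        names = ring_rule[member.residue_name]
    except KeyError:
        raise KeyError(
            f"no ring rule for residue name {member.residue_name!r}"
        ) from None
    idx = []
    for name in sorted(names):
        try:
            idx.append(topology.atom_index(member.chain_id, member.residue_number, name))
        except KeyError:
            raise KeyError(
                f"ring atom {name} missing for residue "
                f"{member.residue_name} {member.label}"
            ) from None
    return np.asarray(idx, dtype=int)


def ring_centroid(
    coords: np.ndarray,
    topology: StructureModel,
    member: ClusterMember,
    ring_rule: Mapping[str, frozenset[str]] | None = None,
) -> np.ndarray:
    """Unweighted mean of a residue's ring heavy-atom coordinates (Å)."""
    rule = ring_rule if ring_rule is not None else DEFAULT_RING_ATOMS
    idx = _member_ring_indices(topology, member, rule)
    return np.asarray(coords, dtype=float)[idx].mean(axis=0)


def pair_distance_series(
    traj: Trajectory,
    a: ClusterMember,
    b: ClusterMember,
    ring_rule: Mapping[str, frozenset[str]] | None = None,
    label: str | None = None,
) -> DistanceSeries:
    """Centroid-to-centroid distance of two residues in every frame.

    Distances are invariant to per-frame rigid motions, so no
    superposition is applied.
    """
    rule = ring_rule if ring_rule is not None else DEFAULT_RING_ATOMS
    if a == b:
        warnings.warn(f"pair distance of {a.label} with itself is identically 0")
    ia = _member_ring_indices(traj.topology, a, rule)
    ib = _member_ring_indices(traj.topology, b, rule)
    ca = traj.frames[:, ia, :].mean(axis=1)
    cb = traj.frames[:, ib, :].mean(axis=1)
    d = np.linalg.norm(ca - cb, axis=1)
    if label is None:
        if a.chain_id == b.chain_id:
            label = f"PRO{a.chain_id}:{a.residue_number}-{b.residue_number}"
        else:
            label = f"{a.label}-{b.label}"
    return DistanceSeries(label=label, values=d)


@dataclass
class CorrelationMatrix:
    """Pearson correlations between distance series (rows) and PCs
    (columns), with undefined entries (zero variance) left as NaN."""

    r: pd.DataFrame
    abs_r: pd.DataFrame

    def ranked(self, pc: int = 1) -> pd.Series:
        """Pairs ranked by |r| with the given PC (descending)."""
        col = f"PC{pc}"
        return self.abs_r[col].sort_values(ascending=False)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return np.nan
    return float((xc @ yc) / (sx * sy))


def distance_pc_correlation(
    series_list: Sequence[DistanceSeries],
    pca: PcaResult,
    n_pcs: int = 10,
) -> CorrelationMatrix:
    """Correlate each pair-distance series with the first ``n_pcs``
    principal-component projections.

    A zero-variance series gives NaN entries (undefined, not zero).
    """
    n_pcs = min(n_pcs, pca.n_modes)
    n_frames = pca.projections.shape[0]
    cols = [f"PC{k}" for k in range(1, n_pcs + 1)]
    rows = {}
    for s in series_list:
        if len(s) != n_frames:
            raise ValueError(
                f"series {s.label!r} has {len(s)} frames, PCA has {n_frames}"
            )
        if np.std(s.values) == 0:
            warnings.warn(f"series {s.label!r} has zero variance; r undefined")
        rows[s.label] = [
            _pearson(s.values, pca.projections[:, k]) for k in range(n_pcs)
        ]
    r = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    return CorrelationMatrix(r=r, abs_r=r.abs())


@dataclass
class FesGrid:
    """2D free-energy surface over two collective coordinates.

    ``free_energy`` is in kcal/mol with the most occupied bin at 0 and
    empty bins at +inf; ``counts`` sums to the number of frames.
    """

    x_label: str
    y_label: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray  # (nx, ny)
    free_energy: np.ndarray  # (nx, ny), +inf where counts == 0
    temperature: float  # K

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def mask(self) -> np.ndarray:
        """True where the bin is empty (F undefined)."""
        return self.counts == 0

    def to_frame(self) -> pd.DataFrame:
        xc, yc = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        return pd.DataFrame(
            {
                "x_center": xc.ravel(),
                "y_center": yc.ravel(),
                "count": self.counts.ravel().astype(int),
                "free_energy": self.free_energy.ravel(),
                "masked": self.mask.ravel(),
            }
        )


def free_energy_surface(
    x: np.ndarray | DistanceSeries,
    y: np.ndarray | DistanceSeries,
    n_bins: tuple[int, int] = (100, 100),
    temperature: float = 310.0,
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
    x_label: str | None = None,
    y_label: str | None = None,
    pad_fraction: float = 0.02,
) -> FesGrid:
    """Histogram two coordinate series and convert to −kT·ln(P/Pmax).

    By default the bin range is the data range padded by 2% on each
    side.  Temperature defaults to 310 K.
    """
    if isinstance(x, DistanceSeries):
        x_label = x_label or x.label
        x = x.values
    if isinstance(y, DistanceSeries):
        y_label = y_label or y.label
        y = y.values
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y series must have equal length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if min(n_bins) < 2:
        raise ValueError("need at least 2 bins per axis")
    if ranges is None:
        ranges = tuple(
            (
                v.min() - pad_fraction * max(np.ptp(v), 1e-12),
                v.max() + pad_fraction * max(np.ptp(v), 1e-12),
            )
            for v in (x, y)
        )
    counts, x_edges, y_edges = np.histogram2d(x, y, bins=n_bins, range=ranges)
    if counts.max() == counts.sum():
        warnings.warn("all points fall in a single bin; surface is degenerate")
    with np.errstate(divide="ignore"):
        F = -KB_KCAL * temperature * np.log(counts / counts.max())
    F[counts == 0] = np.inf
    return FesGrid(
        x_label=x_label or "x",
        y_label=y_label or "y",
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        free_energy=F,
        temperature=temperature,
    )


class Basin(NamedTuple):
    """A metastable basin: its minimum bin, free energy, and depth
    relative to the lowest saddle connecting it to a deeper basin."""

    x_center: float
    y_center: float
    free_energy: float
    depth: float


def find_basins(fes: FesGrid, depth_threshold: float = 0.5) -> list[Basin]:
    """Detect basins on the surface by persistence flood-fill.

    Occupied bins are visited in order of increasing F, merging
    8-connected components.  When a shallower component meets a deeper
    one, its depth is the saddle level minus its minimum; it is kept as
    a basin only if that depth is at least ``depth_threshold``
    (kcal/mol, default ~k_B·T at 310 K).  The global minimum's depth is
    measured to the highest occupied level.  Basins are returned sorted
    by F ascending.
    """
    F = fes.free_energy
    occ = np.argwhere(np.isfinite(F))
    if occ.size == 0:
        return []
    order = occ[np.argsort(F[occ[:, 0], occ[:, 1]], kind="stable")]
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    comp_min: dict[tuple[int, int], tuple[float, tuple[int, int]]] = {}
    basins: list[tuple[tuple[int, int], float, float]] = []  # (min bin, F, depth)

    def find(c):
        root = c
        while parent[root] != root:
            root = parent[root]
        while parent[c] != root:
            parent[c], c = root, parent[c]
        return root

    for i, j in map(tuple, order):
        cell = (i, j)
        level = F[i, j]
        parent[cell] = cell
        comp_min[cell] = (level, cell)
        neighbor_roots = set()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                nb = (i + di, j + dj)
                if nb in parent:
                    neighbor_roots.add(find(nb))
        for root in neighbor_roots:
            cell_root = find(cell)
            if root == cell_root:
                continue
            # merging two components at this level: the shallower one's
            # prominence is level - its minimum
            (fa, ma) = comp_min[cell_root]
            (fb, mb) = comp_min[root]
            if fa <= fb:
                deep_root, shallow = cell_root, (fb, mb)
            else:
                deep_root, shallow = root, (fa, ma)
            depth = level - shallow[0]
            if depth >= depth_threshold:
                basins.append((shallow[1], shallow[0], depth))
            parent[cell_root] = deep_root
            parent[root] = deep_root
            comp_min[deep_root] = min((fa, ma), (fb, mb))
    # surviving components (the global minimum, plus any occupied region
    # disconnected from it): depth measured to the highest occupied level
    top_level = float(F[np.isfinite(F)].max())
    for root in {find(tuple(c)) for c in order}:
        f_min, m_min = comp_min[root]
        depth = top_level - f_min
        if depth >= depth_threshold:
            basins.append((m_min, f_min, depth))
    basins.sort(key=lambda b: b[1])
    xc, yc = fes.x_centers, fes.y_centers
    return [
        Basin(float(xc[b[0][0]]), float(yc[b[0][1]]), float(b[1]), float(b[2]))
        for b in basins
    ]


def compensation_score(a: DistanceSeries, b: DistanceSeries) -> float:
    """Pearson correlation of two pair-distance series.

    A markedly negative score indicates a compensating relationship:
    one pair opens only while the other closes.  Returns NaN (undefined)
    if either series has zero variance.
    """
    if len(a) != len(b):
        raise ValueError("series must have equal length")
    r = _pearson(a.values, b.values)
    if np.isnan(r):
        warnings.warn("zero-variance series; compensation score undefined")
    return r
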
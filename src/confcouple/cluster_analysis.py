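"""Static aromatic-cluster geometry and MSA conservation scanning.

Two complementary views of the aromatic cluster in the mobile "spoon"
and "fork" regions flanking the DXPS active site: (1) all pairwise
ring-centroid distances of the cluster residues in a closed-state
structure, grouped per protomer (PDB chain); and (2) a per-homolog
count of aromatic residues (F/Y/W by default, His optional) inside
named alignment-column windows of a multiple sequence alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coupling import ClusterSpec, ring_centroid
from .trajio import Msa, StructureModel

__all__ = [
    "ClusterGeometryReport",
    "MotifWindows",
    "AromaticCountTable",
    "DEFAULT_AROMATIC_SET",
    "cluster_geometry",
    "scan_msa_aromatics",
    "map_column_to_residue",
]

DEFAULT_AROMATIC_SET = frozenset({"F", "Y", "W"})


@dataclass
class ClusterGeometryReport:
    """Pairwise centroid distances of a cluster, per protomer and overall."""

    cluster: ClusterSpec
    distance_matrix: pd.DataFrame  # symmetric, zero diagonal, Å
    min_distance: float
    max_distance: float
    per_protomer: dict[str, tuple[float, float]]  # chain -> (min, max)


def cluster_geometry(
    structure: StructureModel, cluster: ClusterSpec
) -> ClusterGeometryReport:
    """All pairwise ring-centroid distances of the cluster residues (Å).

    Min/max are over off-diagonal entries, overall and per PDB chain
    (protomer grouping).
    """
    labels = [m.label for m in cluster.members]
    cents = np.stack(
        [
            ring_centroid(structure.coords, structure, m, cluster.ring_rule)
            for m in cluster.members
        ]
    )
    diff = cents[:, None, :] - cents[None, :, :]
    D = np.linalg.norm(diff, axis=2)
    off = D[~np.eye(len(labels), dtype=bool)]
    per_protomer: dict[str, tuple[float, float]] = {}
    for chain in {m.chain_id for m in cluster.members}:
        idx = [i for i, m in enumerate(cluster.members) if m.chain_id == chain]
        if len(idx) < 2:
            continue
        sub = D[np.ix_(idx, idx)]
        sub_off = sub[~np.eye(len(idx), dtype=bool)]
        per_protomer[chain] = (float(sub_off.min()), float(sub_off.max()))
    return ClusterGeometryReport(
        cluster=cluster,
        distance_matrix=pd.DataFrame(D, index=labels, columns=labels),
        min_distance=float(off.min()),
        max_distance=float(off.max()),
        per_protomer=per_protomer,
    )


@dataclass
class MotifWindows:
    """Named inclusive 1-based alignment-column intervals (e.g. spoon/fork)."""

    windows: dict[str, tuple[int, int]]

    def validate(self, n_columns: int) -> None:
        for name, (lo, hi) in self.windows.items():
            if not (1 <= lo <= hi <= n_columns):
                raise ValueError(
                    f"window {name!r} = {lo}-{hi} outside alignment "
                    f"columns 1..{n_columns}"
                )

    def columns(self) -> list[int]:
        """Sorted union of all window columns (1-based)."""
        cols: set[int] = set()
        for lo, hi in self.windows.values():
            cols.update(range(lo, hi + 1))
        return sorted(cols)


@dataclass
class AromaticCountTable:
    """Per-sequence aromatic counts within motif windows."""

    table: pd.DataFrame  # index: sequence id; columns: count, columns
    distribution: Counter  # count value -> number of sequences

    def count(self, seq_id: str) -> int:
        return int(self.table.loc[seq_id, "count"])

    def n_with_count(self, value: int) -> int:
        return self.distribution.get(value, 0)


def scan_msa_aromatics(
    msa: Msa,
    windows: MotifWindows,
    aromatic_set: frozenset[str] = DEFAULT_AROMATIC_SET,
) -> AromaticCountTable:
    """Count aromatic residues per sequence within the window columns.

    Gaps are ignored.  The distribution across sequences (how many
    homologs carry exactly k aromatics) is reported alongside.
    """
    windows.validate(msa.n_columns)
    cols = windows.columns()
    rows = []
    for rid, seq in msa.records:
        hit_cols = [c for c in cols if seq[c - 1] in aromatic_set]
        rows.append((rid, len(hit_cols), hit_cols))
    table = pd.DataFrame(
        rows, columns=["id", "count", "columns"]
    ).set_index("id")
    distribution = Counter(table["count"].tolist())
    return AromaticCountTable(table=table, distribution=distribution)


def map_column_to_residue(msa: Msa, seq_id: str, column: int) -> int:
    """Map an alignment column to the ungapped residue index (1-based).

    The result is the number of non-gap characters up to and including
    the column; a gap at the requested position is an error.
    """
    seq = msa.sequence(seq_id)
    if not 1 <= column <= msa.n_columns:
        raise IndexError(f"column {column} outside 1..{msa.n_columns}")
    if seq[column - 1] == "-":
        raise ValueError(f"column {column} is a gap in sequence {seq_id!r}")
    return sum(1 for ch in seq[:column] if ch != "-")
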
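"""Essential dynamics: superposition, PCA and mode displacement profiles.

The covariance analysed is the *population* covariance (divide by the
number of frames) of the aligned, mean-centered Cartesian coordinates
of the selected atoms, unweighted.  Frames are superposed onto an
iteratively refined mean structure (fit to the first frame, compute
the mean, re-fit; two passes) so the reference introduces no bias.

Each eigenmode is sign-fixed so that its largest-magnitude component
is positive (ties broken by lowest atom index), which makes projection
time series and downstream correlations reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajio import AtomSelection, Trajectory

__all__ = [
    "DegenerateFitError",
    "kabsch_superpose",
    "PcaResult",
    "DisplacementProfile",
    "compute_pca",
    "displacement_along_pc",
    "project_frames",
]


class DegenerateFitError(ValueError):
    """Fit atoms are coincident or collinear; the rotation is not unique."""


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch, SVD form).

    The optimal rotation+translation (no reflection) over the fit atoms
    is applied to *all* atoms of ``mobile``; the returned RMSD is over
    the fit atoms only.

    Parameters
    ----------
    mobile, reference : (n_atoms, 3) arrays in Å.
    fit_indices : indices of the atoms defining the fit.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    fit_indices = np.asarray(fit_indices, dtype=int)
    if fit_indices.size == 0:
        raise ValueError("empty fit selection")
    P = mobile[fit_indices]
    Q = reference[fit_indices]
    p_cen = P.mean(axis=0)
    q_cen = Q.mean(axis=0)
    P0 = P - p_cen
    Q0 = Q - q_cen
    # coincident or collinear fit atoms leave the rotation under-determined
    if np.linalg.matrix_rank(Q0, tol=1e-10) < 2 or np.linalg.matrix_rank(P0, tol=1e-10) < 2:
        raise DegenerateFitError(
            "fit atoms are coincident or collinear; superposition is degenerate"
        )
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    aligned = (mobile - p_cen) @ R.T + q_cen
    rmsd = float(np.sqrt(np.mean(np.sum((aligned[fit_indices] - Q) ** 2, axis=1))))
    return aligned, rmsd


@dataclass
class PcaResult:
    """Eigen-decomposition of the selected-atom coordinate covariance.

    ``modes`` has shape (3N, K) with orthonormal columns; ``projections``
    (n_frames, K) are the mean-centered aligned frames projected onto the
    modes, in Å.  ``align_reference`` stores the full-topology coordinates
    the frames were superposed onto, so new frames can be projected with
    exactly the same alignment.
    """

    selection: AtomSelection
    mean_coords: np.ndarray  # (3N,)
    eigenvalues: np.ndarray  # (K,), Å², descending
    modes: np.ndarray  # (3N, K)
    projections: np.ndarray  # (n_frames, K)
    align: bool
    fit_selection: AtomSelection | None
    align_reference: np.ndarray | None  # (n_atoms_topology, 3)

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total == 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


@dataclass
class DisplacementProfile:
    """Per-atom RMS displacement contributed by one mode (Å)."""

    mode_index: int  # 1-based
    selection: AtomSelection
    displacements: np.ndarray  # (n_selected,) aligned with selection.indices

    def full_profile(self, n_atoms: int) -> np.ndarray:
        """Per-atom displacement over the whole topology; zero outside the
        selection."""
        out = np.zeros(n_atoms)
        out[self.selection.as_array()] = self.displacements
        return out

    def per_residue_max(self, topology) -> dict[tuple[str, str], float]:
        """Aggregate to residues as the max over each residue's selected
        atoms, keyed by (chain_id, residue_key)."""
        out: dict[tuple[str, str], float] = {}
        for idx, d in zip(self.selection.indices, self.displacements):
            atom = topology.atoms[idx]
            key = (atom.chain_id, atom.residue_key)
            out[key] = max(out.get(key, 0.0), float(d))
        return out


def _fix_mode_signs(modes: np.ndarray) -> np.ndarray:
    """Orient each column so its largest-magnitude component is positive
    (ties by lowest index, which argmax already yields)."""
    out = modes.copy()
    for k in range(out.shape[1]):
        i = int(np.argmax(np.abs(out[:, k])))
        if out[i, k] < 0:
            out[:, k] = -out[:, k]
    return out


def _align_frames(
    frames: np.ndarray, fit_idx: np.ndarray, n_passes: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all frames onto an iteratively refined mean structure.

    Returns the aligned frames and the reference they were last fit to.
    """
    reference = frames[0]
    aligned = frames
    used_reference = reference
    for _ in range(n_passes):
        used_reference = reference
        aligned = np.stack(
            [kabsch_superpose(f, reference, fit_idx)[0] for f in frames]
        )
        reference = aligned.mean(axis=0)
    return aligned, used_reference


def compute_pca(
    traj: Trajectory,
    selection: AtomSelection,
    align: bool = True,
    fit_selection: AtomSelection | None = None,
) -> PcaResult:
    """PCA of the selected atoms' aligned Cartesian coordinates.

    Parameters
    ----------
    traj : trajectory (n_frames ≥ 2).
    selection : atoms entering the covariance (e.g. Cα plus ligand
        heavy atoms).
    align : superpose frames before the analysis (default on; distances
        and internal motions only).
    fit_selection : atoms used for the superposition; defaults to
        ``selection``, letting the fit set (e.g. Cα only) differ from
        the analysis set.
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if max(selection.indices) >= traj.n_atoms:
        raise ValueError("selection indices outside trajectory atom range")
    fit_sel = fit_selection if fit_selection is not None else selection
    if align:
        aligned, reference = _align_frames(traj.frames, fit_sel.as_array())
    else:
        aligned, reference = traj.frames, None
    sel_idx = selection.as_array()
    X = aligned[:, sel_idx, :].reshape(traj.n_frames, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centered data matrix == eigendecomposition of the
    # population covariance Xc.T @ Xc / n_frames
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / traj.n_frames
    modes = _fix_mode_signs(Vt.T)
    projections = Xc @ modes
    return PcaResult(
        selection=selection,
        mean_coords=mean,
        eigenvalues=eigenvalues,
        modes=modes,
        projections=projections,
        align=align,
        fit_selection=fit_sel if align else None,
        align_reference=reference,
    )


def displacement_along_pc(pca: PcaResult, k: int) -> DisplacementProfile:
    """RMS displacement of each selected atom contributed by mode ``k``.

    ``d_i = sqrt(λ_k) · ‖(e_k)_i‖`` where ``(e_k)_i`` is the atom's
    3-vector block of the (unit) eigenmode.  ``k`` is 1-based.
    """
    if not 1 <= k <= pca.n_modes:
        raise IndexError(f"mode index {k} out of range 1..{pca.n_modes}")
    mode = pca.modes[:, k - 1].reshape(-1, 3)
    d = np.sqrt(pca.eigenvalues[k - 1]) * np.linalg.norm(mode, axis=1)
    return DisplacementProfile(mode_index=k, selection=pca.selection, displacements=d)


def project_frames(pca: PcaResult, frames: np.ndarray, k: int) -> np.ndarray:
    """Project frames onto mode ``k`` (1-based), reproducing the stored
    alignment and centering.

    ``frames`` may be a :class:`Trajectory`, an (n_frames, n_atoms, 3)
    array over the full topology, or an (n_atoms, 3) single frame.
    """
    if not 1 <= k <= pca.n_modes:
        raise IndexError(f"mode index {k} out of range 1..{pca.n_modes}")
    if isinstance(frames, Trajectory):
        frames = frames.frames
    frames = np.asarray(frames, dtype=float)
    single = frames.ndim == 2
    if single:
        frames = frames[None]
    if pca.align:
        if frames.shape[1] != pca.align_reference.shape[0]:
            raise ValueError(
                "frames are not atom-compatible with the PCA topology"
            )
        fit_idx = pca.fit_selection.as_array()
        frames = np.stack(
            [
                kabsch_superpose(f, pca.align_reference, fit_idx)[0]
                for f in frames
            ]
        )
    sel_idx = pca.selection.as_array()
    if sel_idx.max() >= frames.shape[1]:
        raise ValueError("frames are not atom-compatible with the PCA selection")
    X = frames[:, sel_idx, :].reshape(frames.shape[0], -1)
    proj = (X - pca.mean_coords) @ pca.modes[:, k - 1]
    return float(proj[0]) if single else proj


def project_selected(pca: PcaResult, sel_coords: np.ndarray, k: int) -> float:
    """Project a single already-aligned selected-atom coordinate set
    (3N vector or (N,3)) onto mode ``k`` without re-alignment."""
    x = np.asarray(sel_coords, dtype=float).reshape(-1)
    return float((x - pca.mean_coords) @ pca.modes[:, k - 1])
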
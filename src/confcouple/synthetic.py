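"""Synthetic inputs with known ground truth for every analysis stage.

The trajectory generator emulates, at toy scale, a protein whose slow
dynamics is a two-state open/close transition: a latent telegraph
process s(t) ∈ {0, 1} (per-frame switch probabilities ``rate_up``,
``rate_down``) displaces all "background" atoms along a collective
mode and sets the separation of designated residue pairs, on top of
isotropic Gaussian thermal noise.  Every generator returns its ground
truth (planted mode, variances, analytic correlations, basin centers,
kinetic/melt parameters) alongside the data.

Planted pair correlation.  A pair sits on the x axis at rest
separation d₀; atom b carries a mode component J (the "jump") along x,
so to first order the per-frame distance is

    d(t) ≈ d₀ + J·s(t) + (ε_bx − ε_ax),   ε ~ N(0, σ²) i.i.d.

With σ_s = std(s) = sqrt(p(1−p)) (p the stationary occupancy of state
1), the distance–latent correlation is

    ρ = J·σ_s / sqrt(J²·σ_s² + 2σ²)

which is inverted to plant a target ρ: J = ρ·√2·σ / (σ_s·√(1−ρ²)).
|ρ| = 1 therefore requires σ = 0 (the attainable |ρ| is < 1 for any
positive noise), and ρ strictly between 0 and 1 is unattainable at
σ = 0.  The analytic correlation with the PC1 projection (which adds
one noise degree of freedom) is also reported.

All randomness flows from a single integer seed; independent
sub-streams are derived per purpose so adding one generator call never
perturbs another's output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cluster_analysis import MotifWindows
from .coupling import ClusterMember, ClusterSpec
from .trajio import Atom, Msa, StructureModel, Trajectory

__all__ = [
    "PairSpec",
    "CoupledTrajectoryParams",
    "TrajectoryGroundTruth",
    "POINT_RING_RULE",
    "generate_coupled_trajectory",
    "RingSpec",
    "generate_toy_structure",
    "planted_five_ring_cluster",
    "generate_msa_fixture",
    "sixteen_homolog_fixture",
    "DEFAULT_MSA_WINDOWS",
    "generate_mm_data",
    "generate_melt_curve",
    "generate_cd_timecourse",
]

#: ring rule treating a single CA atom as its own "ring" center, used by
#: the point-atom toy topologies the trajectory generator emits
POINT_RING_RULE = {"GLY": frozenset({"CA"})}


def derive_rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-purpose random stream from one global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# Coupled-mode trajectory
# ---------------------------------------------------------------------------


@dataclass
class PairSpec:
    """One coupled residue pair: specify the target correlation ``rho``
    with the latent mode, or the separation jump ``jump`` (Å) directly
    (exactly one of the two)."""

    rho: float | None = None
    jump: float | None = None
    d0: float = 4.0  # rest (state-0) separation, Å

    def __post_init__(self):
        if (self.rho is None) == (self.jump is None):
            raise ValueError("specify exactly one of rho or jump")
        if self.rho is not None and abs(self.rho) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")


@dataclass
class CoupledTrajectoryParams:
    n_background: int = 8
    n_frames: int = 20_000
    rate_up: float = 0.01  # per-frame 0 -> 1 switch probability
    rate_down: float = 0.01  # per-frame 1 -> 0 switch probability
    amplitude: float = 3.0  # background displacement between states, Å
    pairs: list[PairSpec] = field(default_factory=list)
    noise_sigma: float = 0.5  # Å, isotropic per atom per frame
    seed: int = 0
    latent: str = "telegraph"  # or "ou"
    mode_vector: np.ndarray | None = None  # (3*n_background,), optional

    def __post_init__(self):
        if not (0 < self.rate_up < 1 and 0 < self.rate_down < 1):
            raise ValueError("switch rates must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.latent not in ("telegraph", "ou"):
            raise ValueError(f"unknown latent process {self.latent!r}")


@dataclass
class TrajectoryGroundTruth:
    """What was planted: the collective mode, its variance, and per-pair
    analytic correlations / basin centers."""

    mode: np.ndarray  # unit 3N vector over ALL atoms
    mode_variance: float  # planted variance along the mode, Å²
    expected_lambda1: float  # analytic top PCA eigenvalue: mode_variance + σ²
    occupancy: float  # stationary P(state 1)
    pair_members: list[tuple[ClusterMember, ClusterMember]]
    pair_rho_latent: list[float]  # analytic corr(distance, latent)
    pair_rho_pc1: list[float]  # analytic corr(distance, PC1 projection)
    pair_basin_centers: list[tuple[float, float]]  # (d0, d0 + jump)
    pair_jumps: list[float]
    ring_rule: dict = field(default_factory=lambda: dict(POINT_RING_RULE))


def _point_topology(n_atoms: int, base: np.ndarray) -> StructureModel:
    atoms = [
        Atom(
            atom_index=i,
            atom_name="CA",
            element="C",
            residue_number=i + 1,
            residue_name="GLY",
            chain_id="A",
            is_heavy=True,
        )
        for i in range(n_atoms)
    ]
    return StructureModel(atoms, base)


def _jump_from_rho(rho: float, sigma: float, sigma_s: float) -> float:
    if sigma == 0.0:
        if abs(rho) == 1.0:
            return np.copysign(1.0, rho)  # any nonzero jump gives |r| = 1
        if rho == 0.0:
            return 0.0
        raise ValueError(
            "with noise_sigma = 0 the attainable correlations are exactly "
            "0 or ±1; intermediate rho requires positive noise"
        )
    if abs(rho) >= 1.0:
        raise ValueError(
            "target |rho| = 1 is unattainable with positive noise_sigma "
            "(attainable |rho| < 1); set noise_sigma = 0 for a perfect pair"
        )
    return rho * np.sqrt(2.0) * sigma / (sigma_s * np.sqrt(1.0 - rho**2))


def _rho_from_jump(jump: float, sigma: float, sigma_s: float) -> float:
    if jump == 0.0:
        return 0.0
    denom = np.sqrt(jump**2 * sigma_s**2 + 2.0 * sigma**2)
    return jump * sigma_s / denom


def generate_coupled_trajectory(
    params: CoupledTrajectoryParams,
) -> tuple[Trajectory, TrajectoryGroundTruth]:
    """Generate a toy trajectory with one slow two-state collective mode
    coupled to designated residue-pair separations.

    The topology is a chain of single-CA "GLY" residues (chain A,
    residues numbered from 1): ``n_background`` mode-carrying atoms
    followed by two atoms per pair.  Use ``POINT_RING_RULE`` to treat
    each CA as its own centroid in the coupling analyses.

    The frames contain no rigid-body diffusion (only the planted mode
    plus i.i.d. atomic noise), so PCA of generated trajectories should
    run with ``align=False``; the analytic ground truth (mode direction,
    ``expected_lambda1``, correlations) is exact in that convention.
    Superposing would partially remove whatever rigid-body content the
    random mode direction happens to carry.
    """
    p = params
    n_pairs = len(p.pairs)
    n_atoms = p.n_background + 2 * n_pairs
    occupancy = p.rate_up / (p.rate_up + p.rate_down)
    sigma_s = float(np.sqrt(occupancy * (1.0 - occupancy)))

    # static base coordinates: background atoms spaced on z, each pair on
    # its own well-separated y level with the two atoms along x
    base = np.zeros((n_atoms, 3))
    for i in range(p.n_background):
        base[i] = (0.0, 0.0, 20.0 * i)
    jumps: list[float] = []
    members: list[tuple[ClusterMember, ClusterMember]] = []
    for j, pair in enumerate(p.pairs):
        ia = p.n_background + 2 * j
        ib = ia + 1
        y = 1000.0 + 50.0 * j
        base[ia] = (0.0, y, 0.0)
        base[ib] = (pair.d0, y, 0.0)
        if pair.rho is not None:
            jump = _jump_from_rho(pair.rho, p.noise_sigma, sigma_s)
        else:
            jump = float(pair.jump)
        jumps.append(jump)
        members.append(
            (
                ClusterMember("A", ia + 1, "GLY"),
                ClusterMember("A", ib + 1, "GLY"),
            )
        )

    # displacement vector between the two states, over all atoms
    rng_mode = derive_rng(p.seed, "mode")
    if p.mode_vector is not None:
        m = np.asarray(p.mode_vector, dtype=float).reshape(p.n_background, 3)
    else:
        m = rng_mode.normal(size=(p.n_background, 3))
    norm = np.linalg.norm(m)
    if norm == 0:
        raise ValueError("mode_vector must be nonzero")
    m = m / norm
    D = np.zeros((n_atoms, 3))
    D[: p.n_background] = p.amplitude * m
    for j, jump in enumerate(jumps):
        D[p.n_background + 2 * j + 1, 0] = jump  # atom b moves along +x

    # latent process
    rng_latent = derive_rng(p.seed, "latent")
    s = np.empty(p.n_frames)
    if p.latent == "telegraph":
        state = 1 if rng_latent.random() < occupancy else 0
        u = rng_latent.random(p.n_frames)
        for t in range(p.n_frames):
            s[t] = state
            if state == 0 and u[t] < p.rate_up:
                state = 1
            elif state == 1 and u[t] < p.rate_down:
                state = 0
    else:  # OU-style AR(1) matched to the telegraph's first two moments
        a = np.exp(-(p.rate_up + p.rate_down))
        innov = rng_latent.normal(size=p.n_frames)
        z = np.empty(p.n_frames)
        z[0] = innov[0]
        for t in range(1, p.n_frames):
            z[t] = a * z[t - 1] + np.sqrt(1.0 - a**2) * innov[t]
        s = occupancy + sigma_s * z

    rng_noise = derive_rng(p.seed, "noise")
    frames = base[None, :, :] + s[:, None, None] * D[None, :, :]
    if p.noise_sigma > 0:
        frames = frames + rng_noise.normal(
            scale=p.noise_sigma, size=frames.shape
        )

    topology = _point_topology(n_atoms, base)
    traj = Trajectory(topology, frames)

    norm_D = float(np.linalg.norm(D))
    sigma = p.noise_sigma
    rho_latent = [_rho_from_jump(j, sigma, sigma_s) for j in jumps]
    rho_pc1 = []
    for j in jumps:
        if j == 0.0 or norm_D == 0.0:
            rho_pc1.append(0.0)
        else:
            # the pair atom's x-noise enters both the distance and the
            # mode projection (the mode has a j/|D| component there),
            # hence the sigma^2 * j/|D| cross term
            num = j * norm_D * sigma_s**2 + sigma**2 * j / norm_D
            den = np.sqrt(
                (j**2 * sigma_s**2 + 2 * sigma**2)
                * (norm_D**2 * sigma_s**2 + sigma**2)
            )
            rho_pc1.append(float(num / den))
    truth = TrajectoryGroundTruth(
        mode=(D / norm_D).reshape(-1) if norm_D else D.reshape(-1),
        mode_variance=norm_D**2 * sigma_s**2,
        expected_lambda1=norm_D**2 * sigma_s**2 + sigma**2,
        occupancy=occupancy,
        pair_members=members,
        pair_rho_latent=rho_latent,
        pair_rho_pc1=rho_pc1,
        pair_basin_centers=[
            (pair.d0, pair.d0 + jump) for pair, jump in zip(p.pairs, jumps)
        ],
        pair_jumps=jumps,
    )
    return traj, truth


# ---------------------------------------------------------------------------
# Toy structures with planted ring geometry
# ---------------------------------------------------------------------------

# ring atom names in order around the ring, with circumradius (Å);
# hexagons use the aromatic C-C bond length 1.39 Å (circumradius = side)
_RING_LAYOUT = {
    "PHE": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), 1.39),
    "TYR": (("CG", "CD1", "CE1", "CZ", "CE2", "CD2"), 1.39),
    "TRP": (("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"), 1.39),
    "HIS": (("CG", "ND1", "CE1", "NE2", "CD2"), 1.17),
}


@dataclass
class RingSpec:
    residue_name: str
    centroid: tuple[float, float, float]
    chain_id: str = "A"
    residue_number: int = 0
    normal: tuple[float, float, float] = (0.0, 0.0, 1.0)


def generate_toy_structure(rings: Sequence[RingSpec]) -> StructureModel:
    """Build a structure of idealized aromatic rings (regular polygons)
    whose emitted ring-atom centroids equal the requested centroids.

    Residue keys (chain, number) must be unique.
    """
    seen = set()
    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    for ring in rings:
        if ring.residue_name not in _RING_LAYOUT:
            raise KeyError(f"no ring layout for {ring.residue_name!r}")
        key = (ring.chain_id, ring.residue_number)
        if key in seen:
            raise ValueError(f"duplicate residue key {key}")
        seen.add(key)
        names, radius = _RING_LAYOUT[ring.residue_name]
        n = np.asarray(ring.normal, dtype=float)
        n = n / np.linalg.norm(n)
        # orthonormal in-plane basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(n @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(n, ref)
        u /= np.linalg.norm(u)
        v = np.cross(n, u)
        centroid = np.asarray(ring.centroid, dtype=float)
        k = len(names)
        angles = 2.0 * np.pi * np.arange(k) / k
        # subtract the exact vertex mean so the centroid is met to fp precision
        verts = radius * (np.outer(np.cos(angles), u) + np.outer(np.sin(angles), v))
        verts = verts - verts.mean(axis=0)
        for name, vert in zip(names, verts):
            atoms.append(
                Atom(
                    atom_index=len(atoms),
                    atom_name=name,
                    element=name[0],
                    residue_number=ring.residue_number,
                    residue_name=ring.residue_name,
                    chain_id=ring.chain_id,
                    is_heavy=True,
                )
            )
            coords.append(centroid + vert)
    return StructureModel(atoms, np.vstack(coords))


def planted_five_ring_cluster() -> tuple[StructureModel, ClusterSpec, np.ndarray]:
    """Synthetic five-ring aromatic cluster with a planted centroid
    distance matrix spanning exactly 3.9 to 9.5 Å.

    Residue numbers mirror the *D. radiodurans* cluster narrative
    (295, 302, 303, 309, 316 on one protomer); this is a constructed
    stand-in for the closed-state crystal geometry, not that structure.
    Returns (structure, cluster spec, planted distance matrix).
    """
    centroids = np.array(
        [
            [0.0, 0.0, 0.0],
            [3.9, 0.0, 0.0],
            [1.95, 4.2, 0.0],
            [5.85, 4.2, 0.0],
            [9.5, 0.0, 0.0],
        ]
    )
    resnums = [295, 302, 303, 309, 316]
    resnames = ["TYR", "PHE", "PHE", "TRP", "PHE"]
    normals = [(0, 0, 1), (0, 1, 1), (1, 0, 1), (0, 0, 1), (1, 1, 1)]
    rings = [
        RingSpec(rn, tuple(c), "A", num, normal)
        for rn, c, num, normal in zip(resnames, centroids, resnums, normals)
    ]
    structure = generate_toy_structure(rings)
    cluster = ClusterSpec(
        members=[
            ClusterMember("A", num, rn) for num, rn in zip(resnums, resnames)
        ]
    )
    diff = centroids[:, None, :] - centroids[None, :, :]
    planted = np.linalg.norm(diff, axis=2)
    return structure, cluster, planted


# ---------------------------------------------------------------------------
# MSA fixtures
# ---------------------------------------------------------------------------

DEFAULT_MSA_WINDOWS = MotifWindows({"spoon": (11, 25), "fork": (26, 40)})

_NON_AROMATIC = "ACDEGIKLMNPQRSTV"


def generate_msa_fixture(
    counts: dict[str, int],
    windows: MotifWindows = DEFAULT_MSA_WINDOWS,
    n_columns: int = 50,
    seed: int = 0,
) -> Msa:
    """Build an alignment whose aromatic-residue count inside the window
    columns equals ``counts`` for every sequence, exactly.

    The first aromatic placed in each sequence is Tyr, the rest Phe
    (echoing the Y/F/F composition of the *E. coli* cluster); all other
    columns are filled with non-aromatic residues from a seeded stream.
    """
    windows.validate(n_columns)
    window_cols = windows.columns()
    width = len(window_cols)
    rng = derive_rng(seed, "msa")
    records = []
    for rid, count in counts.items():
        if count < 0 or count > width:
            raise ValueError(
                f"count {count} for {rid!r} does not fit in {width} window "
                "columns"
            )
        row = list(rng.choice(list(_NON_AROMATIC), size=n_columns))
        if count > 0:
            # deterministic, evenly spread positions within the windows
            pos = np.linspace(0, width - 1, count).round().astype(int)
            for k, pi in enumerate(pos):
                row[window_cols[pi] - 1] = "Y" if k == 0 else "F"
        records.append((rid, "".join(row)))
    return Msa(records, n_columns)


def sixteen_homolog_fixture(seed: int = 0) -> tuple[Msa, dict[str, int]]:
    """Sixteen-homolog alignment fixture: Ec 3, Dr 5, Pa 2, Mtb 1
    aromatics in the spoon/fork windows, with exactly 9 of the 16
    sequences carrying three."""
    counts = {
        "Ec": 3, "Dr": 5, "Pa": 2, "Mtb": 1,
        "Kp": 3, "St": 3, "Vc": 3, "Yp": 3,
        "Hi": 3, "Bs": 3, "Sa": 3, "Li": 3,
        "Pf": 2, "Ab": 4, "Ng": 4, "Cj": 2,
    }
    assert sum(1 for v in counts.values() if v == 3) == 9
    return generate_msa_fixture(counts, seed=seed), counts


# ---------------------------------------------------------------------------
# Assay data generators
# ---------------------------------------------------------------------------


def generate_mm_data(
    vmax: float = 1.0,
    km: float = 50.0,
    S: Sequence[float] = (5, 10, 25, 50, 100, 250, 500),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Substrate/velocity pairs from the hyperbolic rate law, optionally
    with additive Gaussian noise.  Returns (S, v, ground truth)."""
    if vmax <= 0 or km <= 0:
        raise ValueError("Vmax and Km must be positive")
    S = np.asarray(S, dtype=float)
    v = vmax * S / (km + S)
    if noise_sigma > 0:
        v = v + derive_rng(seed, "mm").normal(scale=noise_sigma, size=v.shape)
    return S, v, {"vmax": vmax, "km": km}


def generate_melt_curve(
    tm: float = 74.0,
    slope: float = 2.0,
    amplitude: float = 18.0,
    baseline: float = -20.0,
    t_min: float = 20.0,
    t_max: float = 88.0,
    step: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """CD222-vs-temperature logistic melt.  The first-derivative maximum
    of the noiseless curve is exactly at ``tm`` (the logistic
    inflection).  Returns (Timecourse, ground truth)."""
    from .wetlab import Timecourse

    if slope <= 0:
        raise ValueError("slope must be positive")
    T = np.arange(t_min, t_max + step / 2, step)
    y = baseline + amplitude / (1.0 + np.exp(-(T - tm) / slope))
    if noise_sigma > 0:
        y = y + derive_rng(seed, "melt").normal(scale=noise_sigma, size=y.shape)
    return Timecourse(T, y, channel="CD222"), {"tm": tm, "slope": slope}


def generate_cd_timecourse(
    kind: str = "formation",
    amplitude: float = 3.6,
    rate: float = 0.05,
    baseline: float = 0.0,
    t_max: float = 780.0,
    step: float = 10.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
):
    """CD313 timecourse: exponential approach A·(1−e^(−kt)) for adduct
    formation, or baseline + A·e^(−kt) for signal depletion.
    Returns (Timecourse, ground truth)."""
    from .wetlab import Timecourse

    if rate <= 0:
        raise ValueError("rate constant must be positive")
    t = np.arange(0.0, t_max + step / 2, step)
    if kind == "formation":
        y = baseline + amplitude * (1.0 - np.exp(-rate * t))
    elif kind == "depletion":
        y = baseline + amplitude * np.exp(-rate * t)
    else:
        raise ValueError(f"unknown timecourse kind {kind!r}")
    if noise_sigma > 0:
        y = y + derive_rng(seed, "cd").normal(scale=noise_sigma, size=y.shape)
    return Timecourse(t, y, channel="CD313"), {
        "kind": kind,
        "amplitude": amplitude,
        "rate": rate,
        "baseline": baseline,
    }
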
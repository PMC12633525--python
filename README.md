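# confcouple

Conformational-coupling analysis for molecular-dynamics trajectories of
ligand-gated enzymes, with the assay-side calculations used to
characterize their variants.

The motivating system is 1-deoxy-D-xylulose 5-phosphate synthase
(DXPS), a ThDP-dependent bacterial enzyme whose mobile "spoon" and
"fork" loops close over the active site to stabilize the
pre-decarboxylation intermediate C2α-lactyl-ThDP. A conserved cluster
of aromatic residues (Tyr/Phe) in those loops is proposed to lock the
closed conformation; disrupting it opens the enzyme and degrades
catalysis. `confcouple` provides the computational half of that
analysis for any system with a slow two-state collective motion coupled
to local side-chain geometry:

* **Essential dynamics.** Kabsch superposition onto an iteratively
  refined mean structure, then PCA of the selected atoms' Cartesian
  coordinates: the covariance is C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩ (population
  normalization, unweighted), with eigenmodes e_k, eigenvalues λ_k and
  per-frame projections. The per-atom displacement along mode k is
  d_i = √λ_k · ‖(e_k)_i‖.
* **Coupling.** Ring-centroid pair-distance time series d(t), their
  Pearson correlation with the first K principal components, and 2D
  free-energy surfaces F = −k_B·T·ln(P/P_max) over pairs of collective
  coordinates, with metastable-basin detection by persistence
  flood-fill (8-connected, depth measured to the lowest saddle).
* **Cluster geometry & conservation.** Pairwise ring-centroid distance
  matrices of an aromatic cluster in a static structure (per protomer),
  and per-homolog counts of aromatic residues inside named
  alignment-column windows of an MSA.
* **Assay calculations.** ε₂₈₀ = 5690·n_Trp + 1280·n_Tyr;
  Michaelis–Menten fits v = V_max·[S]/(K_m + [S]) with Jacobian
  standard errors and the initial-slope route to k_cat/K_m; apparent
  T_m as the maximum of dCD₂₂₂/dT; band-densitometry percentages;
  iminopyrimidine CD₃₁₃ percent-change and AP-baseline normalization;
  fold-change summaries.
* **Synthetic data.** A telegraph-process trajectory generator that
  plants a slow two-state mode with designated pair correlations
  (analytic ground truth returned alongside), toy ring structures with
  exact planted centroid geometry, MSA fixtures with exact aromatic
  counts, and kinetic/melt/timecourse generators.

## Worked example

`examples/02_coupling_fes.py` plants two anti-coupled residue pairs on
a 20 000-frame two-state trajectory and recovers the coupling:

```
distance/PC correlations (r):
              PC1    PC2    PC3
PROA:9-10   0.995 -0.002 -0.009
PROA:11-12 -0.995  0.019 -0.007

basins on the PC1 vs PROA:9-10 surface (T = 310 K):
  pair distance   4.0 A   F = -0.00 kcal/mol   depth 3.92 kcal/mol
  pair distance  14.0 A   F = 0.03 kcal/mol   depth 3.89 kcal/mol

compensation score between the two pairs: -0.987
(negative: one pair opens only while the other closes)
fraction of frames with both pairs open: 0.0000 (L-shaped surface)
```

The first pair's distance tracks PC1 (r ≈ +1), the second is
anti-coupled (r ≈ −1); the free-energy surface shows the planted
closed (~4 Å) and extended (~14 Å) basins; and the negative
compensation score with an empty both-open quadrant is the half-sites
signature: one pair closes only while the other opens. The other
examples cover the PCA displacement profile (`01`), cluster geometry
and MSA conservation (`03`), and the assay calculations (`04`).

A thin CLI wraps the same functions
(`confcouple simulate|pca|coupling-style subcommands|mm-fit|melt|run`);
`confcouple run --preset coupled-demo --seed 7 --out run/` executes the
whole chain and writes CSVs plus a SHA-256 manifest, reproducible
bitwise for a fixed config.

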
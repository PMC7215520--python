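# Methods

## Scope and model

`resdyn` implements the comparative analysis layer that sits on top of
molecular-dynamics production runs: it consumes protein-only, already
unwrapped and centred trajectories (multi-model PDB, one fixed topology
per run) and computes global conformational metrics, dynamic
cross-correlation, dynamic residue networks, WT − variant Δ profiles with
a k·SD outlier screen, and binding-site consensus sets. It does not run
MD: simulation physics (force fields, thermostats, solvent) is explicitly
out of scope, and a statistically controlled generator stands in for
production trajectories wherever ground truth is needed.

## Superposition and global metrics

Best-fit superposition uses the Kabsch SVD construction with the
determinant correction that excludes reflections. Point sets with fewer
than three points, or with (near-)collinear geometry (centred coordinate
rank < 2, tolerance 1e-8), are rejected as degenerate rather than
silently resolved.

* **RMSD** is computed against frame 0 by default. The reference frame is
  a parameter because common MD toolchains differ (first frame vs energy
  minimised structure) and the original workflow does not pin it down.
* **Rg** is unweighted over the selected atoms (α-carbons by default):
  with a single-atom-per-residue selection, mass weighting would only
  rescale by a near-constant factor, and the comparative quantity is the
  percent difference anyway.
* **RMSF** superposes all frames onto an *iterated mean structure*: fit
  all frames to the running mean, recompute the mean, repeat until the
  mean moves < 1e-6 Å (max-norm) or 10 iterations. The fitting target
  matters (fitting to frame 0 inflates fluctuations far from that frame)
  and the iterated mean is the estimator-theoretic choice when the
  original fitting reference is unspecified.
* **Summary table**: per-protein means are reported at 3 decimals and
  percent differences `100·(mean_WT − mean_variant)/mean_WT` at 2
  decimals, rounded half-up to match how such tables are conventionally
  printed. An optional frame range restricts means to an equilibrated
  tail.
* **KDE**: Gaussian kernels, Scott's rule bandwidth
  (`h = σ̂·n^(−1/5)`), 512-point grid spanning `[min − 3h, max + 3h]`.
  The trapezoidal integral of every estimate is 1 within 1e-3 (the mass
  outside the grid is below kernel-tail truncation at 3 bandwidths). A
  constant series is rejected with a hint that the trajectory is static.

## Dynamic cross-correlation

`C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)` with displacements taken
about the mean position after the same iterated-mean superposition as
RMSF. Superposition defaults on: without it, rigid-body drift makes all
pairs spuriously correlated. Residues with zero fluctuation have an
undefined correlation; their rows/columns are NaN and a warning lists
them. Raw covariances (Å²) are available behind `normalized=False`.

Motion classification bins off-diagonal pairs at thresholds (−0.25,
+0.25) by default: `C ≤ lower` anti-correlated, `C ≥ upper` correlated,
open interval between them uncorrelated. The thresholds are descriptive
(they support statements like "predominantly anti-correlated") and
configurable; the boundary semantics make `(−1, 1)` select exactly the
perfectly (anti)correlated pairs.

## Dynamic residue networks

Contact graphs use all Cβ pairs (Cα for glycine) at a 6.7 Å cutoff,
inclusive boundary (`d ≤ cutoff`), no exclusion of sequence neighbours —
the common contact-map convention; both choices are flags. Per node:

* **L**: the mean BFS distance to *reachable* partners ("total shortest
  paths to the node divided by the node count less one"). A closed-form
  global variant (sum of all pairwise distances over `n(n−1)`) is exposed
  separately as `global_average_path_length`; the per-node form is what
  per-residue Δ profiles require. Isolated residues get a missing value
  and are counted per residue in the outputs.
* **BC**: raw betweenness (Brandes' algorithm via networkx), i.e. the sum
  over unordered pairs of the fraction of shortest paths through the
  node; disconnected pairs contribute zero. Test oracles recompute both
  quantities by Floyd–Warshall and exhaustive path enumeration.

Sampling every n-th frame (e.g. a 100 ps interval via
`stride = round(interval/timestep)`) reflects that network metrics are
expensive and frames are highly autocorrelated on shorter timescales.

Per-frame profiles are min–max normalised across residues within each
frame ("scaled 0 to 1"), then averaged arithmetically over frames;
per-frame normalisation (rather than pooling the whole series) keeps each
frame's ranking information and is the default, with `none` available.
A frame with a constant profile normalises to zeros with a warning. The
raw BC average is always reported alongside, since strongly central
residues are most interpretable on the raw scale.

**Outlier screen**: for a Δ profile (WT − variant), residues with
`|Δ − mean| > k·SD` (population SD, default k = 2) are listed as
increases/decreases, labelled with the comparative semantics (positive
ΔL = accessibility increase in the variant; positive ΔBC = communication
reduction; negative ΔRMSF = flexibility increase). Centring on the mean
(not zero) makes the screen robust to global offsets between runs. An SD
of zero (all Δ identical, up to float fuzz) yields an empty report with a
note.

## Binding-site consensus

Residue identity for set algebra is the residue number (predictor lists
rarely carry chains); conflicting residue names at a number warn rather
than fail. The strict intersection of predictors is the default rule, the
majority rule `k of n` generalises it (`k = 1` union, `k = n`
intersection). The package bundles the published CA-VIII consensus lists
as three positional groups whose union is the 38-residue site; annotation
queries (e.g. which variant positions lie inside) are set membership with
per-tag reporting.

## Synthetic trajectory generator

Frame `t` is
`R_t(base_{s(t)} + Σ_k a_k z_k(t) + ε(t)) + T_t`:

* **Base geometry** — `helix`: ideal α-helix Cα trace (1.5 Å rise, 100°
  turn, 2.3 Å radius); `compact_walk` (default): a 3.8 Å fixed-step walk
  confined to a sphere of radius `4.2·n^{1/3}` Å with 4.0 Å hard-sphere
  rejection, deep backtracking and deterministic restarts when trapped.
  The confinement radius gives globular contact densities at the 6.7 Å
  cutoff comparable to a folded ~290-residue protein.
* **Jitter** — isotropic Gaussian, per-residue σ per axis (default
  0.5 Å), so a factor-free residue has expected RMSF √3·σ.
* **Factors** — a factor is a signed per-residue loading `a_i` (Å) times
  an isotropic standard-normal 3-vector latent drawn i.i.d. per frame.
  This makes the pairwise DCC of two residues with loadings of magnitude
  `a` and jitter σ exactly `±a²/(a²+σ²)` in expectation — the closed form
  the DCC tests check. A scalar latent along a fixed direction would give
  `a²/(a²+3σ²)` instead; the isotropic latent was chosen so the analytic
  target is the simple ratio. Latents are i.i.d. over frames because all
  implemented estimators are invariant to frame order, so temporal
  autocorrelation would add nothing testable.
* **Rigid body** — optional uniform random rotation plus Gaussian
  translation (5 Å scale) per frame, applied to all atoms together, so
  internal geometry (and hence best-fit RMSD) is exactly preserved.
* **Two-state switching** — a second reference geometry displaces the
  trailing third of the chain by a configurable offset along the local
  side-chain direction; the active state flips with a symmetric per-frame
  probability. This produces the bimodal RMSD KDE used to validate
  multi-modal conformational sampling detection.
* **Cβ placement** — 1.53 Å from the Cα along a deterministic local
  direction (bisector away from the midpoint of the sequence
  neighbours), omitted at glycine positions, riding rigidly on its Cα.
* **Determinism** — identical config + seed gives bit-identical output.
  Variant pairs share a base geometry (a separate geometry seed) while
  drawing independent noise streams; perturbations modify σ on a residue
  block, flip factor-loading signs, or displace the base geometry.

Defaults (268 residues numbered from 23, 2000 frames at 100 ps, σ =
0.5 Å) mirror the trajectory dimensions the generator stands in for.
What the generator does **not** emulate: realistic secondary structure
beyond glycine placement, anharmonic/multi-well local dynamics (other
than the explicit two-state mode), temporal autocorrelation, and
solvent/temperature effects. Passing tests therefore demonstrate that
the estimators recover known statistical structure, not that any
biological conclusion about a real protein would be reproduced.

## Problem sizes in tests and the acceptance script

Statistical checks use the smallest sizes at which the targeted
tolerances are comfortably met: 2000 frames for RMSF recovery within
10% of √3·σ, 5000 frames for DCC within ±0.05 of the analytic ratio,
100-residue/400-frame pairs for the null-control (≤ 10% flagged at
k = 2) and perturbation-recovery screens, and ≤ 12-node graphs for the
brute-force oracle comparisons (the oracles are exponential in the
worst case). These sizes are fixed in the tests; the library itself has
no size limits beyond memory.

## Known limitations

* Multi-model PDB is the only trajectory format; binary MD formats can be
  converted upstream (e.g. with mdtraj/MDAnalysis) before analysis.
* Networks are unweighted and undirected; no community detection or other
  centralities.
* The per-node L of a disconnected graph averages over the reachable set
  only, which can make L non-monotone under edge addition when a new
  (distant) component becomes reachable — the reported missing-value
  counts should be checked when interpreting sparse frames.
* DCC is linear correlation; in-phase but orthogonal motions score zero
  (no mutual-information variant).
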
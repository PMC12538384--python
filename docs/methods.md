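# Methods

This note records the models, parameters, and numerical choices behind
`qtaimnet`, and the limitations of each.

## 1. Promolecular model density

The electron density is a promolecular model: a sum of spherically symmetric
atomic terms, each a sum of Slater-type shells,

    rho(r) = sum_A sum_k c_{A,k} * exp(-zeta_{A,k} * |r - R_A|),

with coefficients `c > 0` and exponents `zeta > 0` from a built-in per-element
shell table (H through Cl main-group elements, 3d metals Fe–Zn with a diffuse
valence shell, 4d metals Ru–Ag). All internal coordinates are bohr; XYZ files
are read and written in angstrom (conversion constant 0.52917721067 Å/bohr).

Gradient and Hessian are analytic. For a single shell with distance
`d = |r - R|`, using the softened distance `s = sqrt(d^2 + a^2)`:

    grad = -(zeta * f / s) (r - R),            f = c * exp(-zeta * s)
    hess = (zeta^2 f / s^2 + zeta f / s^3) (r-R)(r-R)^T - (zeta f / s) I

with `a = 0` (no softening) everywhere except at nuclei (below). Evaluating
exactly on a nucleus with `a = 0` raises `DegenerateEvaluationError`; the cusp
makes the derivatives undefined there.

**Limitation.** A promolecular density has no charge relaxation, no covalent
redistribution, and no spin density; it is a stand-in chosen so that every
topological quantity has a closed form or cheap numerical oracle. Absolute
descriptor values are not comparable to DFT densities; only the machinery and
the relative contrasts (tier perturbations, ligand-field effects) carry over.

## 2. Critical-point search and classification

Critical points (CPs) of `rho` are found by Newton–Raphson from geometric
seeds:

* nuclei (nuclear CPs are placed analytically, see below);
* midpoints of all atom pairs within a 5 Å cutoff;
* centroids of triangles and tetrahedra of atoms that are pairwise within
  the same cutoff.

Newton iterations (at most 80, step clipped at 0.5 bohr) converge when
`|grad rho| <= grad_tol = 1e-10`. Converged points are rejected if they leave
the molecular bounding box (margin 6 bohr) or land within 0.3 bohr of a
nucleus; duplicates within 1e-3 bohr are merged keeping the smaller gradient
norm. CPs are classified by the signs of the Hessian eigenvalues; an
eigenvalue within `rank_tol = 1e-10` of zero makes the CP degenerate, which is
reported, excluded, and warned about rather than guessed at.

**Seeding choice.** Pair midpoints are taken for *all* pairs within the
cutoff, not only plausibly bonded pairs: a promolecular density places
(3,−1) saddles between non-bonded atoms too, and missing those saddles breaks
the Poincaré–Hopf count. This is deliberately more generous than covalent-
radius-based seeding.

**Nuclear cusp.** The exponential cusp makes the true Hessian singular at a
nucleus. Nuclear CPs are therefore placed exactly at the nuclei with
`rho` evaluated exactly, `|grad rho|` defined as 0 (the cusp is a non-smooth
maximum), and curvature taken from the cusp-softened density
(`s = sqrt(d^2 + a^2)`, `a = soften_radius = 0.05` bohr), which yields a
finite, triply degenerate negative curvature and the correct (3,−3)
signature.

## 3. Bond paths

From each bond CP, two steepest-ascent trajectories are launched at
`±0.01 bohr` along the eigenvector of the positive Hessian eigenvalue and
integrated with fixed-step gradient ascent (step 0.01 bohr, adaptive halving
when `rho` fails to increase, at most 10 000 steps). A trajectory terminates
on entering the 0.1 bohr capture radius of a nucleus, which is appended as
the endpoint. The bond path is the polyline nucleus–CP–nucleus; its arc
length is the summed segment length. Failed ascents are counted and reported,
never silently dropped.

The Poincaré–Hopf relation `n − b + r − c = 1` is computed for every
topology; violations produce a warning and are surfaced in the result record.

## 4. Descriptors

Thirteen scalars per CP, from `rho` and the sorted Hessian eigenvalues
(λ1 ≤ λ2 ≤ λ3): rho, |grad rho|, Laplacian, Hessian determinant, the three
eigenvalues, ellipticity `λ1/λ2 − 1`, `eta = |λ1|/λ3`, the Abramov kinetic
energy density `G = (3/10)(3π²)^{2/3} ρ^{5/3} + (1/6)∇²ρ` (the `|∇ρ|²` term
vanishes at a CP), the virial potential `V = ¼∇²ρ − 2G`, the total energy
density `H = G + V`, and `|V|/G`. Ratios with vanishing denominators are NaN
sentinels, imputed explicitly during featurization (zero fill plus an
indicator column), never raised and never silently replaced.

## 5. Synthetic complexes, tiers, and labels

A synthetic complex places a metal at the origin and `n_ligands` main-group
atoms by rejection sampling on the radial shell 3.5–5.5 bohr with a minimum
interatomic separation of 2.2 bohr. Datasets have exact round-robin charge
and metal marginals. All randomness is counter-based
(`np.random.SeedSequence((root_seed, stage, item))`), so every object is
reproducible in isolation.

Two *tiers* emulate levels of theory: the high tier is the parent complex;
the low tier multiplies every shell exponent by `1 + u`,
`u ~ U(−ε_ζ, ε_ζ)`, and optionally jitters positions by `N(0, ε_geo²)`.

Labels are linear in pooled CP descriptors plus a charge term. The default
rule is

    y = 3.0 * mean(bond ellipticity) + 1.0 * mean(bond rho)
        + 0.3 * mean(nuclear rho) + 1.0 * charge  (+ optional Gaussian noise).

The ellipticity dominance is deliberate: bond-CP density is largely
inferable from the bond arc length, and nuclear density from element
identity, but the ellipticity of a bond in a promolecular density is created
entirely by the surrounding ligand field. It is therefore a signal that only
a density-topology-aware featurization can see, which is what the
QTAIM-on/QTAIM-off experiment arms are designed to contrast.

## 6. Level-of-theory comparison statistics

Tiers are matched by molecule id; CPs by atom index (nuclear) or sorted
endpoint pair (bond). Per descriptor, the discrepancy statistic is the median
over matched CPs of `|log10 max(|a|, ε) − log10 max(|b|, ε)|` with
`ε = 1e-12`; pairs with opposite signs are excluded from the median but
counted (a signed log ratio is undefined, and the Laplacian legitimately
changes sign between tiers). Connectivity robustness is summarized by the
histogram of per-molecule absolute bond-path-count differences and
`percent_within(k)`.

## 7. Heterographs and the GNN

Each molecule becomes a typed graph with atom, bond(-CP) and one global node;
edges are bond–atom incidence in both directions plus star edges between
every node and the global node (so every graph is connected even with no bond
CPs). Atom features: element one-hot + Z (+ 13 nuclear-CP descriptors when
QTAIM features are on); bond features: arc length (+ 13 bond-CP
descriptors); global: charge, spin, atom count, molecular weight. Features
are z-scored with statistics fit on the training split only; constant
columns are dropped and recorded; NaN sentinels become zero plus an
indicator column.

The network is a typed message-passing network built on an in-package
reverse-mode autodiff over numpy/scipy (no deep-learning framework is
available in the environment):

* linear per-type input embeddings into a shared hidden width;
* `rounds` residual message-passing rounds, `h ← h + relu(W_self h +
  W_msg agg + W_glob g)`, with mean aggregation over typed incidences;
* mean or attention pooling over atoms and bonds (set2set is omitted: it
  requires an LSTM, adds hand-rolled-framework risk, and is exercised by no
  experiment here);
* readout = linear skip from the pooled representation **plus** a small relu
  MLP. The explicit linear path is what lets the model recover exactly
  linear label mechanisms without fighting the nonlinearity.

Training uses decoupled weight decay (AdamW-style), mini-batches over a
disjointness-checked train/val split, z-scored labels, early stopping on
validation loss with best-state restoration, and is bit-reproducible for a
fixed seed. Typical settings for the synthetic recovery experiments:
hidden 16, 1 round, lr 0.01, weight decay 0.1–0.2, batch 512, up to 1000–1500
epochs. Weight decay matters: without it the network interpolates the small
training sets (train loss ~1e-18) and generalizes poorly.

Metrics: MAE, RMSE, R² (NaN when the target has zero variance), and
EwT% (errors within a threshold, default 0.0434 in label units).

## 8. Experiment protocols

Splits: `random` (seeded shuffle, fractions 0.8/0.1/0.1), `charge_ood`
(train on neutral, test on ±1, other charges excluded), `element_ood`
(train on molecules with all Z ≤ 36, test on the rest). All splits conserve
the dataset: train + val + test + excluded is an exact partition. Learning
curves use nested training subsets (smaller sets are prefixes of larger ones
per seed) against a fixed test set. OOD experiments train a QTAIM-on and a
QTAIM-off arm on the identical split and additionally report extreme-outlier
counts (|error| > 5·MAD).

`experiments.replication_report` recomputes bond-path agreement percentages
and charge-OOD split sizes from deposited large-scale tier tables
(`labels.csv`, `bond_counts_<tier>.csv`); it runs only when those external
tables are present under `data/tmqm_plus/`.

## 9. Numerical tolerances

| Quantity | Tolerance | Rationale |
| --- | --- | --- |
| CP gradient norm at convergence | 1e-10 | Newton converges quadratically; this is far below any descriptor's sensitivity |
| Degenerate-eigenvalue threshold | 1e-10 | relative to O(1) curvatures in bohr units |
| CP dedup radius | 1e-3 bohr | two Newton basins converging to one CP |
| Descriptor identities (H = G + V etc.) | 1e-12 | pure floating-point algebra |
| Ellipticity at a symmetric diatomic | 1e-6 | limited by Newton convergence and eigen-decomposition, not by algebra |
| Analytic vs. finite-difference gradient | rel. 1e-6 (h = 1e-5) | central differences at well-conditioned points |
| Analytic vs. finite-difference Hessian | rel. 1e-5 (h = 1e-4) | second differences lose ~eps/h² to cancellation; a blanket 1e-6 is not attainable for Hessians in double precision |
| Log-ratio floor in LOT statistics | 1e-12 | keeps log10 defined for underflowing descriptors |

## 10. Limitations

* The density is promolecular; nothing here validates against real
  wavefunction or cube-file densities, and no atomic-basin integration
  (charges, volumes) or non-nuclear attractor handling is implemented.
* The GNN stack is a minimal numpy implementation: CPU only, dense within
  node types, no dropout/normalization layers, no set2set pooling. It is
  adequate for hundreds of molecules, not tens of thousands.
* Synthetic labels are linear in pooled descriptors by construction; results
  quantify *recoverability of known signal*, not predictive power on real
  chemistry.
* The full-scale replication statistics require external data tables that
  cannot ship with the repository; the computation is implemented and
  unit-tested on miniature tables only.
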
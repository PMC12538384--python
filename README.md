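# qtaimnet

Electron-density topology (QTAIM), critical-point descriptors, and
heterograph neural networks for molecular property prediction — with a fully
synthetic, download-free test bed.

## What this package does

The Quantum Theory of Atoms in Molecules (QTAIM) characterizes a molecule by
the topology of its electron density: maxima at nuclei, (3,−1) saddle points
("bond critical points") between bonded atoms, ring and cage critical points,
all tied together by the Poincaré–Hopf relation `n − b + r − c = 1`. Scalars
evaluated at those critical points — density, Laplacian, ellipticity, kinetic
and potential energy densities — are compact, physically interpretable bond
descriptors.

`qtaimnet` implements the full pipeline:

1. **Model densities** (`qtaimnet.density`) — analytic promolecular densities
   (sums of Slater shells) with exact gradients and Hessians.
2. **Topology extraction** (`qtaimnet.topology`) — Newton–Raphson critical
   point search from geometric seeds, Hessian-signature classification,
   steepest-ascent bond-path tracing, Poincaré–Hopf verification.
3. **Descriptors** (`qtaimnet.descriptors`) — 13 scalars per critical point,
   including the Abramov kinetic energy density and the virial-based
   potential/total energy densities.
4. **Synthetic data** (`qtaimnet.synthetic`) — deterministic toy
   transition-metal complexes, *tier pairs* emulating two levels of theory,
   and labels that are known linear functions of QTAIM descriptors, so every
   downstream stage has a ground truth.
5. **Level-of-theory robustness** (`qtaimnet.lot`) — median absolute log10
   descriptor ratios and bond-path-count agreement between matched tiers.
6. **Graphs + GNN** (`qtaimnet.graphs`, `qtaimnet.gnn`) — atom/bond/global
   heterographs with optional QTAIM features, and a typed message-passing
   network with mean/attention pooling, built on an in-package numpy
   autodiff (no deep-learning framework required).
7. **Experiments** (`qtaimnet.experiments`) — random / charge-OOD /
   element-OOD splits, nested learning curves, and two-arm
   (QTAIM-on vs QTAIM-off) comparisons.

See `docs/methods.md` for models, parameters, numerical tolerances, and
limitations.

## Worked example

A symmetric diatomic with one unit Slater shell per atom
(`rho = e^{-d_1} + e^{-d_2}`, nuclei 4 bohr apart):

```python
import numpy as np
from qtaimnet.density import AtomSite
from qtaimnet.topology import build_topology
from qtaimnet.descriptors import attach_descriptors

atoms = [AtomSite(0, "C", np.zeros(3), shells=((1.0, 1.0),)),
         AtomSite(1, "C", np.array([4.0, 0.0, 0.0]), shells=((1.0, 1.0),))]
topo = build_topology(atoms)
print(topo.counts, topo.poincare_hopf)
bond = attach_descriptors(topo)["bond"][0]
print(bond["rho"], bond["ellipticity"], bond["G_kinetic"])
```

prints

```
(2, 1, 0, 0) 1
0.2706705664732254 0.0 0.3251896...
```

i.e. two nuclear CPs, one bond CP, Poincaré–Hopf satisfied; the bond-CP
density matches the closed form `2 e^{-2} = 0.270671` exactly, the
ellipticity vanishes by symmetry, and the bond path arc length is 4.000000
bohr. (At this particular separation and exponent the Laplacian at the bond
CP happens to be exactly 0: the axial curvature `2e^{-2}` cancels the two
transverse curvatures `-e^{-2}` each.)

A random synthetic complex goes through the same machinery:

```python
from qtaimnet.synthetic import generate_complex
cx = generate_complex(seed=42, n_ligands=5)
topo = build_topology(cx.atoms)
print([a.element for a in cx.atoms], topo.counts, topo.poincare_hopf)
```

```
['Fe', 'F', 'Cl', 'F', 'O', 'O'] (6, 6, 1, 0) 1
```

— an Fe center with 5 ligands: 6 nuclear CPs, 6 bond CPs, 1 ring CP,
`6 − 6 + 1 − 0 = 1`.

The same is available from the command line:

```bash
qtaimnet generate --n 20 --seed 1 --out scratch/demo      # XYZ + labels.csv
qtaimnet analyze --geoms scratch/demo --out scratch/an    # CPs + descriptors
qtaimnet topology --xyz scratch/demo/synt-000001-00000.xyz --out scratch/t.json
```

plus `generate-tiers`, `compare-lot`, `featurize`, `split`, `train`,
`evaluate`, `learning-curve`, and `ood` for the full pipeline
(`qtaimnet --help`).

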
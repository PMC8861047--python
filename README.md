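# placemol

Conditional autoregressive generation of 3d molecular structures.

`placemol` implements a generative neural model that builds molecules atom by
atom in Euclidean space, conditioned on target properties — scalar
electronic properties (e.g., a HOMO-LUMO gap or a relative atomic energy),
1024-bit path fingerprints, or atomic compositions.  It is aimed at inverse
molecular design: instead of screening structures and computing their
properties, you specify property values and sample 3d candidate structures
that exhibit them with high probability.

## The model

A molecule is a tuple of positions **R**≤n and types **Z**≤n.  Given k target
conditions Λ, the model factorizes the conditional distribution
autoregressively,

    p(R≤n, Z≤n | Λ) = Π_i p(r_i, Z_i | R≤i−1, Z≤i−1, Λ),

splitting each factor into *type first, then position*.  The positional
factor is never parameterized in absolute coordinates; it is reconstructed
from predicted distributions over the **pairwise distances** between the new
atom and every already-placed atom,

    p(r_i | R≤i−1, Z≤i, Λ) = (1/α) Π_j p(r_ij | R≤i−1, Z≤i, Λ),

evaluated on a grid of candidate positions around a *focus* atom, which
makes generation exactly invariant under rotation and translation.  Two
auxiliary tokens steer the process: an *origin* token at the center of mass
(inside-out growth) and a *focus* token marking the atom next to which the
new atom must be placed.  A *stop marker* type lets the model retire atoms
one by one and terminate, so molecules of variable size and composition are
sampled without specifying either in advance.

Atom-wise features come from a SchNet-style continuous-filter convolution
network (invariant to rigid motion); conditions are embedded per property
(Gaussian radial basis for scalars, MLP for vectors, fraction-weighted type
embeddings for compositions) and aggregated into a conditioning vector that
both output heads consume.  Training minimizes cross-entropy between
predicted type/distance-bin distributions and ground truth along sampled
atom-placement trajectories (2n supervised steps for an n-atom molecule).
Generated structures are filtered for valency and connectivity via bond
perception, and deduplicated by canonical SMILES with mirror images
(enantiomers) identified.

The network, including training, runs on a small numpy reverse-mode
autodiff that ships with the package — there is no deep-learning framework
dependency.

## Worked example

Train a tiny model on toy carbon chains whose only condition is the chain
length, then ask it for molecules of length 4:

```bash
placemol make-fixtures --outdir fx --n-toy 48
cat > chain.yaml <<'YAML'
preset: tiny
chemical_types: [6, 8]
conditions:
  - {name: length, kind: scalar, lam_min: 2.0, lam_max: 9.0, d_omega: 1.0,
     length: 0, type_order: [], g_dim: 8, widths: [16, 16]}
train_data: fx/toy.xyz
val_data: fx/toy.xyz
properties: fx/toy_properties.tsv
seed: 1
training: {batch_size: 5, lr: 0.001, max_epochs: 40, seed: 2,
           neighbor_mode: radial, neighbor_cutoff: 1.6}
YAML
placemol train --config chain.yaml --outdir run
placemol generate --checkpoint run/best.npz --n 20 --condition length=4 \
    --seed 3 --max-atoms 12 --grid-spacing 0.1 --outdir gen
placemol filter --input gen/generated.xyz --outdir gen/report
```

The train step prints, e.g.

```
trained 40 epochs; best validation loss 1.6385; checkpoint at run/best.npz
```

(the loss is the mini-batch objective: average per-step type cross-entropy
plus twice the average distance cross-entropy — its floor is the entropy of
the Gaussian-expanded targets, not zero), and the generate/filter steps end
with

```
wrote 20 structures to gen/generated.xyz
20/20 valid, 4 unique
```

`gen/manifest.tsv` lists one row per sample with its size and termination
status; after longer training than this 40-epoch demo the sizes concentrate
on the requested length 4.

## Library surface

```python
import placemol as pm

ds = pm.load_qm9("path/to/qm9")                  # eV-converted properties
train, val, test = pm.split_dataset(ds, 55_000, 50_000, 5_000, seed=0)
base = pm.fit_energy_baseline(train, "U0")       # per-element baseline
rae = pm.relative_atomic_energy(ds[0], base, "U0")
rep = pm.validate_structure(ds[0])               # valency + connectivity
key = pm.canonical_key(ds[0])                    # enantiomer-safe SMILES key
```

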
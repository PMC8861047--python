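# Methods

This note documents the model, the procedures, the tunable parameters, the
synthetic-data generator, and the numerical and design choices made where the
design was genuinely open.  It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model

**Factorization.**  The joint distribution of an n-atom structure given k
condition values Λ is factorized autoregressively over atoms; each factor
splits into the next type (a categorical over the chemical vocabulary plus a
stop marker) and, given the type, the next position.  The positional
distribution is reconstructed from per-predecessor *distance* distributions:
for a candidate point r′, the unnormalized mass is the product over all
preceding atoms and tokens j of the predicted probability of the bin
containing ‖r_j − r′‖, normalized over a candidate grid.  Because only
distances enter, the construction is exactly equivariant under rigid motion.

**Tokens.**  Two auxiliary pseudo-atoms are prepended to every partial
structure: the origin token (center of mass during training, the coordinate
origin during generation) and the focus token (co-located with the atom the
next placement must neighbor).  Both are embedded and featurized exactly
like atoms; they contribute rows to the type-head average and factors to the
positional product, but no probability factors of their own.

**Representation.**  Atom-wise features are produced by a SchNet-style
network: a learned embedding per type code followed by interaction blocks
whose filters are generated from Gaussian-expanded pairwise distances with a
smooth cosine cutoff; self-interactions are excluded.  Internal details
beyond "F features, N interaction blocks" (filter-network widths, radial
basis count, cutoff) are configuration, since they are not fixed by the
model class.

**Conditioning.**  Scalars are expanded on a Gaussian radial basis with
centers λ_min + lΔω for 0 ≤ l ≤ (λ_max−λ_min)/Δω and width Δω, then passed
through a small MLP.  Values outside [λ_min, λ_max] are accepted without
clamping — the basis decays smoothly, which is what permits targeting
property values beyond the training range.  Vectors (e.g., 1024-bit path
fingerprints) feed an MLP directly.  Compositions weight learnable
per-element embeddings by element *fractions* and concatenate them in a
fixed global element order; the total atom count is deliberately carried by
a separate scalar condition, so the composition block is size-free.  The
per-condition features are concatenated in declared order and aggregated by
an MLP into y ∈ R^D.

**Heads.**  The type head maps every feature row concatenated with y to
scores over the type classes, softmaxes per row, and averages the row-wise
softmaxes uniformly (token rows included — they are treated like ordinary
atoms throughout).  The distance head gates each row with a learnable
embedding of the already-sampled next type (Hadamard product), concatenates
y and softmaxes over L distance bins of width Δμ; bin b(d) =
⌈(d + Δμ/2)/Δμ⌉, with an overflow bin beyond (L−1)Δμ.

## Trajectories

A training molecule is converted to a 2n-step supervised sequence: the
first placement is the atom closest to the center of mass (ties uniform);
every later step focuses a uniformly drawn unfinished placed atom and
places its unplaced neighbor closest to the center of mass, or supervises
the stop marker and retires the focus if no unplaced neighbor exists.
Neighborhood is bonds when perception succeeds, otherwise a radial cutoff
(3 Å default).  A fresh sequence is drawn per molecule per epoch.  The
center of mass is mass-weighted (standard atomic weights); the unweighted
centroid is available but not the default, as the choice is not forced by
the model.

## Training

Per step, the type loss is the negative log-probability of the true next
type; on placement steps the distance loss is the mean over preceding rows
of the cross-entropy between the predicted bin distribution and a
normalized Gaussian expansion of the true distance over the bin centers
(width parameter γ = 10/Δμ by default).  A batch of M sequences is scored
as (1/M) Σ_m Σ_a [ℓ_type/|A_m| + δ(a)·ℓ_dist/(0.5|A_m|)] with δ = 0 on stop
steps.  Log arguments are clamped at 1e-12; early training can hit empty
bins.  Optimization is Adam (default schedule: lr 1e-4, halved after 10
epochs without validation improvement, stop at lr ≤ 1e-6, mini-batches of
5); validation sequences are drawn once with a fixed seed so model
selection compares like with like, and the lowest-validation-loss snapshot
is returned.  Gradients are computed by the package's own reverse-mode
autodiff; a finite-difference check is part of the acceptance suite.

## Generation

Both tokens start at the coordinate origin.  Each step re-draws the focus
uniformly among unfinished atoms (the origin stands in before the first
placement), samples the type from the averaged type distribution, and — for
chemical types — samples the position from the grid reconstruction: a cubic
lattice clipped to a sphere, centered on the focus (spacing 0.05 Å, radius
1.7 Å by default; the radius must cover first-neighbor bond lengths since
training always places atoms adjacent to the focus).  Products over up to
~36 rows of small bin probabilities are accumulated in log space with
max-subtraction before normalization.  Sampling is the exact normalized
categorical over grid points — no temperature, no top-k.  Generation stops
when every atom is retired; attempting to place more than `max_atoms`
(default 35) aborts the sample, which is then marked unfinished.

## Validity and uniqueness

Bond perception from raw coordinates uses RDKit's distance-based
connectivity plus neutral bond-order assignment.  Two special cases: (i)
aromatic rings of carbon/nitrogen can defeat plain order assignment, so a
rescue pass marks all-C/N 5- and 6-rings aromatic and accepts the structure
if a valence-consistent kekulization exists (structures rescued this way
are flagged on the bond graph); (ii) pure-hydrogen structures (H2) break
the order solver and fall back to van-der-Waals connectivity with single
bonds.  Validity then requires the summed integer bond orders to equal the
fixed neutral valences (H 1, C 4, N 3, O 2, F 1; configurable) for every
atom, and a single connected component.  Uniqueness keys are canonical
SMILES computed from the perceived graph with stereochemistry assigned from
the 3d coordinates; the key is the lexicographic minimum over the structure
and its mirror image, so enantiomer pairs collide by construction.  A
non-isomeric variant (stereo descriptors dropped) classifies generated
structures that share a reference bonding pattern but differ in
stereochemistry as novel stereoisomers.

## Data and conditioning properties

The QM9 reader parses the per-molecule extended-XYZ dialect (15-field
property line, tab or space separated, tolerating the `*^` exponent quirk)
and converts energetic fields from Hartree to eV (1 Ha = 27.211386 eV) on
ingestion — every threshold this package works with is in eV.  Dataset
splitting removes structures failing the validity check first, applies any
exclusion predicate to the pool candidates only (excluded molecules remain
in the test remainder), then draws the pool uniformly under a seed.

The *relative atomic energy* is implemented as the residual of an ordinary
least-squares fit of molecular energy onto per-element atom counts (no
intercept), divided by the atom count — negative values mean more stable
than the per-element baseline predicts.  A per-element linear baseline was
chosen because the quantity must generalize across compositions, including
compositions absent from training.  Note the exact residual identity: the
atom-count vector lies in the design's column space, so Σ rae·n² = 0
exactly on the fitting split, while the plain mean of rae is only as small
as the noise.

Path fingerprints are the toolkit's linear-path fingerprint (paths of up to
7 atoms, 1024 bits) on the perceived bond graph, so conformers of one graph
map to identical bit vectors; Tanimoto similarity is |a∧b|/|a∨b| with the
all-zero pair defined as 1.

## Synthetic data and the desk-scale study

Full-scale training (50k QM9 molecules, F = 128, 9 interaction blocks,
tens of GPU-hours) is far outside a verification run, so the package ships
a fixed desk-scale study on synthetic data (`placemol.experiments`,
exercised by `tests/test_acceptance.py` and `scripts/acceptance.py`).

The toy generator builds chains, rings and tetrahedra at an idealized
1.5 Å bond length with optional coordinate noise and per-element synthetic
energies.  It emulates exactly what the mechanism tests need — connected
structures with unambiguous neighborhoods, sizes and compositions
correlated with attached condition values — and none of what real data
adds: no chemical diversity, no conformational flexibility, no
property–structure relationships beyond the constructed ones.  Passing the
desk-scale study therefore demonstrates that the machinery is correct
(distributions normalized and invariant, trajectories contractual,
gradients exact, conditioning effective in a regime a tiny model can
master); it does not demonstrate chemical accuracy on real molecules.

Fixed choices in the study:

* **Toy network preset.**  F = 16 features, 2 interaction blocks, 120
  distance bins of 0.1 Å, D = 16.  The interaction cutoff is 12 Å rather
  than the full-size default of 5 Å: with only two blocks the receptive
  field is two cutoffs, and stop decisions need whole-structure
  information, so the cutoff must span the largest toy chain (~10.5 Å).
  The full-size preset achieves global coverage through depth (9 blocks)
  instead.  Toy runs train with Adam at lr 1e-3 (staged down to 3e-4);
  the conservative full-scale schedule starting at 1e-4 remains the
  default of `TrainingConfig`.
* **Overfit-and-regenerate.**  Five chains C_{n−1}O (n = 3…7), conditioned
  on composition and atom count, trained with a fixed staged schedule
  (250/200/150 epochs at lr 1e-3/3e-4/1e-4) deep into the overfit regime —
  the batch loss must end below 25% of its initial value, and in practice
  lands near 21–24% (the floor is the entropy of the Gaussian-expanded
  distance targets, not zero) — then 200 samples conditioned on the first
  molecule's composition.  The compositions were designed with pairwise
  distinct element-fraction profiles: the composition embedding sees
  fractions only, so two compositions with equal fractions (e.g., C3O3 and
  C2O2) are indistinguishable to it by construction and would make the
  target ill-posed.  Match rates decrease with chain length — an n-atom
  molecule needs 2n correct type decisions, so per-step errors compound —
  which is why the designated regeneration target is fixed a priori as the
  first (smallest) training molecule.
* **Size control.**  72 training + 12 validation noisy carbon chains
  (lengths 3–8, σ = 0.01 Å) in a balanced design — equally many chains per
  length, so the stop statistics are not hostage to a lopsided random size
  draw — with the chain length as the only (scalar) condition; staged
  training (200 epochs at lr 1e-3, 80 at 3e-4), then 500 samples per
  target length.  This is the study's slowest experiment (a few minutes on
  one CPU).  Generation uses a 0.1 Å grid spacing
  (radius 1.7 Å) rather than the 0.05 Å default purely for speed; the
  spacing only discretizes the position draw.
* **Gradient check.**  Central differences at ε = 1e-6 against the
  autodiff gradients, with an absolute floor of 1e-4 in the relative-error
  denominator: at the loss scale of the probe, round-off limits the
  difference quotient to ~1e-10, so smaller gradients cannot be resolved
  (wrong gradients would still surface as order-one relative errors).

## Numerical choices

* Softmaxes and cross-entropies route through a stable `logsumexp`
  primitive; explicit probability logs are clamped at 1e-12.
* Grid masses are accumulated in log space with per-point max subtraction;
  an all-`-inf` mass vector raises a sampling error rather than returning
  NaNs.
* Ties (closest atom to the center of mass, equally near unplaced
  neighbors) break uniformly at random under the caller's seeded
  generator; all randomness flows through explicit `numpy` generators, and
  every generated sample is reproducible from (seed, sample index).
* The shifted softplus is computed as `logaddexp(0, x) − ln 2`, exact in
  both tails.

## Known limitations

* Bond perception and canonical SMILES depend on the perception toolkit
  and its version; counts of "valid" structures on real corpora shift
  accordingly.  The aromatic C/N rescue is a reimplementation of the idea,
  not a port of any particular published heuristic.
* The desk-scale study trains tiny models on toy geometry; it bounds
  mechanism correctness, not chemical quality.  Conditional control
  degrades for the largest toy structures (compounding of per-step type
  errors), and the reported match/mean statistics fluctuate a few percent
  across seeds.
* No DFT or force-field relaxation, no property-prediction networks, no
  charged or open-shell species; valences are fixed neutral values.
* Training is single-process and dense-matrix; the full-size preset is
  implemented and runs, but training it to the quality reported for
  GPU-scale models is outside the package's intended use.
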
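# Methods

## The model

The package scores a protein–ligand binding pose by asking a statistical
question: *how much more likely are the observed residue–atom distances
under this pose than under a non-interacting reference?*  A pose is
represented as a heterogeneous complex — protein residues at residue level,
ligand atoms and metal ions at atom level — and reduced to the set of
residue–atom minimum distances d_ij (the minimum over the residue's heavy
atoms of the Euclidean distance to ligand atom j) and metal–atom distances
d_kj, restricted to pairs within a cutoff (default 9 Å).

**Distance likelihood (NMDN score).**  For each pair, the concatenated
residue and atom embeddings pass through a deep MLP (five blocks of linear
→ batch-norm → ReLU → dropout; hidden width 4096 in the full-size
configuration, much smaller in the desk-scale configurations used by the
tests) and three linear readouts that parametrize a Gaussian mixture over
the distance:

    p_ij(r) = Σ_n ρ_ijn N(r | μ_ijn, σ_ijn)

Mixture weights go through a softmax; standard deviations through a
softplus with floor σ_min = 0.01 Å (both maps are modelling choices — only
the mixture-density structure itself is fixed).  Training minimises the
negative log density at the observed distance, summed over all pairs
within the training cutoff, for protein–ligand and metal–ligand heads
separately (identical architectures, different input widths).

At inference the raw likelihood is normalized into a statistical
potential.  The reference probability of a pair is the average predicted
density over six points spanning the 0.5 Å below the reference distance
(with the default reference of 9.0 Å: {8.5, 8.6, …, 9.0}); averaging six
points rather than evaluating one stabilises the normalizer.  The per-pair
score is the log ratio

    score_ij = ln p_ij(d_ij) − ln p_ref_ij

and the pose score is the sum over all pairs within the test cutoff.  A
pair whose observed density equals its reference density contributes
exactly zero; pairs beyond the cutoff are never enumerated and contribute
exactly zero.  A plain-ratio variant is available behind a flag
(`log_ratio=False`) for comparison.  Training and test cutoffs are
independent settings (both default 9 Å, reference distance defaults to the
test cutoff).

**Affinity head (pKd score).**  Binding affinity is predicted as a sum of
pair contributions plus a solvation correction.  Each distance is expanded
in 64 radial basis functions on the exponentially transformed distance,

    g_k(d) = exp(−β_k (e^{−d} − μ_k)²) · φ(d),

with centers initialized equally spaced in [e^{−10}, 1], widths initialized
to the constant that makes adjacent Gaussians overlap at half maximum
(β₀ = ln2 / (Δ/2)², Δ the center spacing), and a quintic smooth cutoff
φ(d) = 1 − 6x⁵ + 15x⁴ − 10x³, x = d/d*, d* = 10 Å, which is 1 at contact,
0 beyond d*, and C¹ at both ends.  Both centers and widths are learnable
(widths kept positive through a softplus).  The residue and atom embeddings
are passed through shifted-softplus (SSP(x) = ln(eˣ+1) − ln 2) then linear
maps to width 128; the RBF vector through a linear map to width 128; the
three branches combine by Hadamard product.  The protein–ligand readout
concatenates this 128-dim hidden state with a 64-entry RBF expansion of the
ligand's MMFF-RMSD feature (192 inputs total) and maps to a scalar PL_ij;
the metal–ligand readout maps the 128-dim hidden state directly (no RMSD
feature).  Two further linear readouts on the hidden state give pairwise
solvation coefficients whose means over the protein–ligand pairs within
9 Å, α_gw and α_wo, weight the ligand's transfer free energies:

    pKd = Σ PL_ij + Σ ML_kj + α_gw·ΔG_gas→water + α_wo·ΔG_oct→water

If no protein–ligand pair falls within the cutoff the coefficients are
defined as zero and a warning is emitted.  The affinity loss is the batch
MAE; joint training uses w_nmdn·(L_PL + L_ML) + w_pkd·L_pKd with both
weights defaulting to 1 (the relative weighting is a free choice).

**Weak-binder screening variant.**  To keep predictions honest on
non-binders, a fine-tuning objective replaces the MAE for weak-binders
(measured activity worse than 10 μM) with the hinge
max(pred − label − 1.0, 0): predictions up to one log-unit above the
measured value are free, anything higher is penalised linearly.  This
fine-tuning updates the affinity head only; the density heads and
featurizer stay frozen.

## Inputs and encoders

Protein structures are read from PDB (biotite); alternate locations
resolve to the highest-occupancy conformer, waters and non-metal
heteroatoms are dropped, single-atom HETATM records whose element is in
the configurable metal list (default Zn, Mg, Ca, Mn, Fe, Ni, Cu, Co, K,
Na) become metal ions, and non-standard amino acids are kept with code
"X".  Residue–atom distances use protein heavy atoms only (crystal
structures usually lack hydrogens); ligand hydrogens are included by
default since H is part of the atom vocabulary — both behind flags.
Ligand poses come from multi-record SDF (RDKit), with the element
vocabulary restricted to H, B, C, N, O, F, P, S, Cl, Br, I; a pose with
other elements is rejected with a diagnostic (configurable to skip so a
screening run continues).

Embeddings are consumed through a provider contract: either precomputed
arrays from a keyed archive (NPZ or HDF5, groups `protein/<id>`,
`ligand/<id>`, `metal/<id>`, any width — a residue protein-language-model
embedding is typically 1280-wide) or the built-in baseline featurizer.
The baseline uses a frozen lookup over amino-acid type for residues
(mirroring the convention that the pretrained residue encoder is not
fine-tuned), a trainable element lookup plus a linear refinement over
invariant local geometry for ligand atoms, and a trainable element lookup
for metals.  Because all geometric inputs are pairwise distances, every
score is invariant under rigid motions and atom relabeling by
construction; the test suite verifies this to 1e-6.

The neural layers, reverse-mode automatic differentiation and the Adam
optimizer are implemented in numpy inside the package (`nmdn.autodiff`,
`nmdn.nn`); a directional finite-difference check against the analytic
gradient of the combined loss guards the implementation.

## Synthetic data: what it emulates and what it does not

The generators produce three kinds of fixtures, all pure functions of
their parameters and a seed:

* **Geometric toys** (`gen_complex`): a compact ligand blob with residues
  placed so each residue is either within the cutoff of every ligand atom
  or outside it for all of them, making the expected within-cutoff pair
  fraction equal the requested fraction (default 0.7).  Used for parser,
  pair-enumeration and invariance tests.
* **Planted-mixture complexes** (`gen_mixture_complex`): ligand atoms
  spaced 30 Å apart so each residue forms exactly one pair whose distance
  is an exact draw from a known per-(amino-acid, element) two-component
  Gaussian mixture (component means 2–7 Å, σ 0.35–0.8 Å, ≥1 Å mean
  separation).  These planted densities are the ground truth for
  parameter recovery (KL between truth and the learned conditional
  density, by quadrature) and for pose ranking (one native-like pose with
  mixture-drawn distances against decoys with uniform distances;
  the oracle ranking uses the true mixtures through the same
  normalization).
* **Screening and affinity fixtures**: score tables with a controllable
  active/inactive separation (separation 0 gives enrichment factor 1 in
  expectation), and affinity labels from a planted rule
  pKd* = Σ w(class)·e^{−d/2} + 0.4·ΔG_gw + 0.25·ΔG_wo + 4, which a
  correctly wired affinity head must recover to < 0.2 MAE on held-out
  complexes.

These fixtures deliberately do not emulate force-field geometry, real
binding-site chemistry, pose-generation error modes, or the label noise of
experimental affinities.  Passing tests therefore demonstrate that the
machinery is correct — densities normalized, scores decomposable and
invariant, recoverable from data generated by the model family — not that
the defaults reach any particular accuracy on real complexes, which
depends on the pretrained encoders and training corpus supplied by the
user.

## Evaluation metrics and the selection protocol

`screening_metrics` implements the standard evaluation battery: enrichment
factor in both top-fraction and fixed-false-positive-rate conventions
(both appear in the literature; top-fraction is the default), docking
success rate (any of the top-k scored poses within an RMSD threshold,
default 2 Å, plus the median top-1 RMSD), Pearson/Spearman scoring and
ranking powers with a ligand-count-weighted per-target average, and
symmetry-aware ligand RMSD (minimised over graph automorphisms, computed
without superposition since docked poses share the protein frame).

The combined two-score selection takes the top 0.5% of ligands under each
score, merges them, and — while the union holds fewer than 1% of the
library — appends the next-ranked unselected ligand from each score
alternately (distance-likelihood score first; the alternation order is a
convention).  On libraries under 200 ligands the one-ligand-per-score
minimum can exceed the 1% target, in which case the minimum wins.  All
ranking ties break by stable order with ligand/pose id as the
deterministic secondary key.

The end-to-end protocol consumes externally generated poses (one SDF per
protein–ligand pair, arbitrary order; the default configuration expects
10 poses per pair): every pose is scored, the top-1 by distance-likelihood
score is selected, and the affinity head runs on the selected pose.  Pose
generation itself is out of scope by design — the file contract decouples
the scorer from any particular docking engine.

## Numerical choices and problem sizes

* All arithmetic is float64; mixture log densities use log-sum-exp, so the
  NLL is finite even far in the tails.
* Batch norm uses batch statistics during training and frozen running
  estimates at inference; all reported scores are eval-mode and
  deterministic.  Dropout defaults to 0.1 for full-size training and is
  disabled in the small recovery configurations.
* Optimizer: Adam, lr 1e-4 by default (recovery experiments use 1e-3 to
  2e-3); these are implementation defaults, not derived quantities.
* The recovery experiments are sized for a single CPU: 5,000 distance
  samples per class (2,500 eight-pair complexes), a width-64 five-layer
  head with 5 mixture components trained for 60 epochs (~40 s); the
  affinity recovery uses 240 training complexes for 150 epochs (~30 s);
  pose ranking uses 200 systems of 4 poses.  KL is estimated by
  trapezoidal quadrature on a 0.05–14 Å grid (step 0.005 Å).
* Ties in pose selection resolve to the lexicographically first pose id;
  input order never affects any metric.

## Known limitations

* The pretrained residue/atom/metal encoders are not bundled; with the
  baseline featurizer the density heads can only condition on amino-acid
  type, element and coarse local geometry.  Real discriminative power
  requires user-supplied embeddings through the archive contract.
* The solvation free energies and MMFF-RMSD are inputs; the package ships
  an MMFF94-based RMSD utility but no solvation predictor.
* mmCIF input, protonation, bond perception beyond SDF content and
  biological-assembly expansion are out of scope.
* The full-size configuration (hidden width 4096, 10 components) is
  supported but not exercised by the test suite, which runs reduced
  widths throughout.
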
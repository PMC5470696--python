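# Methods

`predsav` predicts whether a single amino acid variant (SAV) is
disease-associated (+1) or neutral (−1) from the local environment of the
mutated residue in the wild-type 3-D structure. The pipeline has three
stages: neighborhood feature encoding, two-step feature selection, and a
gradient-tree-boosting (GTB) classifier. This note records the model, its
assumptions, the tunable parameters, and the design choices made where the
procedure was genuinely open.

## Structure model

PDB files are parsed into a single-chain list of residues with heavy-atom
(non-hydrogen) coordinates. Only the 20 canonical amino acids are kept;
selenomethionine (MSE) is read as methionine, other modified residues are
dropped with a warning. For atoms with alternate locations the first-listed
altloc is kept — deterministic and close to common practice; occupancy
weighting would change coordinates by fractions of an Å and none of the
features downstream are that sensitive. Residues are addressed internally
by `seq_index`, a 0-based contiguous index along the parsed chain; author
numbering (with insertion codes) is kept for reporting and for variant
tables, which address residues the way publications do. A variant whose
stated wild-type amino acid disagrees with the structure is flagged and
still encoded, on the view that the pipeline should surface rather than
silently drop bookkeeping errors.

A residue's representative point is the unweighted centroid of its heavy
atoms (an alpha-carbon alternative is available via `center_mode="ca"`).
The centroid follows the reading that the representative point lies "among
the atoms" rather than on the backbone, and it makes the contact network
and the tessellation consistent with each other.

## Neighborhood feature encoding

Each variant is described by three blocks built from a per-residue table of
B base features (B = 117 by default, standing in for external predictor
outputs such as PSSM columns, predicted accessibility, disorder, energy
scores):

* **Sequence window** (11·B values): the base rows at chain offsets −5 … +5
  around the variant residue, zero-filled beyond the termini. Zero-filling
  keeps the dimensionality fixed without borrowing interior statistics for
  terminal residues.
* **Euclidean neighborhood** (B values): for each base feature, the sum of
  that feature over all residues whose *minimum heavy-atom distance* to the
  variant residue is ≤ 5 Å. The defining sum is ambiguous about whose score
  is summed; we sum the **neighbors'** scores, consistent with the Voronoi
  block and with the stated purpose of describing the residue's
  environment. The literal center-score reading (center score × neighbor
  count) is available via `euclidean_semantics="center_times_m"`. The
  sequence-separation condition |r−n| ≥ 1 is read minimally: only the
  residue itself is excluded; chain neighbors are eligible.
* **Voronoi neighborhood** (B values): the same sum over residues sharing
  at least one Voronoi facet between their heavy atoms — computed as
  atom-level Delaunay adjacency (an edge of the tessellation joining an
  atom of one residue to an atom of the other), lifted to residues. No
  distance cap is applied by default, since the definition is purely
  facet-sharing; note that convex-hull edges can join distant residues.

With B = 117 and window 11 the encoded vector has 1287 + 117 + 117 = 1521
features, named `seq[{offset:+d}]:{base}`, `euc:{base}`, `vor:{base}`.

Degenerate point sets (coplanar/co-spherical) make the tessellation
ill-defined; the default is to raise an error, with an opt-in deterministic
jitter of 1e-6 Å seeded from the structure id. Erroring by default was
chosen over silent perturbation for reproducibility.

## Contact network features

A residue-contact graph joins residues whose centroids lie within 6.5 Å.
Eight per-residue descriptors are computed: degree, clustering coefficient,
betweenness (raw dependent-pair counts, unnormalized — within a fixed graph
the scale is monotone and irrelevant to tree learners), closeness
((n_c−1)/Σd within the node's component), eccentricity and eigenvector
centrality computed per connected component (avoiding infinities on
disconnected graphs), k-core number, and average nearest-neighbor degree.
The eigenvector is the principal adjacency eigenvector per component,
entries made positive and L2-normalized; singleton components get the
trivial unit entry. These conventions are fixed for determinism; numeric
equality with any particular network tool's normalization is not claimed.

## Four-body pseudo-potential

The Delaunay tessellation of residue centroids partitions a structure into
tetrahedra; each tetrahedron's vertices form an unordered amino acid
quadruplet. Over a corpus of structures the potential of a composition is

    Q = ln (f + ε) / (p + ε)

with f its observed fraction among tetrahedra, p its multinomial
expectation (4!/Π c_t!)·Π a_t^{c_t} from the corpus residue-type fractions
a_t, and ε a pseudocount defaulting to 1/(2·total tetrahedra) so unseen
compositions stay finite. The natural log is used (any base is a constant
scale for learning). Tetrahedra are treated as a single type; an optional
typing by sequence separation is deliberately not enabled, as no principled
partition was required by the downstream features. A per-residue mean-Q
column (mean over incident tetrahedra) is exposed as an optional base
feature; it is not part of the default 117-column contract.

## Two-step feature selection

**Step 1 — stability selection.** Each of `n_resamples` (default 200)
rounds draws ⌈n/2⌉ variants without replacement, multiplies each
standardized feature column by an independent factor ~ U[weakness, 1]
(weakness 0.5), and fits a lasso on the ±1 labels along 10 log-spaced
penalties from the subsample's critical penalty α_max down to α_max/10; a
feature is "selected" in a round if its coefficient is nonzero anywhere on
the path. A feature's score is its selection fraction; features with score
strictly greater than the cutoff (0.2) survive. The resample count,
subsample fraction, weakness and penalty path are not pinned by the
procedure's description; the defaults follow standard randomized-lasso
practice and are all configuration-exposed. The penalty floor of α_max/10
keeps per-round selections sparse so that scores discriminate (a much
smaller floor would let nearly everything enter at the path's end).

**Step 2 — sequential forward selection (SFS).** Starting from the empty
set, every remaining candidate is scored by the pooled out-of-fold AUC of
the GTB learner under a stratified 5-fold partition that is fixed for the
whole run (paired comparisons across candidates reduce evaluation
variance). The first pick is the unconditional argmax — any feature beats
the empty, chance-level model — and each later argmax is accepted only if
it improves the AUC strictly (min_gain 0, "until the AUC no longer
increases"); ties break toward the higher stability score, then the
lexicographically smaller name. During selection the learner uses 200
trees rather than the final 2000: selection needs the *ordering* of
candidate subsets, not calibrated absolute AUCs, and the ordering is stable
at the smaller size.

If no feature clears the stability cutoff (e.g. on signal-free data), the
pipeline falls back to the 20 best-scoring features as SFS candidates
rather than failing, with a warning.

## Gradient tree boosting

The classifier is Θ_M(χ) = Θ₀ + Σ_m ν·γ_m(χ) fitted by functional gradient
descent on the logistic loss L(y, Θ) = log(1 + exp(−yΘ)), y ∈ {−1, +1}:

* Θ₀ = argmin_c Σ L(y_i, c) = log(n₊/n₋) (the training log-odds under this
  loss; the class probability is σ(Θ) and labels threshold at probability
  0.5, ties predicting +1);
* each iteration fits a least-squares regression tree of depth ≤ 3 to the
  negative gradient r_i = y_i σ(−y_i Θ(χ_i));
* each leaf value is one Newton step on the logistic loss over the leaf's
  training points, γ = Σ r_i / Σ |r_i|(1−|r_i|) — the standard estimator of
  the per-leaf line search, which has no closed form;
* updates are shrunk by ν = 0.1 (the conventional default; the procedure
  description leaves it at "default parameters").

Defaults are 2000 trees of depth 3. Tree induction is delegated to
scikit-learn's regression trees (seeded, so equal-gain splits break
deterministically); the boosting loop, initialization, gradient and Newton
leaf updates are implemented in this package, and a test checks AUC
agreement within 0.02 against an independently implemented boosted
classifier configured identically. No stochastic subsampling is used.
Models persist as versioned JSON (metadata plus flat tree arrays) and
round-trip predictions bit-identically.

## Evaluation

Sensitivity, specificity, precision, F1, accuracy and Matthews correlation
are computed from the confusion counts; zero denominators return 0 and are
flagged rather than propagating NaN. AUC is the Mann–Whitney pair
statistic with midranks for ties, which equals the trapezoidal ROC area.
Cross-validation is stratified and seeded; both the unweighted fold-mean of
each metric and the pooled out-of-fold AUC are reported, since either
averaging convention is defensible and they differ slightly.

**Selection leakage.** Following the original protocol, feature selection
is performed once on the full dataset and the selected set is then
cross-validated (on a fresh fold partition). With far more features than
variants this estimate is *optimistic when no real signal exists*:
spuriously label-correlated features survive selection and lift the
subsequent CV of the selected set well above chance even on
permutation-destroyed labels. `nested_pipeline_auc` therefore re-runs the
entire pipeline
(stability selection, SFS, GTB) inside each training fold and scores only
the untouched fold; this estimate is unbiased and sits at chance level
(≈ 0.5) under label permutation. The nested estimate is what the
permutation controls in the test suite and the acceptance script use; the
non-nested CV is still reported as the protocol's own headline number.

## Synthetic data

The generator produces an idealized α-helix (rise 1.5 Å, 100°/residue,
radius 2.3 Å) with N/CA/C/O plus one pseudo side-chain atom per residue,
jittered by seeded Gaussian noise (σ = 0.05 Å) to guarantee general
position. A helix was chosen over a random coil because it reproduces
realistic local packing density at the 5 Å neighborhood and 6.5 Å contact
cutoffs. The ideal consecutive-CA chord is 3.83 Å; with the jitter,
individual CA–CA distances scatter ≈ ±0.2 Å around it.

Labeled datasets plant a class-mean shift (default 2.0, in units of the
noise sd) on a chosen subset of base features (default 5 of 117), with
balanced ±1 labels over 400 variants. For the end-to-end benchmark each
variant's base row is expanded to a per-residue table (shared class shift,
fresh residue-level noise) and run through the full encoding on a
60-residue helix, so all three feature blocks inherit the signal. What
passing tests on this benchmark show is that the machinery recovers a known
planted signal at a realistic dimensionality; they do not show that any
particular set of real predictor outputs separates disease from neutral
variants, nor do the synthetic helices reproduce tertiary contacts,
loops/sheets, or sequence–structure compatibility.

## Problem sizes and numerics

The test suite and the acceptance script run the planted-signal benchmark
at 400 variants × 1521 encoded features with 100 stability resamples for
score rankings, 200 trees during SFS and 2000 in the final model; the
leakage-free permutation control uses 2-fold nesting with the SFS capped at
3 features per fold (the cap bounds the greedy search's cost and does not
bias the out-of-fold AUC). Ten generator seeds are used where a claim is
about seed-to-seed reliability. Tolerances: geometric oracles compare
exactly or at 1e-8; the Mann–Whitney/trapezoid identity at 1e-12; the
multinomial normalization at 1e-10. Degenerate inputs (single-class
labels, zero-variance features, empty neighbor sets, disconnected contact
graphs, < 4 points for tessellation) either have a defined convention
(documented above) or raise early with a named cause.

## Known limitations

* Features are computed on the wild-type structure only; the mutant enters
  only through whatever mutant-aware columns the base table supplies.
* The 117 base features are a user-supplied contract, not a recomputation
  of the external predictors; column semantics are the user's
  responsibility.
* The non-nested CV headline is optimistic in the absence of signal (see
  above); for model comparison on real data, use `nested_pipeline_auc`.
* Single chain, single model; no biological-unit expansion or mmCIF input.
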
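# Methods

This note documents the models and procedures implemented in `cancerlect`,
the parameter choices that matter, the design decisions taken where the
design was genuinely open, and the limits of what the synthetic-data tests
demonstrate.

## Problem and data model

The task is binary classification of protein sequences: cancerlectins
(positive) versus other lectins (negative). Sequences are strings over the
20 canonical amino-acid letters; records carrying ambiguity codes or rare
residues (B, J, O, U, X, Z, `*`) are excluded whole rather than cleaned,
because every descriptor below indexes the strict 20-letter alphabet and a
partially dropped sequence would silently change every length-normalized
feature. Exclusions are reported per record with a reason
(`non-canonical residue` or `too short for descriptor parameters`), and
the counting identity `kept + excluded = input` is maintained.

Length filtering enforces the mathematically necessary minimum: a
lag-parameterised descriptor with λ or nlag = 30 requires L > 30, so the
pipeline filters at `min_length = 31` before extracting those families.
There is no maximum-length rule; none of the implemented descriptors has
one.

## Descriptor families

All families are deterministic functions of the sequence and fixed
property tables (`cancerlect.physchem`).

* **AAC / DPC / skip-grams.** Residue, adjacent-pair, and gapped-pair
  frequencies. The k-skip bigram family counts ordered pairs at gaps
  0..k and aggregates them into a single 400-vector normalized by the
  total pair count; gap aggregation (rather than per-gap concatenation)
  is used so that the dimension is 400 for every k, and skip = 0 reduces
  exactly to DPC.
* **Conjoint triad (CTF).** Residues map to 7 classes clustered by dipole
  and side-chain volume: {A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K},
  {D,E}, {C}. Triad counts over all L−2 windows are divided by L−2, so the
  343-vector is a frequency distribution. Simplex normalization was chosen
  over the min–max rescaling some CTF variants use because a frequency
  reading is exactly testable (non-negativity, unit sum) and
  length-independent.
* **Pse-AAC (type 1).** λ = 30 correlation factors from the mean squared
  difference of standardized hydrophobicity (Tanford), hydrophilicity
  (Hopp–Woods), and side-chain mass; weight w = 0.05; the 20+λ = 50
  components share the denominator Σf + wΣθ and sum to 1. Properties are
  standardized to zero mean and unit variance over the 20 residues
  (population variance, denominator 20).
* **Amphiphilic Pse-AAC (type 2).** 2λ correlation terms — the mean lag
  products of standardized hydrophobicity and of hydrophilicity
  separately — with w = 0.5, giving 20+2λ = 80 components. Product terms
  can be negative, so only the shared normalization (not a simplex
  constraint) holds.
* **Autocorrelations.** Normalized Moreau-Broto (Σ PᵢPᵢ₊d / (L−d)), Moran
  (lag covariance over population variance), and Geary (half mean squared
  lag difference over sample variance) over 8 standardized AAindex
  properties (CIDH920105, BHAR880101, CHAM820101, CHAM820102, CHOC760101,
  BIGC670101, CHAM810101, DAYM780201) and 30 lags → 240 components each.
  When a property is constant along a sequence its variance is zero up to
  rounding; terms with variance ≤ 1e-12 are defined as 0 so homopolymers
  are processable instead of raising.
* **Sequence-order coupling numbers and quasi-sequence-order.**
  τ_d = Σᵢ dist(Aᵢ, Aᵢ₊d)² for d = 1..30, per distance matrix. Two
  matrices are used: the **Grantham** amino-acid difference matrix,
  computed exactly from Grantham's composition/polarity/volume formula
  (weights 1.833 / 0.1018 / 0.000399, scale 50.723 — this reproduces the
  published integer table to rounding), and a **synthetic physicochemical
  distance matrix** built as the Euclidean distance over the standardized
  Pse-AAC property triple. The latter is a constructed stand-in for the
  Schneider–Wrede matrix of the classical quasi-sequence-order
  formulation, whose 400 entries are not redistributable here; it plays
  the same structural role (a physicochemical residue-pair distance) but
  its values are this package's own. SOCN is the raw τ vector (2 × 30);
  QSO divides 20 composition terms and 30 weighted order terms (w = 0.1)
  by the shared denominator so each 50-block sums to 1.
* **188-dimension physicochemical set.** 20 AAC components plus, for each
  of 8 three-group alphabet partitions (hydrophobicity, normalized van der
  Waals volume, polarity, polarizability, charge, surface tension,
  secondary structure, solvent accessibility): 3 group compositions, 3
  between-distinct-group transition frequencies (divided by L−1), and 15
  distribution values — the positions of the first, 25 %, 50 %, 75 %, and
  last occurrence of each group as percentages of L, with the q-quantile
  occurrence taken as the ⌈q·n⌉-th of the group's n occurrences and 0 for
  absent groups. 20 + 8×21 = 188.

Default λ, nlag, and weights are the values under which the families'
dimensions take their conventional published sizes (50, 80, 240, 60, 100);
all are overridable per call and per CLI flag.

Feature names are `<family>.<component>` (`ctf.3_1_5`, `pseaac.theta7`,
`qso.grantham.tau12`) so concatenated tables keep unambiguous headers.

## Tables and serialization

`FeatureTable` holds ordered unique feature names, an n × d float matrix,
optional 0/1 labels (1 = positive = cancerlectin), and column provenance.
ARFF output declares one numeric attribute per feature and a final nominal
`class {0,1}` attribute; unlabelled tables write `?`. Only this dialect is
accepted on read (sparse/string/date attributes are rejected with a line
number) — the reader is a consumer of the pipeline's own files, not a
general ARFF library. Floats are serialized with shortest-round-trip text,
making write∘read the identity.

## SMOTE

Synthetic minority rows are `x + u·(x_nn − x)` with u ~ U[0,1] and x_nn one
of the k = 5 nearest minority neighbors (Euclidean, raw feature values) of
minority row x. Parents cycle deterministically through the minority rows
— one synthetic row per parent per 100 % of rate — so rate 100 exactly
doubles the minority class: 178/226 → 356/226 = 582. Original rows are
preserved verbatim and first. Balancing is applied to training folds only;
evaluation folds and supplied test sets are never resampled, so evaluated
row counts are invariant to balancing.

## MRMD

Each feature receives `relevance + distance`: relevance is the absolute
Pearson correlation of the column with the 0/1 label (0 for constant
columns); distance is the mean Euclidean distance between the
min–max-scaled column and every other scaled column, divided by the
largest such mean so both terms live in [0,1]. Cosine and Tanimoto
distances are selectable alternatives. Ties rank by original column order.
Selection keeps the top-m ranked columns in original order; `m = "auto"`
sweeps every rank prefix and scores it by 10-fold cross-validated
random-forest accuracy, keeping the smallest m that attains the maximum.
The auto sweep costs d model fits per fold and is intended for tables that
have already been reduced.

## Classifiers and evaluation

* **Random forest**: 100 trees, ⌊log₂ d⌋+1 candidate features per split,
  unlimited depth, seeded.
* **RBF-SVM**: `c` and `g` tuned by exhaustive grid search over
  c = 2^i (i = −5..15 step 2) × g = 2^j (j = −15..3 step 2) — 110 pairs —
  scored by pooled stratified 5-fold CV accuracy; ties break toward
  smaller c, then smaller g (prefer stronger regularization; keeping the
  first-found winner would make the result depend on iteration order).
  An SVM trained without an explicit g uses g = 1/d and logs it; 1/d is
  the canonical default for this kernel, and the alternative sometimes
  quoted (1 over the positive-class count) is noted as a discrepancy
  rather than implemented.
* **Evaluation**: stratified 10-fold cross-validation with confusion
  counts pooled over folds (every row predicted exactly once, so accuracy
  has an exact n denominator — the majority baseline on a 178/226 table
  scores exactly 226/404 = 55.9406 %), or a supplied labelled test set
  scored in one pass. Sensitivity, specificity, and MCC are derived from
  the same counts.

## Synthetic data generator

The generator emulates the study conditions the classifier targets: 178
positive / 226 negative training sequences, 20/20 test, lengths uniform on
100–600 residues, i.i.d. uniform background composition. Two independent
signal knobs:

* **Motifs** (order-sensitive signal): positive sequences receive one
  instance of *each* configured consensus motif, placed uniformly within
  disjoint L/k segments so instances never overwrite each other, with 5 %
  per-position substitution noise. Consensi use the bracketed-alternative
  syntax motif-discovery tools print; `X` positions draw from the
  background. The defaults are two degenerate lectin-like consensi of
  widths 50 and 41. Planting every configured motif (rather than sampling
  one) reflects how conserved blocks co-occur within a protein family and
  is what makes the order signal recoverable at these class sizes; a
  single sampled motif is obtained by configuring a one-element motif
  list.
* **Composition shift** (composition signal): the positive background adds
  δ = 0.02 to each hydrophobic residue's probability (C, L, V, I, M, F, W)
  and renormalizes.

With both knobs at their defaults, conjoint-triad features + random forest
reach ≥ 0.90 10-fold CV accuracy; with both at zero the classes are draws
from one distribution and accuracy stays inside the 99 % binomial band
around the majority fraction. These two calibration facts are asserted in
the test suite at the full 404-row scale.

What the simulation does **not** emulate: phylogenetic correlation between
sequences (real lectins are a homologous family, not i.i.d. draws),
realistic background composition, domain architecture, or the actual
motif content of curated cancerlectins. Passing tests therefore
demonstrate that the pipeline recovers signal it is pointed at and stays
calibrated in its absence — not that any particular accuracy will be
achieved on curated databases, whose headline numbers require the original
data and are out of scope here.

## Reproducibility

All stochastic stages (simulation, SMOTE, fold shuffling, forest training)
take explicit seeds. The pipeline runner fans one global seed out to
per-stage seeds through a fixed SHA-256 derivation, writes every
intermediate artifact, and records each file's digest in a manifest;
re-running a config reproduces the report bit-identically.
`scripts/acceptance.py --seed N --out results.json` recomputes the
headline quantities (descriptor dimensions, SMOTE bookkeeping, majority
baseline, strong-signal and null CV accuracies) from scratch at 404
training rows.

## Known limitations

* The Schneider–Wrede stand-in matrix changes SOCN/QSO values relative to
  tools that bundle the original matrix (dimensions and normalization
  identities are unaffected).
* Which 8 autocorrelation properties the conventional web servers use is
  not standardized; a different property set changes autocorrelation
  values but not their count or contracts.
* MRMD's published description leaves the distance variant and stopping
  rule open; the implementation declares its formula (validated against a
  brute-force oracle) rather than matching any particular binary's output.
* `mrmd_select(m="auto")` is O(d) model fits per fold — quadratic overall
  in wide tables — and is meant for post-reduction refinement at small d.
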
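# Methods

## Feature model

A PSSM is an L×20 real matrix p<sub>i,j</sub>; internally columns are always
in canonical alphabetical amino-acid order (A C D E F G H I K L M N P Q R S
T V W Y), remapped from PSI-BLAST's native output order at parse time so
that column index j has one fixed meaning everywhere. The parser consumes
the log-odds block of `-out_ascii_pssm` dumps by default (the standard
choice for PSSM-derived features); the weighted-percentages block is
selectable with `block="percentages"`. Parsed values are used raw — no
sigmoid or rescaling — so the features below are covariances on the
log-odds scale.

The ACC transform computes, per lag g = 1..λ, the lag-g auto-covariance of
every column and the lag-g cross-covariance of every ordered column pair,
each centered by the column's own full-sequence mean and divided by L−g
(no Bessel correction, no variance normalization — these are covariances,
not correlations). Layout is lag-major; within a lag, AC follows canonical
column order and CC runs lexicographically over ordered pairs (j1, j2),
j1 ≠ j2. Consequences worth knowing:

- adding a constant to a column changes nothing (mean-centering removes it);
- scaling the matrix by s scales every feature by s²;
- λ must satisfy 1 ≤ λ ≤ L−1; the default λ = 1 (400 features) reflects the
  finding that deeper lags add little signal for EC-class prediction at a
  multiplied cost.

Non-standard residues (B, Z, X, U) are tolerated with a warning: their PSSM
rows are ordinary score rows and the transform reads only matrix values.

## Classifiers

All four classifiers share one neighbor search: brute-force Euclidean
distances, ties at equal distance broken by ascending training index
(deterministic). Euclidean on raw ACC features is the default metric; an
optional z-score standardization is deliberately absent by default so that
the covariance scale semantics of the features are preserved. k defaults to
10 for the multi-label classifiers and 1 for IB1.

- **IB1** — majority vote among the k nearest single-label neighbors; vote
  ties break to the lowest class index.
- **MLkNN** — per label j, prior P(H_j) = (s + n_j)/(2s + n) and
  neighbor-count conditionals P(c | H_j), P(c | ¬H_j) estimated on the
  training set with each sample's own row excluded from its neighborhood,
  Laplace-smoothed with s = 1 (the algorithm's published default). The
  score is the two-hypothesis posterior; assignment is score > 0.5
  (strictly greater — a score of exactly 0.5 is not assigned).
- **BRkNN** — score is the fraction of the k neighbors carrying the label;
  if no label clears 0.5 the single top-scoring label is assigned (lowest
  index on ties), because an enzyme always has at least one class.
- **IBLR-ML** — per label, a logistic regression (L2-regularized,
  deterministic lbfgs fit) over the m neighbor label-fraction meta-features,
  computed leave-one-out on the training set. A label constant across
  training data gets no model; its score is the empirical prior clipped to
  (0.01, 0.99).

## Ensemble rules

Per sample, over a stack of member classifiers: the mean rule averages
scores; the majority rule assigns a label iff strictly more than half of
the members assign it (the strict reading of majority voting); the top-K
rule averages only the K largest member scores per label. Score rules are
thresholded at 0.5 with the same single-top-label fallback. The TOP3 preset
is top-K with K = 3. For the majority rule the reported score is the vote
fraction, so downstream ranking metrics remain defined.

## Metrics

Per-label confusion counts feed accuracy (TP+TN)/n, precision, recall and
F; zero denominators yield 0 (conservative, standard in multi-label
suites). Macro aggregates average the indicator over labels; micro applies
it to summed counts. Example-based average precision ranks each sample's
labels by descending score — ties broken by ascending label index via a
stable sort — and averages the true-label prefix densities; samples with no
true label are excluded with a logged count (the per-sample normalizer is
otherwise undefined). The report also exposes the exact-match ratio, since
"accuracy" in multi-label work can mean either the macro binary accuracy or
subset accuracy; both are computable from one report.

## Cross-validation protocol

K-fold CV (default 5 folds, shuffled with the run seed) with out-of-fold
predictions pooled into a single n×m score/bipartition pair before the
metric suite runs — the WEKA/MULAN evaluation convention; per-fold reports
are also returned. Fold assignment depends only on (n, folds, seed,
stratify), never on features. Plain random folds are the default; an
optional label-powerset stratification handles small unbalanced sets.
Dataset redundancy reduction (e.g. CD-HIT at threshold 0.65, word length 5)
belongs upstream of this toolkit and is not executed by it.

## Synthetic data generator

The generator emulates the inputs the pipeline consumes, not real
evolutionary profiles: L×20 Gaussian background noise (sd `noise_sd`,
default 1) with L uniform on [50, 120] (the short end of real protein
lengths; keeps the default test runs fast), m = 6 labels, and per-sample
label cardinality drawn from {1: 0.7, 2: 0.25, 3: 0.05} — matching the
1–3-labels-per-enzyme structure of curated EC annotations, where most
enzymes are monofunctional.

Each label owns a disjoint group of ⌊20/m⌋ columns. Because ACC features
are invariant to constant column shifts, a flat mean offset would be
invisible downstream; the class signal is therefore a positionally
modulated offset: active groups receive class_shift·(1 + 0.5·z_i) with z a
stationary AR(1) latent series (coefficient `ar_coeff`, default 0.6, unit
marginal variance) shared across the group's columns. The group mean still
shifts by `class_shift`, and the group's lag-g auto- and cross-covariances
gain 0.25·class_shift²·ar_coeff^g — signal the AC and CC features carry.
With class_shift = 0 profiles are pure background, indistinguishable across
labels. One integer seed drives everything: profile i uses the stream keyed
(seed, i), label assignment a separate keyed stream, so outputs are
bit-reproducible.

What passing tests on this generator do **not** show: real PSSMs have
integer-quantized, heavy-tailed, strongly position-dependent scores, class
signal spread over many correlated columns rather than disjoint groups, and
label frequencies far from uniform. The generator demonstrates that the
pipeline recovers covariance-structured class signal end-to-end; it is not
evidence about accuracy on Swiss-Prot-scale data.

## Numerical and degenerate-input conventions

- PSSM round-trip: the ASCII writer prints full float precision, so
  write→parse is exact; the percentages block it emits is zero-filled.
- All smoothed MLkNN probabilities lie strictly inside (0,1) by
  construction; posteriors are computed directly from the two-hypothesis
  Bayes ratio without log-space tricks (k+1 ≤ a few dozen bins, no
  underflow risk).
- Profiles shorter than λ+1 are rejected by name; k ≥ n is rejected.
- EC label encoding accepts `d[.d[.d[.d]]]` strings, ';' or ',' separated;
  a first digit outside 1–6 is an error naming the offending ID (the
  six-class scheme predates EC class 7, translocases).

## Design choices that were genuinely open

- Which ASCII block to featurize: log-odds (chosen) vs percentages
  (exposed as a flag).
- CC pair ordering and lag-major layout: unambiguous, documented, and fixed
  by the `feature_names` contract.
- Whether CV should stratify: default off (plain shuffled folds), since the
  protocol this mirrors does not state stratification; the flag exists for
  small unbalanced datasets.
- The end-to-end null condition compares the no-signal pipeline's average
  precision to the label-prior ranking baseline computed on the same truth
  matrix, rather than to an absolute constant — the prior baseline is what
  an uninformed ranker achieves and is itself dataset-dependent.

## Known limitations

- Brute-force neighbor search is O(n²) in memory/time; fine for the
  thousands-of-samples scale this targets, wrong for much larger corpora.
- IBLR-ML's meta-learner sees only neighbor label fractions, not raw
  features (by definition); with k small its meta-feature space is coarse.
- The PSI-BLAST configuration that produced a profile (database, iteration
  count, E-value) is not recoverable from the ASCII dump and materially
  affects features; profiles being compared should come from one
  configuration.
- `parse_ascii_pssm` accepts the standard `-out_ascii_pssm` dialect only;
  binary ASN.1 PSSMs are out of scope.
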
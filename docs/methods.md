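# Methods

## Problem and model

N6-methyladenosine (m6A) is the most abundant internal mRNA modification;
mapping it experimentally at single-nucleotide resolution is laborious, so
sequence-based prediction of methylatable adenosines is a standard
complement. `m6avote` classifies 51-nt RNA windows centered on a candidate
adenosine (the central, 26th residue) as methylated (`m6A`) or not
(`non-m6A`). Coordinates are 1-based on the given sense strand; reverse
complements are never scanned, because the mark lives on single-stranded
transcripts.

The classifier is an ensemble of three support vector machines, each seeing
the same window through a different representation:

1. **PseDNC + RBF SVM.** The pseudo dinucleotide composition concatenates
   the 16 dinucleotide frequencies f_k with lambda tier correlation factors

       theta_j = (1/(L-1-j)) * sum_i Theta(D_i, D_{i+j}),
       Theta(Da, Db) = (1/v) * sum_u [P_u(Da) - P_u(Db)]^2,

   over the v = 3 nearest-neighbor thermodynamic properties of RNA
   dinucleotides (enthalpy, kcal/mol; entropy, cal/(mol*K); free energy,
   kcal/mol), each standardized to mean 0 / SD 1 over the 16 dinucleotides
   before use (the entropy unit mismatch is irrelevant after
   standardization). The combined vector is

       d_k = f_k / (1 + w * sum theta),          k <= 16,
       d_{16+j} = w * theta_j / (1 + w * sum theta),

   non-negative and summing to 1. Defaults lambda = 6, w = 0.9;
   `optimize_psednc_params` re-derives them by 10-fold CV over
   w in {0.1..1.0} and lambda in {1..10}. Two raw property rows coincide
   (GG=CC and AC=GU), so Theta vanishes on those pairs by construction.

2. **Discriminative substrings + linear SVM.** Every substring with length
   in [4, 12] occurring in training sequences of exactly one class is a
   Boolean presence feature. The lower bound 4 is the method's defining
   parameter; the upper cap of 12 is ours — without it, whole 51-nt
   training windows become single-use features (`max_len=51` restores the
   uncapped reading). By default a substring is dropped when a shorter
   contained substring already separates the classes (`minimal_only`),
   since on the training data the superstring's presence implies the
   substring's. The vocabulary is an explicit object passed to the
   encoder, so held-out sequences can never leak into mining.

3. **Gapped k-mer string kernel SVM.** Each length-l word contributes one
   count to each of its C(l,k) gapped k-mers (k informative positions,
   l-k wildcards); the kernel is the inner product of count vectors,
   computed sparsely for Gram matrices and by the equivalent
   Hamming-distance closed form sum C(l-m, k) for single pairs. Defaults
   l = 10, k = 6. Matrices are cosine-normalized (unit diagonal) before
   SVM training with a precomputed kernel.

**Voting.** V_i = sum_k w_k * [pre(C_k) = class_i]; the predicted class
maximizes V_i. Weights are uniform by default (the configuration under
which the three-voter analysis below applies); an alternative policy sets
w_k proportional to each classifier's in-training CV accuracy, with ties
broken deterministically toward the largest-weight classifier. For three
independent classifiers of equal accuracy q in (0.5, 1), majority voting
achieves 3q^2 - 2q^3 > q (since q(2q-1)(q-1) < 0), which is the rationale
for the ensemble: individually ~70%-accurate, mutually diverse views.

## Training and evaluation choices

- SVM kernels per view: RBF for PseDNC (smooth low-dimensional
  compositional features), linear for the sparse high-dimensional Boolean
  motif vectors, precomputed normalized gkm kernel for the string view.
- Hyperparameters are grid-searched inside the training fold only:
  C over 2^-5..2^15 (powers of 4) for all three, gamma over 2^-15..2^3
  (powers of 4) for the RBF view. The search uses stratified 5-fold CV by
  default (`TrainingRecipe.inner_cv`): model selection is far less
  variance-sensitive than model assessment, and 5 folds halve training
  cost relative to 10 with no measurable change in the selected models;
  the evaluated protocols themselves (below) are unaffected.
- For the motif view the vocabulary is part of the model, so the inner
  CV re-mines it on every inner training split (cheap, via precomputed
  per-sequence substring sets). Mining once per training fold would leak
  inner-validation sequences into the features and make every C look
  perfect, voiding both the selection and the reported cv_accuracy.
- Jackknife = leave-one-out with the **full recipe re-fit every round**,
  including motif re-mining and hyperparameter search. `kfold` uses
  seeded stratified splits and reduces exactly to the jackknife at k = n.
  A `reuse_vocabulary` mode mining one global vocabulary exists, is
  clearly labeled leakage-prone, and is never a default.
- Metrics: Sn, Sp, Acc, MCC from the pooled confusion matrix. In batch
  reports an MCC with an empty marginal is reported as 0 with a
  `degenerate` flag rather than raised.
- Labels are +1/-1 internally; reports print `m6A` / `non-m6A`.
- Dinucleotide frequencies default to overlapping counting (all L-1
  adjacent pairs), the established PseDNC convention; a literal
  non-overlapping mode (pairs 1-2, 3-4, ...) is available, and on
  odd-length sequences it ignores the trailing residue rather than
  erroring, since the canonical 51-nt windows are odd.

## Synthetic data

Real m6A benchmark sets are experimentally derived and not redistributable
here, so `m6avote.synthetic` generates structurally equivalent data:
balanced classes of 51-nt windows over a configurable background
composition (uniform by default), every window centered on A. Positives
carry a planted consensus motif — default `GGACU`, mimicking the
methyltransferase recognition context, with its A on the window center —
with probability `plant_prob` (default 0.9) at a jittered offset (default
+/-3). Offsets that would put a non-A motif letter onto the forced central
adenosine are excluded from the candidate set (for GGACU at jitter 3 the
allowed shifts are -3, 0, +3); this keeps the window invariant and makes
`plant_prob=1` guarantee a verbatim motif. Negatives are pure background
and may contain the motif by chance, as real unmethylated windows may; a
`strict_negatives` mode rescreens them for separability tests.

What this emulates — and what it does not: the generator reproduces class
balance, window geometry, compositional structure and a localized
sequence signal, but not the redundancy filtering, transcriptome-specific
composition, or the partially characterized context of real yeast m6A
sites. Passing the synthetic benchmark therefore demonstrates that the
pipeline recovers a planted signal without leakage at realistic sizes,
not that it attains any particular accuracy on real transcriptomes.

## Problem sizes and numerical choices

- The end-to-end benchmark runs 200+200 windows, stratified 10-fold CV,
  across replicate seeds (5 in the test suite, 3 in
  `scripts/acceptance.py`); the null control uses 100+100 windows with
  `plant_prob=0` and must stay inside the 3-sigma binomial band around
  0.5 — the designated leakage alarm.
- Property standardization uses the population SD over the 16
  dinucleotides; a zero-variance property column is an error.
- Kernel matrices are checked symmetric to 1e-9, PSD to -1e-6, unit
  diagonal to 1e-9 after normalization; PseDNC vectors sum to 1 within
  1e-9.
- Grid-search ties resolve to the first grid point in iteration order;
  all shuffling is seeded, making every workflow byte-reproducible under
  a fixed seed.
- The model archive is a single joblib file containing the property
  table, PseDNC config, motif vocabulary, gkm parameters and training
  residues, fitted SVMs, weights, seed and a training-set fingerprint
  (order-insensitive sha256), version-stamped.

## Known limitations

- Trained on synthetic data the tool demonstrates the machinery; real
  use requires real labeled windows in the paired-FASTA format.
- The voting gain 3q^2 - 2q^3 - q presumes comparably accurate,
  independent voters. On single-signal synthetic data the string-kernel
  view dominates the other two, and their errors correlate on windows
  where the planted signal is absent (unplanted positives, chance-motif
  negatives); there the majority vote tracks the dominant view to within
  one or two accuracy points rather than beating it. The acceptance
  script reports this margin (`ensemble_minus_best_single_acc`) so the
  behavior is measured, not assumed. Balanced views — as on real
  transcriptome data, where each representation captures a different
  partial signal — are the regime the ensemble is designed for.
- The exclusive ("appears in exactly one class") motif criterion becomes
  brittle as training sets grow: common true motifs start occurring in
  chance negatives and drop out of the vocabulary, leaving longer,
  rarer contexts. Frequency-thresholded exclusivity is out of scope.
- The gkm view recomputes the training-vs-query kernel at prediction
  time, so archives store training sequences; for the intended n (a few
  thousand windows) this is cheap.
- No probability calibration of vote scores, no more than three base
  classifiers, no stacking.
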
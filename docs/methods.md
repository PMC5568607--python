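# Methods

## Problem and model

`seqaudit` treats label auditing as a self-consistency question: train a
multi-class ensemble on the labeled data, then ask, sequence by sequence,
how the ensemble's *out-of-bag* members vote. Because each tree's OOB set
was not used to grow that tree, the OOB vote fraction v[s, c] is an
internal cross-validation signal: for a correctly labeled, typical
sequence it concentrates on the true class; for a mislabeled sequence it
concentrates elsewhere. Unanimity (consistency 100%) does not imply
correctness — unanimous agreement on a class *other than the label* is
precisely the audit signal.

The shortlist criterion v[s, true(s)] < 1/K is deliberately weak: with
votes summing to one over K classes, it is exactly the point at which some
other class must out-vote the recorded one, so every shortlisted sequence
is also argmax-misclassified. Stricter thresholds are a flag
(`--threshold`); the default generalizes the case study's 1/7.

## Featurization

Sequences are cleaned (upper-cased; X/B/Z/J/U/O, gaps and stops removed
with per-record counts logged) and mapped through an alphabet scheme — a
partition of the 20 canonical residues. Shipped schemes: `aac` (identity,
20), `sez-table` and `sez-lit` (Sezerman, 11), `dav` (Davies, 9). The
printed source row for the Sezerman grouping is typographically garbled
(21 letters, T appearing twice), so both defensible resolutions ship as
data files and either can be selected; `sez-table` (T with ST, ninth group
WC) is the default used in the three-scheme audit. Non-canonical residues
are removed rather than mapped to an extra group because the feature
spaces are exactly |Σ| ∈ {20, 11, 9} symbols with no wildcard column.

n-gram features use the window-count denominator L − n + 1, making each
size-n block a probability distribution; the alternative denominator L is
a config switch (`FeatureConfig.denominator="length"`) since published
descriptions of "relative frequency" are ambiguous on this point.
Sequences shorter than n get an all-zero block and a warning rather than
an error, for robustness on fragments. Column order is deterministic:
ascending n, then lexicographic in the scheme's group order.

## Feature selection

The optional filter scores each feature by the number of one-vs-one class
pairs (21 for K = 7) whose two-sided Welch t-test has p < α (default
0.05, no multiple-testing correction — the filter is a ranking device,
not an inference). Welch's unequal-variance form is chosen because class
sizes are strongly unbalanced. Selection is either `min_pairs` (keep
count ≥ v) or `target_size` (top v by descending count, then ascending
minimum pairwise p, then feature name — fully deterministic). The subset
sizes 585/386/238 used in the original Class C study are recorded as
conventional `target_size` values (`STUDY_TARGET_SIZES`); the exact
subsets are not recoverable without the original data, so they are
configuration, not assertions. Features with zero variance in both groups
of a pair contribute no significance for that pair.

## Forest

Defaults: 500 trees, seed 42, stratified bootstrap with per-class sample
size equal to the smallest class count (drawn with replacement per
class), CART trees with floor(√p) candidate features per split and
unlimited depth. "Stratified" is realized as equal per-class sampling —
the standard reading when the goal is that class-size imbalance not
dominate the vote. A single seed drives everything; per-tree RNG streams
and tree seeds are derived from it, so runs are bit-reproducible.

Votes are OOB by default: in-bag votes are memorization-biased toward
perfect self-consistency and would hide mislabels. `vote_mode="all"`
tallies every tree for comparison. Sequences with zero OOB trees (not
observed at these defaults; expected OOB count is ≈ T·e⁻¹ per tree under
an unstratified bootstrap and higher under the stratified one for small
classes) are flagged and excluded downstream with a warning. Argmax ties
break to the earliest class in canonical order (the class order fixed at
dataset load), for determinism.

Confusion summaries report class error 1 − counts[t,t]/rowsum[t] (one
minus sensitivity) and overall accuracy trace/total, kept exact
internally; the report layer rounds errors to 3 decimals and accuracies
to 2, matching the case-study table precision. Note the printed source
tables themselves mix truncation and rounding in the last decimal, so
recomputed errors can differ from printed ones by up to one unit in the
third decimal; the regression tests assert agreement at that resolution.

## Synthetic data

The generator emulates what the featurization can actually see:
compositional class differences. Each class receives a profile over the
20 residues — drawn from a symmetric Dirichlet(α₀) or supplied explicitly
— and sequences are i.i.d. draws from their generating class's profile
with lengths uniform in [250, 600] (a GPCR-like scale). A mislabel plan
plants sequences generated from one class but labeled as another; planted
sequences replace members of the assigned class, preserving label
proportions. The `easy_preset` uses the case study's seven classes at
their real 88:12:52:86:98:26:16 imbalance (quarter scale, 378 sequences),
α₀ = 0.05 (strongly separated compositions) and 10 planted mislabels
spread over six class pairs.

What this does **not** emulate: positional/motif structure, homology and
phylogenetic correlation between sequences, length–class correlation, or
the soft overlap of real sub-families (real Class C families like Ph/VN
overlap far more than Dirichlet-0.05 profiles). Passing the recovery test
therefore shows the pipeline's machinery is sound end-to-end — that
compositional outliers of this strength are reliably flagged — not that
real-database recall is 10/10. Recovery degrades monotonically as α₀
grows, and a smoke test pins that qualitative behavior at three settings.

## Bundled reference tables

The case study's printed tables are shipped as CSV with a SHA-256
manifest verified at load: three 7×7 confusion matrices (with the printed
class-error column kept alongside the counts), the per-sequence vote rows
of the three mG/GB/Ph shortlists, and the printed overall accuracies.
Decoding notes: row sums reproduce the documented per-class totals
(351/48/208/344/392/102/65) and the AAC trace is 1380. The printed
two-of-three refined list misplaces one id (b3s157_triad, which all three
transformation shortlists contain) and omits another (a7s0d2_nemve,
present in two); recomputation from the per-transformation rows
nevertheless yields the documented bucket sizes 5 and 8, and the
recomputed membership is treated as correct.

## Problem sizes and numerics

The test suite and acceptance script run the full three-scheme audit at
the 378-sequence preset with 500 trees (seconds on one CPU); unit tests
use smaller slices and 40–200 trees. Vote-row normalization is asserted
to 1e-9; vote fractions are exact multiples of 1/oob_tree_count by
construction. Feature matrices are dense float64 (378 × 8420 ≈ 25 MB at
the preset scale).

## Limitations

- Purely compositional features: mislabels distinguishable only by
  residue order or position escape the audit.
- The t-test filter assumes approximately continuous feature values;
  for very short sequences the frequencies are coarse and the test
  loses calibration.
- Shortlists are candidates for curation, not verdicts; a systematically
  mislabeled *majority* within a class would invert the signal.
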
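# seqaudit

Audit the class labels of a protein sequence database the way an ensemble
classifier sees them.

Curated sequence databases inherit labels from automatic annotation
pipelines, and some of those labels are wrong. `seqaudit` flags candidate
mislabels without alignments or structures: it featurizes each unaligned
sequence as reduced-alphabet *n*-gram frequencies, trains a stratified
random forest, and inspects the **per-sequence out-of-bag (OOB) vote
fractions** of the ensemble. A sequence whose own trees consistently vote
it into a *different* class than its database label — under several
independent featurizations — is a strong candidate for expert re-curation.
The tool never rewrites labels; it produces shortlists.

The approach was developed for G protein-coupled receptor (GPCR) Class C
sub-family labels (seven sub-families: mG, CS, GB, VN, Ph, Od, Ta; 1510
sequences), and the printed tables of that case study ship with the
package as checksummed fixtures for the arithmetic (no-retraining) code
path. It applies to any FASTA + label-TSV dataset with K ≥ 2 classes.

## Method

For a sequence of cleaned length *L* over an alphabet Σ (the 20 amino
acids, or a reduced alphabet grouping physico-chemically similar
residues — Sezerman/11, Davies/9), the feature vector concatenates, for
*n* ∈ {1, 2, 3}, the relative frequencies

&nbsp;&nbsp;&nbsp;&nbsp;f(g) = #windows equal to g / (L − n + 1),&nbsp;&nbsp;g ∈ Σⁿ,

giving |Σ| + |Σ|² + |Σ|³ columns (8420 / 1463 / 819 for 20 / 11 / 9
symbols). Optionally, features are filtered by how many of the K(K−1)/2
one-vs-one class pairs show a significant Welch *t*-test.

A forest of *T* trees (default 500, seed 42) is grown on stratified
bootstraps: each tree resamples every class to the smallest class size,
so the 48-member and 392-member sub-families weigh equally. For sequence
*s*, the vote fraction v[s, c] is the share of *s*'s out-of-bag trees
voting class *c* (Σ_c v[s, c] = 1). The **consistency** of *s* is
v[s, true(s)], and *s* is shortlisted when

&nbsp;&nbsp;&nbsp;&nbsp;v[s, true(s)] < 1/K&nbsp;&nbsp;(strict),

which by pigeonhole forces argmax_c v[s, c] ≠ true(s): the ensemble not
only misclassifies *s*, it does so decisively. Shortlists computed under
the different featurizations are merged by sequence id and bucketed by
agreement count; ids flagged by all featurizations are
transformation-independent candidates.

## Worked example

Report-only run on the bundled GPCR Class C case-study tables (pure
arithmetic, no forest training):

```
$ seqaudit report --outdir out/
flagged in exactly two: 5; in all three: 8
```

Five sequences were shortlisted under exactly two of the three
featurizations and eight under all three (3 mG, 1 GB, 4 Ph) — eight
transformation-independent mislabel candidates out of 1510 sequences.
`out/confusion_aac.csv` holds the recomputed confusion summary, e.g.
overall accuracy 0.91 and class errors mG 0.028, Od 0.343; the top of
`out/shortlist_aac.csv` reads

```
transformation,id,true_label,predicted_label,v_true,mG,CS,GB,VN,Ph,Od,Ta
aac,XP_001521075,Ph,mG,0.017,0.549,0.006,0.429,0.000,0.017,0.000,0.000
aac,XP_002735016,mG,GB,0.026,0.026,0.000,0.958,0.000,0.016,0.000,0.000
```

— XP_001521075 is labeled Ph but 54.9% of its OOB trees vote mG and only
1.7% vote Ph.

Full pipeline on synthetic data with known planted mislabels:

```
$ seqaudit simulate --seed 42 --outdir sim/          # 378 seqs, 7 classes, 10 planted
$ seqaudit audit --fasta sim/synthetic.fasta --labels sim/synthetic.labels.tsv \
    --seed 42 --skip-select --outdir audit/
$ head -4 audit/merged_shortlist.csv
id,true_label,n_transformations,transformations
GB_0000,GB,3,aac;sez-table;dav
Ph_0000,Ph,3,aac;sez-table;dav
Ph_0001,Ph,3,aac;sez-table;dav
```

All ten planted mislabels (`sim/synthetic.truth.tsv`) land in the merged
shortlist, flagged by all three featurizations.

Each stage is also independently runnable: `seqaudit featurize | select |
train | shortlist | merge`, and everything is importable
(`import seqaudit`).

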
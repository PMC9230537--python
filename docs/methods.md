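# Methods

This note documents the models and procedures implemented in `rbpdetect`,
the parameters that matter, the numerical choices behind them, and what the
synthetic fixtures do and do not establish about real data.

## Annotation curation

Coding sequences are labelled by a case-insensitive regular expression over
the `/product` qualifier:

```
tail[ -]?fib(er|re) | tail[ -]?spike | receptor[ -]binding protein | receptor[ -]recognizing protein
```

The bare words `spike`, `fiber` and `binding protein` deliberately do not
match: they are used for too many non-RBP proteins to be trusted as labels.
A regex-matched product is still discarded if it contains any of
*adaptor, wedge, baseplate, hinge, connector, structural, component,
assembly, chaperone, attachment, capsid, proximal, measure* — annotations
of proteins that are related to RBPs (assembly chaperones, baseplate
components, …) without being RBPs.  Non-matching products are usable
negatives only when they are confidently annotated, so *probable, probably,
uncharacterized, uncharacterised, putative, hypothetical, unknown,
predicted* disqualify an Other.  Keyword matching for both exclusion lists
is plain substring matching on the whole product line; anchoring to word
boundaries was considered and rejected because real annotations hyphenate
and concatenate freely.

Quality filters: a sequence with any residue outside the 20 canonical
amino acids is dropped (`B J O U X Z` and `*` count as unknown; one
trailing `*`, an artifact of some GenBank translations, is stripped before
the check).  RBPs must be 200–1500 aa — the length range expected for tail
fibers and tailspikes — with both boundaries inclusive ("shorter than 200"
removes 199 and keeps 200).  Others must be ≥ 30 aa.  The unknown-residue
check runs before the length check, so a short sequence with an `X`
is booked under `unknown_aa`; each removal is booked exactly once.

Duplicates: exact-sequence duplicates collapse to their first occurrence
within each group.  A sequence present in both groups is removed from
*both*: its label is ambiguous evidence, and keeping it on either side
would teach a model the wrong thing.  The two directions are tallied
separately (`dup_cross_rbp`, `dup_cross_other`).

Subsampling and splitting: Others are uniformly subsampled without
replacement to `ratio × n_RBP` (default 10, the class balance used for
model training; an overdraw is an error, and `ratio=None` disables the
step for exact-count validation).  The train/test split assigns records
dated up to and including the cutoff month (default 2021-09) to training;
the date comes from the GenBank record (LOCUS) date.  Curation is
idempotent: running it on its own output removes nothing.

## Profile HMM engine

The engine implements the classical match/insert/delete profile
architecture with plain **local Viterbi** scoring:

* an alignment may enter at any match state and exit from any match state
  at no cost; flanking residues are attributed to the background and
  cancel out of the log-odds;
* match and insert emissions contribute `log2(e(x)/bg(x))`; deletions emit
  nothing; interior transitions use the profile's probabilities;
* scores are reported in bits with 1-based inclusive hit coordinates.

There are no E-values, glocal corrections or Dirichlet mixture priors:
hit calling uses a fixed bit-score threshold (default **25 bits**), chosen
conservatively so that profile sets built from handfuls of sequences do
not fire on background composition.  On the synthetic fixtures the margin
is enormous (true-family scores run to hundreds of bits; 100 shuffled
decoys produce zero calls), so the exact value is not delicate.  The
Viterbi recursion is verified exactly (to 1e-9) against exhaustive
enumeration of all legal state paths on toy instances; the delete-state
chain is folded into a cumulative running maximum, which is an exact
rewriting, not an approximation.

Profile estimation from an MSA uses uniform sequence weights and flat
Laplace pseudocounts (+1 by default) on emissions and transitions;
columns with gap fraction ≤ 0.5 become match states; insert emissions are
set to the background, making insertions score-neutral.  This is a
deliberately reproducible simplification of hmmbuild's effective-sequence
weighting and mixture priors; profiles built by HMMER remain usable
through the HMMER3 reader.

HMMER3 ASCII I/O targets the `HMMER3/f` dialect.  Values are stored as
negative natural logs at five decimals, so probabilities survive a round
trip only to ~1e-5 relative accuracy; the reader keeps the quantised
values exactly as stored (no renormalisation), which makes
`write ∘ read` the identity on bytes from the second write on.  Files
written here are readable by pyhmmer/HMMER, and hmmbuild output is
parseable (statistics and cutoff lines are skipped).

## Domain architectures and custom HMM construction

Residue **200** divides the termini: a hit whose alignment starts at
residue ≤ 200 is N-terminal, later hits are C-terminal (the cutoff residue
belongs to the N-terminus; a start-based rule is used because hits can
span the boundary).  Any recognized domain designates an RBP — sensitivity
is the point of the domain track; precision comes from the curation of the
profile set.

Proteins with a domain at exactly one terminus seed new profiles:

1. the unknown terminus is excised — residues 1..min(200, len) when the
   N-terminal domain is missing, and everything after the last N-terminal
   hit (`ali_end + 1` .. end) when the C-terminal domain is missing; empty
   C parts (hit runs to the end) are skipped and logged;
2. parts are clustered greedily, longest first: a part joins the first
   cluster whose representative it matches at ≥ 0.9 identity, where
   identity is the number of identical residues under a maximal-matching
   global alignment (equivalently the longest common subsequence)
   normalised by the shorter sequence — the convention of greedy
   clustering tools;
3. clusters with ≥ 5 members are aligned center-star around their
   representative (pairwise global alignments merged with
   "once a gap, always a gap"; match +1, mismatch −1, gap open −2,
   extend −0.5).  Fewer than five observations are not enough to estimate
   a profile and the cluster is skipped;
4. each alignment yields a new profile (`custom_N_k` / `custom_C_k`)
   appended to the base set.

Adding profiles can only add hits at a fixed threshold, so the set of
domain-positive proteins never shrinks after augmentation; the report
counts one-sided proteins, clusters, built profiles and the detection gain
on re-scan.

## Classifier

The embedding interface is pluggable.  The built-in embedder hashes
overlapping 3-mers into **d = 400** buckets (stable MD5-based indices) and
normalises counts to frequencies — deterministic, dependency-free, and
sufficient for compositional signals.  Protein language-model embeddings
(1024-d) are supported as precomputed matrices; the pretrained weights are
not bundled, and requesting that embedder without them raises with advice.

Nested stratified cross-validation uses 4 outer and 4 inner folds (the
inner count mirrors the outer loop).  The default grid is
`max_depth ∈ {3, 5, 7} × n_estimators ∈ {100, 300, 500}`; inner selection
maximises mean F1 with ties resolved to the earlier grid point; outer
folds report F1 and PR-AUC.  The final model is refit on all data with
hyperparameters selected by an inner-style CV over the full dataset.
Scores at exactly the 0.5 threshold are called positive.  The test suite
and the acceptance script run reduced grids (e.g. `{3,5} × {100,300}`) and
a 10-seed null at n = 220 — problem sizes chosen to keep single-CPU runs
short while leaving the measured properties unchanged.

HMM-score fusion appends one column per profile holding the best bit
score on that protein (0 when there is no hit) after the embedding block.
Raw bits are used rather than a normalised encoding: tree ensembles are
invariant to monotone per-feature transforms.

## Evaluation

F1 = 2TP/(2TP+FP+FN); sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
MCC by its standard formula.  Degenerate denominators yield 0.0 with a
warning so an all-negative predictor still produces a full metrics row.
PR-AUC integrates precision step-wise over achievable recalls (tied scores
enter together, no interpolation) — the same convention as scikit-learn's
average precision, against which it is cross-checked, and additionally
verified by explicit threshold enumeration.  Concordance counts all
2^m − 1 exclusive Venn regions of the methods' correct-positive sets plus
the positives missed by every method; external predictors enter as
two-column (id, label) prediction files, with multi-class scores reduced
by argmax beforehand.

## Synthetic fixtures

The generators are pure functions of their spec, seed included.

* **GenBank fixture** — 1,000 CDSs across 40 genomes by default, with a
  category mix covering every curation rule: keyword variants that must
  pass, exclusion keywords, out-of-range lengths, unknown residues, and
  planted within-group and cross-group duplicate pairs.  The ground truth
  records each CDS's *intended* outcome at generation time (not by running
  the curation rules), so the comparison is independent.  Record dates
  straddle the cutoff month; proteins are back-translated with a fixed
  codon choice so the `translation`-less code path can also be exercised.
* **Modular proteins** — each protein is an N-family member (200 aa,
  spanning exactly the terminus cutoff) followed by a C-family member
  (140 aa).  A family is a consensus plus a hypervariable position set
  (fraction = mutation rate, default 10%), mimicking the receptor-facing
  variability of real RBP domains; members differ from the consensus only
  at those positions, so within-family identity is at least 1 − rate by
  construction and the domain edges stay conserved (default 10 residues),
  as real domain boundaries tend to be.  Three C-terminal families are
  withheld from the base profile set; each has 6 construction carriers,
  10 held-out carriers, and 3 "orphans" whose N terminus is unrelated
  background — undetectable until the custom C profile exists, which is
  what makes the post-augmentation detection gain measurable.
* **Two-class sets** — background-composition proteins with a signature
  3-mer (`WYW`) implanted a fixed number of times (default 4) at
  non-overlapping positions in positives; effect 0 makes the classes
  exchangeable.  Prevalence defaults to 1:10, the ratio the curation
  pipeline produces.  An optional HMM-score block separates the classes
  by a configurable mean shift with sequences left as pure noise, which
  isolates the fusion benefit.

What passing these fixtures does **not** show: real RBP domains indel,
recombine and drift far more than the substitution-only family model;
real annotations misspell and contradict beyond the keyword mix; and
hashed 3-mer embeddings are a far weaker representation than language
models.  The fixtures validate the machinery — the rules, the
bookkeeping, the algorithms and their couplings — not biological
performance, which requires the real genome collections, Pfam profiles
and language-model weights that are deliberately out of scope here.

## Known limitations

* One best hit per profile per protein; repeated domains of the same
  family are reported once.
* The center-star aligner is a default good enough for high-identity
  clusters; an external aligner can be substituted where cluster
  divergence is high.
* `build_from_msa` folds the rare delete→insert transition through the
  preceding match state (the 7-transition plan has no slot for it); on
  gappy, low-identity alignments HMMER-built profiles are preferable.
* Dates are read from the GenBank record date, which on re-annotated
  records can postdate original submission.
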
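# rbpdetect

Identification of bacteriophage **receptor-binding proteins (RBPs)** — tail
fibers, tailspikes and tail tip proteins — in annotated phage genome data.
RBPs are the primary determinants of phage host specificity and the main
target of host-range engineering, but their annotations in public databases
are inconsistent, and their strong evolutionary diversification defeats
simple homology search.

`rbpdetect` implements two complementary detection tracks over a shared
curation pipeline, plus the synthetic data generators and the evaluation
harness needed to validate every stage without external downloads:

1. **Curation** (`rbpdetect.curation`) — parse GenBank records, label each
   CDS *RBP* or *Other* from its `/product` annotation with a keyword
   pattern (`tail fiber`/`fibre`, `tail spike`, `receptor-binding protein`,
   `receptor-recognizing protein`, and spacing/hyphenation variants),
   discard misleading annotations (`assembly`, `hinge`, `baseplate`, … for
   RBPs; `hypothetical`, `putative`, … for Others), filter on residue
   quality and length (RBPs 200–1500 aa, Others ≥ 30 aa), deduplicate
   within and across groups, subsample negatives, and split train/test by
   genome record date.
2. **Domain track** (`rbpdetect.profile_hmm`, `rbpdetect.domains`) — a
   self-contained profile-HMM engine (build from MSA, local Viterbi
   log-odds scoring in bits, HMMER3 ASCII I/O) and the modular-architecture
   logic: hits starting at residue ≤ 200 are N-terminal (structural),
   later hits C-terminal (receptor-binding/cleaving/chaperone).  A protein
   with any recognized domain is called an RBP.  Proteins with a domain at
   only one terminus seed **custom HMM construction**: the unknown terminus
   is excised, parts are greedily clustered at 90% identity, clusters of
   ≥ 5 members are center-star aligned and turned into new profiles.
3. **Classifier track** (`rbpdetect.classifier`) — an XGBoost binary
   classifier over fixed-length protein embeddings (pluggable; a
   deterministic hashed 3-mer embedder is built in, protein language-model
   vectors can be supplied externally), tuned and evaluated by **nested
   4-fold cross-validation** (inner folds select `max_depth` and
   `n_estimators` by F1; outer folds measure F1 and PR-AUC).  Per-profile
   HMM bit scores can be fused to the embedding as an extra feature block.
4. **Evaluation** (`rbpdetect.evaluate`) — F1, MCC, sensitivity,
   specificity, step-wise PR-AUC, and Venn-style concordance counts of
   correct positive predictions across any number of predictors.

## Model summary

A profile HMM with `L` match states scores a protein `x` by the best local
alignment log-odds

```
S(x) = max over paths π of log2 [ P(x, π | model) / P(x | background) ]
```

with match/insert emissions, M→M/I/D transitions, free entry into and exit
from any match state, and a fixed Robinson–Robinson background.  Scores are
in bits; a hit is called at ≥ 25 bits by default.  The Viterbi
implementation is verified against exhaustive path enumeration.

## Worked example

Generate a synthetic annotated-genome fixture, curate it, and mine custom
HMMs from one-sided proteins:

```bash
python -c "from rbpdetect.synthetic import *; gen_genbank(GenBankFixtureSpec(seed=0), 'fixtures')"
rbpdetect build-dataset --genbank fixtures --cutoff 2021-09 --ratio 4 --seed 42 --out dataset
# retained 125 RBPs and 500 Others (375 removed)
cat dataset/ledger.tsv
# step    removed
# rbp_excluded_keyword    40
# other_excluded_keyword  100
# rbp_length      40
# rbp_unknown_aa  20
# other_unknown_aa        20
# other_length    30
# dup_within_rbp  5
# dup_within_other        5
# dup_cross_rbp   5
# dup_cross_other 5
# other_subsample_discarded       105
```

Every removal is tallied: 1,000 input CDSs = 625 retained + 375 removed.
The FASTA headers carry `accession|protein_id|label|split`.

```bash
rbpdetect build-hmms --fasta proteins.faa --hmms base.hmm --out hmm_out
# built 3 custom HMMs; 9 additional detections
```

On the modular fixture (three C-terminal domain families withheld from the
base profile set), the pipeline finds 18 one-sided proteins, clusters their
C-terminal parts into exactly 3 clusters, builds one custom profile per
cluster, and the re-scan then detects 9 proteins that no base profile
recognized (37/37 detected overall).

Training and applying the classifier:

```bash
rbpdetect train --rbps dataset/rbps.faa --others dataset/others.faa --out model.ubj
rbpdetect predict --model model.ubj --fasta proteins.faa --out predictions.tsv
rbpdetect evaluate --truth truth.tsv --pred xgb=predictions.tsv --out eval_out
```

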
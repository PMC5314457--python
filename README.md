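# il10pep

Composition-based prediction, design and motif analysis of **IL-10
inducing peptides**.

Interleukin-10 is an immunosuppressive cytokine: T-helper epitopes that
trigger its release dampen the immune response, which makes them valuable
to *include* in tolerogenic vaccines (e.g. asthma immunotherapy) and
essential to *remove* from anti-tumour vaccines. Classical epitope tools
predict MHC class II binding but say nothing about which cytokine a bound
peptide induces. `il10pep` addresses that gap for immunologists and
vaccine designers: given peptide sequences, it predicts whether they are
IL-10 inducers, ranks single-residue analogs of a query peptide, and scans
whole proteins for inducing regions.

## Method

Peptides (8–42 residues) are encoded as fixed-length vectors:

- **AAC** — amino-acid composition, `AAC(i) = 100 · R(i) / N` (20 features);
- **DPC** — dipeptide composition over the N−1 overlapping pairs,
  `DPC(i) = 100 · D(i) / (N−1)` (400 features);
- split composition (per-half blocks), terminal compositions (NT8 / CT8 /
  NT8CT8 fragments) and per-position one-hot **binary profiles** of the
  derived 16-mer (first 8 + last 8 residues).

Five classifier families (RBF-kernel SVM, random forest, k-NN, an
SMO-style SVM, and a pruned decision tree) are trained on these encodings
and evaluated under **stratified five-fold cross-validation**. Each model
emits a continuous score oriented so that higher = more likely inducing; a
single decision threshold is tuned on the pooled out-of-fold scores by
maximising the Matthews correlation coefficient

    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

alongside sensitivity, specificity, accuracy and ROC AUC. Supporting
analyses include correlation-based feature subset selection (CFS merit
with best-first search), mining of **class-exclusive contiguous motifs**
with support/coverage tables, and per-position two-sample residue
enrichment statistics on the terminally aligned 16-mers.

When two models are supplied — the main model (inducers vs non-inducing
MHC II binders) and an alternate model (inducers vs MHC II non-binders) —
predictions use an **AND rule**: a peptide is called an inducer only if
both models agree, so MHC II non-binders are not mistaken for inducers.

A seeded synthetic-data generator reproduces the statistical structure of
curated inducer/non-inducer datasets (class sizes, length extremes,
R/L- vs A/G/P-shifted composition, planted exclusive motifs) with a
ground-truth manifest, so the whole toolkit is testable end to end without
any external download.

## Worked example

Simulate a labelled dataset, cross-validate a random-forest DPC model,
train it, and use it:

```bash
il10pep simulate --n-pos 120 --n-neg 120 --seed 42 --out-dir demo
il10pep cv    --pos demo/positives.fasta --neg demo/negatives.fasta \
              --encoder DPC --algorithm random_forest --param trees=300 --seed 42
il10pep train --pos demo/positives.fasta --neg demo/negatives.fasta \
              --encoder DPC --algorithm random_forest --param trees=300 --seed 42 \
              --out demo/rf_dpc.joblib
```

The `cv` command prints the pooled operating point and the per-fold table:

```
{
  "Algorithm": "random_forest",
  "Encoder": "DPC",
  "Threshold": 0.5,
  "Sensitivity": 90.83,
  "Specificity": 95.83,
  "Accuracy": 93.33,
  "MCC": 0.87,
  "AUC": 0.977
}
```

i.e. at the MCC-optimal threshold of 0.5 (fraction of positive trees),
90.8% of inducers and 95.8% of non-inducers are recognised out-of-fold.
Designing analogs of a query peptide ranks every single-residue
substitution by predicted induction:

```
$ il10pep design --model demo/rf_dpc.joblib --peptide ACDEFGHIKL
rank  mutation  sequence    score_main  verdict
1     K9R       ACDEFGHIRL  0.6400      inducer
2     K9L       ACDEFGHILL  0.5700      inducer
3     D3L       ACLEFGHIKL  0.3367      non-inducer
...
```

— replacing Lys9 with Arg or Leu (the residues enriched in inducers)
lifts the peptide above the decision threshold. Scanning a protein
reports every window (1-based inclusive coordinates):

```
$ il10pep scan --model demo/rf_dpc.joblib --sequence MKTLLRRDHLAEYAAGGPPAGATLLRV --window 15
start  end  sequence         score_main  verdict
1      15   MKTLLRRDHLAEYAA  0.7933      inducer
2      16   KTLLRRDHLAEYAAG  0.6900      inducer
...
7      21   RDHLAEYAAGGPPAG  0.1200      non-inducer
```

— the R/L-rich N-terminal windows score high, the A/G/P-rich middle does
not. `il10pep motifs` and `il10pep enrich` produce the exclusive-motif
coverage tables and positional/compositional enrichment statistics;
`il10pep predict` scores peptide libraries, optionally with `--alt-model`
for the two-model AND rule.

## Layout

- `src/il10pep/dataset_io.py` — FASTA / plain-list reading, validation,
  deduplication, dataset summaries
- `src/il10pep/encoders.py` — AAC/DPC/split/terminal/binary encoders
- `src/il10pep/metrics.py` — Sn/Sp/Acc/MCC, ROC AUC, threshold sweeps
- `src/il10pep/model_suite.py` — classifiers, stratified CV, CFS,
  persistence, external validation
- `src/il10pep/motif_miner.py` — exclusive motif mining and coverage
- `src/il10pep/positional_analysis.py` — positional and compositional
  enrichment statistics
- `src/il10pep/applications.py` — Predict / Design / Protein-Scan
- `src/il10pep/synthetic_data.py` — seeded generator with ground truth
- `src/il10pep/cli.py` — the `il10pep` command

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known limitations.
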
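# mirpipe

A tested, reusable re-implementation of a plasma small-RNA-seq miRNA
analysis pipeline with downstream biomarker statistics:

1. **preprocess** — 3' adapter trimming (seeded prefix match with a
   mismatch budget), junk/low-complexity/quality filtering, the 18–26 nt
   length window, and collapsing to unique sequences with per-sample
   counts and a full rejection ledger.
2. **annotate** — contaminant ncRNA removal (exact substring), then
   ungapped mapping to precursor hairpins allowing one internal mismatch
   and bounded 5'/3' end variation; sequences on the arm opposite a sole
   annotated mature become novel candidates with an 80 nt flank window.
3. **hairpin** — a self-contained minimum-energy folding DP (per-pair
   energies GC −3, AU −2, GU −1 kcal/mol, hairpin loop ≥ 3 nt) plus
   evaluation of 11 structural criteria (stem pairs ≥ 16, free energy
   ≤ −15, hairpin length ≥ 50, loop ≤ 20, mature-region bulge/error
   limits, ≥ 80 % of the mature in the stem, …) to accept or reject
   novel candidates. Externally folded dot-brackets can be plugged in via
   `SecondaryStructure.from_dotbracket`.
4. **quantify** — miRNA × sample count matrix and median-of-ratios
   library-size normalization against a geometric-mean pseudo-reference
   (S_j = median_i c_ij / (∏_k c_ik)^(1/m)).
5. **diffexp** — Welch t / one-way ANOVA / chi-square / Fisher screening
   on normalized values, DE called at |log2FC| ≥ 1 and raw p < 0.05
   (deliberately no FDR adjustment), with volcano-plot records.
6. **biomarker** — rank-based ROC/AUC (ties = ½), combined two-marker
   logistic ROC, univariate OLS screens, a p < 0.10-gated multivariable
   model of pain interference, questionnaire-derived covariates
   (alcohol grams, pack-years, smoker status), and Table-1-style group
   summaries with t/ANOVA/chi-square tests.
7. **simulate** — synthetic hairpin references, adapter-ligated FASTQ
   reads (negative-binomial counts, isomiR end variation, planted
   mismatches, junk and contaminant reads) and cohort tables with
   planted group and slope effects, so the whole pipeline is testable
   offline and deterministically.

## CLI

```bash
mirpipe demo demo_dir --seed 11        # write synthetic inputs + config
mirpipe run demo_dir/config.yaml       # full run into demo_dir/run/
mirpipe hairpin GGGGAAAACCCC           # fold one sequence
mirpipe hairpin <seq> --mature 10-32   # ...and evaluate the 11 criteria
mirpipe preprocess --fastq s1=s1.fastq --adapter TGGAATTCTCGGGTGCCAAGG \
    --out unique.tsv
mirpipe quantify --counts counts.tsv --out normalized.tsv
mirpipe de --normalized normalized.tsv --group s1=A --group s2=B ... \
    --out de.tsv
mirpipe biomarker --cohort cohort.tsv --marker mir-x --out stats.json
```

A run directory contains one TSV per stage (`unique_sequences.tsv`,
`annotations.tsv`, `hairpin_criteria.tsv`, `counts.tsv`,
`normalized.tsv`, `diffexp.tsv`, `volcano.tsv`, `biomarker.json`) plus a
line-delimited JSON `run_log.jsonl` reconciling record counts at every
stage boundary. Identical config + seed ⇒ byte-identical outputs.

## Layout

```
src/mirpipe/
  seqio.py       FASTA/FASTQ/TSV I/O (Biopython-backed), RNA/DNA handling
  preprocess.py  cleaning + unique-sequence collapsing
  annotate.py    contaminant removal, precursor mapping, classification
  hairpin.py     folding DP, feature extraction, 11-criteria evaluation
  quantify.py    count matrix + library-size normalization
  diffexp.py     group comparisons + DE calling
  biomarker.py   ROC, OLS models, covariates, cohort summaries
  simulate.py    synthetic reference/read/cohort generators
  pipeline.py    config, staged runner, demo generator
  cli.py         click entry points
tests/           unit + property (hypothesis) + acceptance suites
scripts/acceptance.py
```
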
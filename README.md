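# splicetransfer

Transfer of splicing-defined tumour subtypes from cell lines to
patients: cassette-exon PSI screens, an iterative semi-supervised
random-forest classifier, Boruta consensus signature selection,
unsupervised validation, and survival contrasts — plus a seeded
synthetic-cohort generator so the entire pipeline runs and is tested
without any external data.

## The problem

Basal breast cancer *cell lines* divide into two well-characterised
subtypes — basal A (epithelial-like) and basal B (mesenchymal,
stem-like, drug-resistant) — but basal-like / triple-negative *tumours*
carry no such annotation, even though the distinction is prognostically
relevant. Given (i) inclusion/skipping junction counts for cassette
exons in labelled cell lines and unlabelled patients and (ii) patient
survival endpoints, the package answers: which exons distinguish the
subtypes, can the labels be carried across the culture-to-tumour domain
gap, what is the minimal splicing signature, and do the transferred
groups differ in survival?

## The method

For each cassette exon and sample, Ψ = IC/(IC+SC). Events are screened
by coverage (IC+SC ≥ 10 per group), a Kruskal–Wallis test on Ψ, and a
reliability rule |ΔΨ| > 0.1 with sign-probability ≥ 0.95 (Beta(IC+1,
SC+1) posterior, Monte-Carlo).

The core classifier is self-training across domains: a 1000-tree random
forest is fitted on labelled cell lines; patients with class-B
probability > 0.6 (or < 0.4) are candidates; at most 10·r of them are
admitted at round r with their predicted labels; the forest is refitted
and the loop repeats until no patient clears a threshold. Never-admitted
patients stay *unclassified*. A consensus Boruta selection (10 runs,
features confirmed ≥ 7 times) distils the admitted-cohort-relevant
events into a minimal signature, which is validated by t-SNE/k-means
segregation of held-out cohorts and by Kaplan–Meier / log-rank /
univariate Cox contrasts between the transferred groups.

See `docs/methods.md` for assumptions, parameter semantics, the
synthetic-cohort generative model, and known limitations.

## Worked example

```bash
splicetransfer all --seed 1 --outdir run1
```

generates the default synthetic cohort (12+12 labelled cell lines, 120
patients, 200 cassette exons of which 30 differ by |ΔΨ| = 0.4, planted
subtype hazard ratio 4) and runs every stage. The equivalent library
call:

```python
from splicetransfer.pipeline import load_config, run_all
manifest = run_all(load_config(None), "run1", seed=1)
```

Output of the bundled runner (`python scripts/acceptance.py --seed 1
--out results/acceptance.json`), which does exactly this:

```
pipeline complete (seed 1):
  events selected by screen : 31
  transfer rounds           : 8
  patient assignments       : {'A_like': 58, 'B_like': 60, 'unclassified': 2}
  consensus signature size  : 30
  hold-out segregation acc. : 1.000
  survival contrast HR / p  : 4.410 / 0.0001
```

Reading: the screen recovered the 30 planted differential exons (plus
one borderline noise event); the transfer classified 118/120 patients
over 8 rounds; Boruta confirmed 30 events in ≥ 7 of 10 runs; the
signature separates a held-out 55-cell-line cohort perfectly in the
t-SNE view; and the transferred B-like group shows the planted excess
hazard (Cox HR 4.4 against a generative value of 4, log-rank
p = 1e-4).

Stage outputs land in the run directory as plain TSV/JSON
(`assignments.tsv`, `signature.tsv` + BED6, `embedding.tsv`,
`contrast.json`, Kaplan–Meier step tables) together with a
`manifest.yaml` recording every threshold, derived seed and output
digest; re-running with the same config and seed reproduces every table
byte-identically.

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` re-runs the
full pipeline from scratch with the shipped defaults (as above), prints
the summary, and writes the results object to `--out`.

## Layout

```
src/splicetransfer/
  synthetic.py     seeded cohort generator + fixture I/O
  splicing.py      counts container, PSI, coverage & deltaPSI screens, BED
  differential.py  Kruskal-Wallis / Wilcoxon / Fisher / z-score / CD44-CD24
  transfer.py      IterativeTransferClassifier (sklearn estimator) + wrappers
  signature.py     BorutaConsensus selector + signature tables
  validation.py    t-SNE, segregation accuracy, clustering baselines
  survival.py      Kaplan-Meier, log-rank, Cox HR, terciles (lifelines)
  pipeline.py      stage orchestration, manifest
  cli.py           `splicetransfer` console entry point
```
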
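# mirconnect

Connectivity scoring of small molecules against miRNA perturbation
signatures.

Small molecules that reproduce — or reverse — the transcriptional
footprint of a miRNA perturbation are candidates for modulating that
miRNA's activity, a route to drugging miRNAs that sidesteps the
delivery problems of oligonucleotide therapeutics. `mirconnect`
implements the signature-matching pipeline for this question: it takes
treatment/control expression profiles from miRNA transfection
experiments and from small-molecule perturbation "instances"
(connectivity-map style: one molecule, many cell lines/doses/batches),
and produces a ranked, permutation-tested table of small-molecule–miRNA
associations.

## Method

For every perturbation experiment the package builds

* a **response signature** — the up- and down-regulated probe sets
  called differentially expressed (fold change ≥ 2 for unreplicated
  miRNA designs; SAM at FDR ≤ 0.05 for replicated ones; amplitude
  *a* = (t − c)/((t + c)/2) with the |a| > 2/3 twofold boundary for
  molecule instances), and
* a **ranked response pattern** — the full probe list ordered from the
  most up- to the most down-regulated by the same statistic.

Pairs are scored by bidirectional weighted Kolmogorov–Smirnov
enrichment (weight exponent *p* = 1): the molecule's up/down sets are
walked along the miRNA's pattern and vice versa, giving four
directional enrichment scores ES ∈ [−1, 1]. Each direction's pair
(ES_up, ES_down) combines to a Total Enrichment Score
TES = (ES_up − ES_down)/2 when the two scores oppose in sign and 0
otherwise; the instance's TES is the mean of the two scan directions.

A molecule's *t* instances are then aggregated against one miRNA
profile by a KS-type order statistic on their positions V(1..t) within
the TES ranking of all *n* instances:

    a = max_j [ j/t − V(j)/n ]      b = max_j [ V(j)/n − (j−1)/t ]
    AS = a  if a > b,  else  −b

so AS → +1 when the molecule's instances crowd the top of the ranking
(transcriptional mimicry) and AS → −1 at the bottom (reversal — the
pharmacologically interesting case for an oncogenic miRNA).
Significance comes from a permutation null: signatures are replaced by
uniform random probe sets of the same sizes, the chain is recomputed
(1000 rounds by default), and *p* is the fraction of null |AS|
exceeding the observed |AS|.

## Worked example

`examples/03_score_cohort.py` simulates one miRNA profile plus 10
molecules × 3 instances in which molecule `SM0000` exactly reverses the
miRNA signature, and runs the whole chain:

```
cohort: 10 molecules x 3 instances; planted reversal molecule: SM0000
molecule         AS      p
SM0000      -0.9333  0.000  <- planted
SM0002      +0.7333  0.140
SM0004      +0.6667  0.215
...
SM0001      +0.2667  0.975
```

The planted molecule's instances occupy the bottom of the TES ranking,
so its Association Score is strongly negative and no random-signature
permutation beats it (p = 0.000); the null molecules scatter across the
ranking with unremarkable p-values. The other examples cover signature
building (`01`), the enrichment walk (`02`), and the permutation null
(`04`).

The same pipeline is available from the shell:

```
mirconnect simulate --out fixture --relation reversal --seed 17
mirconnect build-signatures --in fixture --out sigs
mirconnect score --in fixture --signatures sigs --out results --seed 17
mirconnect export --associations results/associations.tsv \
    --catalogue fixture/catalogue.tsv --out significant.tsv --alpha 0.05
```

All formats are plain text: TSV/GCT 1.2 matrices, GMT signatures
(`_up`/`_down` lines), RNK patterns, TSV association tables.

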
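# Methods

This note records the model, the numerical conventions, and the design
choices behind `mirconnect`, in the order the pipeline applies them.

## Differential-response statistics

Three statistics convert a treatment/control profile into a response
signature and a ranked response pattern. Which one applies is decided
by the experiment's design, not by the user:

* **Fold change** (unreplicated miRNA designs, one sample in at least
  one class). Per-probe ratio t/c of class means; up-regulated at
  t/c ≥ 2, down-regulated at t/c ≤ 1/2. The symmetric reciprocal rule
  for the down direction is a package choice: a usable signature needs
  both directions, and it matches the amplitude boundaries below. The
  pattern ranks probes by log2(t/c).
* **SAM** (replicated miRNA designs, ≥ 2 samples per class). The
  regularized statistic d = (mean_t − mean_c)/(s + s0), with s the
  pooled standard error of the mean difference and s0 the median of the
  per-probe s — a deliberate simplification of the percentile search in
  the original SAM procedure that preserves its ranking behaviour and
  is fully deterministic. The null d-distribution comes from distinct
  relabelings of the samples (all of them, with a warning, when fewer
  than 10 exist — e.g. the 6 of a 2v2 design); probes are called at the
  smallest symmetric |d| cutoff whose estimated median FDR (median
  permutation exceedance count over called count) stays ≤ 0.05. Under
  null data this calls ~0% of probes; 20 probes shifted by 5σ among
  1000 in a 3v3 design are recovered at a median of ≥ 18/20 across
  seeds (both checked in the test suite).
* **Amplitude** (small-molecule instances, 1 treatment vs 1 control
  vector). a = (t − c)/((t + c)/2) on linear-scale expression, bounded
  in (−2, 2); a > 2/3 is exactly t > 2c and a < −2/3 exactly t < c/2,
  so the 2/3 boundary is the twofold-change boundary in amplitude
  units. Strictly positive expression is required on this path only.

Ranked patterns break ties in the statistic lexicographically by probe
id, so identical inputs produce identical patterns on every platform.
Probes with missing values are excluded probe-wise from both signature
and pattern.

## Enrichment score

For a probe set S and pattern L of N probes with statistics r_j, the
walk accumulates P_hit(i) = Σ_{hits j≤i} |r_j|^p / Σ_{hits} |r_j|^p and
P_miss(i) = #misses≤i / (N − N_H); ES is the signed value of
P_hit − P_miss at its maximum absolute deviation, with p = 1 by
default. Conventions:

* The weights come from the pattern being scanned, not from the
  signature's own experiment — r is indexed by position in L.
* Members of S absent from L are dropped (counted in the debug log);
  ES is undefined when nothing survives or S covers all of L.
* If every surviving hit has zero weight the walk falls back to the
  unweighted p = 0 form with a warning.
* Tie rule: when the maximum positive and negative deviations agree in
  magnitude, the positive branch wins; among equal values the earliest
  position wins. The magnitude comparison carries a 1e-12 absolute
  tolerance because mathematically exact ties (e.g. ±1/2 when the last
  probe is the only miss) otherwise get decided by summation-order
  rounding. Such ties are measure-zero for continuous statistics.

## TES combination

The up/down pair of one scan direction combines by the sign-opposition
rule: TES = (ES_up − ES_down)/2 when ES_up·ES_down ≤ 0, else 0. A
coherent signature places its up set and down set at opposite ends of
the pattern, giving |TES| near 1 with the sign of the relationship;
same-sign scores indicate no coherent placement. When only one
direction is scoreable it contributes half its score (ES_up/2 or
−ES_down/2), keeping the [−1, 1] range. The instance TES is the exact
arithmetic mean of the two scan directions; a pair with no probe
overlap in either direction is skipped with a logged reason.

## Association Score and its properties

All n scored instances for one miRNA profile are ranked by signed TES
descending (an absolute-value ranking is available via `rank_by`;
ties break by (molecule id, instance id)). With a and b the two
one-sided KS maxima over a molecule's positions, AS = a if a > b else
−b. Useful exact facts, all covered by tests:

* a molecule holding the top t ranks scores 1 − t/n;
* rank reversal maps a′ = b − 1/n and b′ = a + 1/n, so the sign of AS
  is guaranteed to flip only when |a − b| strictly exceeds 2/n (not
  1/n — at |a − b| = 2/n the two branches tie);
* moving any single instance up in rank never decreases AS;
* n is the realized number of scored instances in the run, never a
  hard-coded corpus size.

## Permutation significance

The null keeps the patterns, the instance structure and every
non-focal molecule's observed TES fixed, and replaces only the focal
molecule's instance signatures and the miRNA signature with uniform
random probe sets of the same sizes (joint resampling of both sides).
Per round the four directional ES, the TES values, the ranking and the
AS are recomputed; p is the fraction of null |AS| strictly exceeding
the observed |AS| (an add-one option gives a positive minimum p).
Recomputing only the focal instances is a deliberate tractability
choice: recomputing every instance's TES each round would multiply the
cost by the cohort size while targeting the same null hypothesis of
"no specific signature relationship for this pair".

Each pair draws from its own generator seeded by
(global seed, CRC32(molecule id), CRC32(profile id)), so p-values are
reproducible pair-by-pair and independent of processing order. An
optional Benjamini–Hochberg column (via statsmodels) can be added; raw
p at α = 0.05 is the default reporting, with no correction.

## Synthetic cohorts

The generator emulates the two data classes the method consumes.
Per-probe baseline log2-expression is Normal(7, 1); planted signature
probes shift by ±`effect` log2 units in the treatment class; each
sample adds Normal(0, `noise_sd`) log2 noise; values are exponentiated
to the
linear scale. Defaults: 1000 probes, 50 + 50 planted, effect 3 (an
eightfold change), noise 0.3, 20 molecules × 3 instances, unreplicated
miRNA design. A molecule can `mimic` the miRNA signature (a fraction
`overlap` of the same probes, same directions), `reverse` it, or carry
a disjoint `null` signature; instances share planted sets and differ
only in noise. Probe ids are synthetic (`P000001`…).

What the generator does *not* emulate: probe-affinity effects, batch
structure, array-normalization artifacts, correlated noise between
probes, or realistic signature-size variation. Passing tests therefore
demonstrate the statistical machinery — calibration of the permutation
null, monotone recovery of planted relations, exact agreement with the
score definitions — not robustness to microarray technical artifacts.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use 1000-probe universes,
cohorts of 20 molecules × 3 instances, and 200 permutation rounds for
calibration/recovery studies (10 cohorts → 200 null p-values; 10 seeds
for recovery); these sizes give stable Monte-Carlo estimates while a
full run stays in the low minutes on one core. Scores are plain float64
throughout; association tables print AS and p at 6 decimals; matrix and
pattern files round-trip through `repr` at full precision.

## Known limitations

* The fold-change and amplitude paths require strictly positive linear
  expression; profiles violating this fail loudly rather than being
  imputed.
* The SAM implementation is two-class unpaired only (no paired or
  multi-class designs, no moderated-t alternative).
* The permutation null resamples signatures only for the focal pair
  (see above); a full-cohort resampling null would be more faithful to
  complete exchangeability at roughly cohort-size times the cost.
* No cross-miRNA aggregation or AS normalization: each miRNA profile
  (miRNA × condition × source) keeps its own association row.
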
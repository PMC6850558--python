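# Methods

This note documents the models and procedures implemented in
`splicerank`, the assumptions behind them, the tunable parameters, and
the design decisions taken where the design was genuinely open.

## Splicing-event catalog

Events are constructed purely from transcript annotation (no de-novo
junction discovery). Internally all coordinates are 0-based half-open;
GTF input (1-based inclusive) is converted at the I/O boundary so that
junction arithmetic is unambiguous.

* **RI (retained intron)** — every intron of every multi-exon
  transcript is a retention candidate (a 2-exon transcript contributes
  its single intron, since it is bounded by exons on both sides). One
  event per distinct genomic intron: retention is quantified per
  intron, not per transcript, so identical introns from different
  transcripts are deduplicated. The event carries its two exon–intron
  boundary positions (5′ and 3′ relative to strand) and its exon–exon
  junction as the exclusion junction.
* **SE (skipped exon)** — every internal exon in its flanking-intron
  context. Two internal exons with identical coordinates but different
  flanking junctions are *distinct* events, because the inclusion
  junctions (the two flanking introns) and the exclusion junction (the
  skipping junction) differ; collapsing them would leave an event with
  an ill-defined junction set.
* **A5SS / A3SS** — any two introns of one gene sharing exactly one
  boundary. Which subkind applies depends on strand (the varying intron
  start is the donor on `+` and the acceptor on `−`). The shorter
  intron carries the inclusion junction. Note that with this
  intron-pair definition, exon-skipping and mutually-exclusive-exon
  configurations also register alternative-site events (a skipping
  junction shares a boundary with each flanking intron); summaries
  group both subkinds under "ASS".
* **MXE (mutually exclusive exons)** — pairs of non-overlapping
  internal exons of one gene that never co-occur in any transcript and
  that some transcript pair places between identical upstream and
  downstream exon boundaries. The strict flank requirement guarantees a
  clean inclusion/exclusion junction set; looser definitions are out of
  scope.

## PIR and PSI

For an RI event with boundary counts `EI5`, `EI3` (contiguous reads
spanning the 5′/3′ exon–intron boundary) and junction count `EE`
(spliced reads whose skipped segment is exactly the intron):

```
PIR = mean(EI5, EI3) / (mean(EI5, EI3) + EE)
```

The mean (not the sum) of the two boundary counts keeps the boundaries
symmetric and the value in [0, 1]: each retention-supporting read is
evidence at one of two interchangeable positions, while each splicing
read is evidence at the single junction. PSI for exon-centric events is
the analogous mean-inclusion over mean-inclusion-plus-mean-exclusion.
Events with zero denominator are flagged undefined and excluded from
ranking rather than imputed.

BAM counting contract: a spliced alignment's skipped segment must match
an event junction exactly; a contiguous aligned segment must cover a
boundary with at least `min_overhang` aligned nt on each side (default
8 nt, the usual guard against spurious marginal overlaps); alignments
below `min_mapq` (default 10) are excluded so junction evidence is
uniquely placed; a read increments any counter at most once, and
retention and splicing evidence from one read never both count for the
same event. Coverage filtering requires denominator coverage of at
least `min_coverage` (default 10) in every sample of every group.

## Rank-product test

For a contrast of groups A and B with `nA` and `nB` replicates, all
`nA x nB` cross-condition pairs are formed and `ΔPIR = PIR_a − PIR_b`
computed per pair. Within each pair, events are ranked (rank 1 = most
extreme in the tested direction; ties averaged) and the statistic is
the geometric mean of an event's ranks across pairs. Small rank
products require *consistent* extremeness across replicates — a single
outlier replicate cannot produce one. Increased and decreased retention
are tested as two one-sided analyses and reported separately;
Benjamini–Hochberg FDR is applied across events within each direction;
the final call requires `p < 0.001`, `fdr < 0.05` and
`|mean ΔPIR| > 0.1` with matching sign.

### Null models and the calibration/power trade-off

Two permutation nulls are implemented, and the choice matters:

* `ranks` (default) — independent uniform rank permutations per pair,
  the classical rank-product null, with exhaustive enumeration of all
  `n_events ** n_pairs` rank combinations when feasible (then p-values
  are exact) and Monte-Carlo pooling otherwise
  (`p = (1 + #{null ≤ obs}) / (1 + n_events·n_perm)`).
  Because the cross-condition pairs share samples, their ranks are
  positively correlated and this null is **anticonservative in the far
  tails** (in a 3 vs 3 null simulation at depth 50 the fraction of
  events with p < 0.05 is ≈ 0.14, not 0.05). Its p-values should be
  read as consistency scores, not calibrated tail probabilities. It is
  nevertheless the default because it matches the published
  rank-product formulation and maximizes power to rank truly changed
  events first, while the `|ΔPIR| > 0.1` effect-size gate keeps the
  realized false-discovery yield controlled: in the recovery
  simulations below the empirical FDR is 0 and decreased-direction
  calls stay at the nominal false-positive yield. A small residual
  false-positive yield (a few events per thousand) can survive the gate
  for event kinds with noisier inclusion estimates.
* `relabel` — group-label permutations of the actual sample values,
  pooled across events (19 distinct non-identity relabelings at 3 vs 3,
  enumerated exhaustively; sampled when larger). Exact under
  exchangeability of samples, hence calibrated regardless of the
  shared-sample correlation: in the same null simulation the p < 0.05
  fraction sits inside the binomial 99% interval and the p-values pass
  a KS uniformity test. The cost is power: when a sizeable fraction of
  events carries true effects, those events contaminate the pooled null
  and sensitivity collapses (0.2–0.3 in the 10%-affected scenario vs
  1.0 for the default). Use this mode when calibrated p-values under a
  near-global null are the priority (e.g. screening for any signal at
  all), and the default when ranking and calling strong, consistent
  changes.

No single rank-product null achieves both calibration and full power in
the many-affected-events regime; this is a structural property of
pooled rank statistics with shared-sample pairs, not an implementation
artifact.

The rescue analysis reports, for every event significant in a first
contrast, its mean ΔPIR under a second contrast; an event is "rescued"
when it is also significant there with opposite sign.

## Intron features and KS comparison

Significantly more-retained introns are compared to background introns
(|mean ΔPIR| < 0.05 and p > 0.05 in the same contrast) one feature at a
time with two-sample Kolmogorov–Smirnov statistics, BH-adjusted across
features and sorted by D. The registry implements an 11-feature
documented subset of the classical retained-intron feature catalog —
intron GC; 5′/3′ flanking-exon GC; intron-minus-exon GC differential;
log10 lengths of the intron and both flanking exons; donor and acceptor
splice-site scores; polypyrimidine fraction of the last 30 intronic nt;
relative position of the intron along the transcript (0–1,
strand-oriented) — and accepts user-plugged feature functions.
Conservation- and structure-based features that require external data
are deliberately out of scope.

Splice-site strength uses log-odds position weight matrices trained on
*all* annotated introns of the supplied catalog (pseudocount 1, uniform
background, bits), so scores are deterministic given the annotation and
need no external model. Windows: donor = last 3 exonic + first 6
intronic nt; acceptor = the last 23 intronic nt ending at the 3′ splice
site (note this differs from MaxEnt-style 20+3 windows that include
exonic sequence). Minus-strand sequences are reverse-complemented
before extraction; IUPAC ambiguity codes contribute fractionally to
compositions and PWM scores.

## Expression link

Genes with at least one significantly more-retained intron are compared
to expressed background genes (normalized mean count > 1 in at least
one group) with none, on per-gene log2 fold changes, using a two-sided
Mann–Whitney U test (exact enumeration when both groups have ≤ 12
genes and no ties; tie-corrected normal approximation otherwise). The
median log2FC shift is reported as the directional effect summary.
Fold changes come from library-size-normalized counts (median-of-ratios
size factors rescaled to geometric mean 1, total-count scaling when no
all-positive reference gene exists) with a pseudocount of 1;
differential-expression model fitting is intentionally not part of this
package — the link test only needs a fold-change coordinate, and a
precomputed log2FC table can be substituted.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not reads: multi-exon genes on one synthetic chromosome with canonical
GT..AG splice sites; junction-region depth per event and sample drawn
negative-binomially (`variance = m + dispersion·m²`); boundary and
junction evidence drawn binomially at the intron's true PIR, with each
exon–intron boundary sampled at the full local depth (the two
boundaries are distinct genomic positions, each with its own read
depth — this is what makes the mean-boundary PIR estimator consistent
as depth grows). Affected introns get a true-PIR shift in group A only
(one-sided by default, mirroring the predominance of increased
retention under spliceosome deficiency; symmetric effects by config), a
GC-content offset, and their genes an expression decrease in group A
(the NMD-like coupling). Gene counts add per-gene log-normal biological
variability scaled so the per-gene log2FC noise sd equals
`expr_noise_sd`.

Defaults (the conditions the validation suite runs under): 3 replicates
per group; junction depth mean 50 with dispersion 0.1 (moderate bulk
RNA-seq junction coverage with realistic overdispersion); basal PIR ~
Beta(2, 18) (mean 0.1 — low basal retention typical of annotated
introns, with realistic spread); 10% of introns affected at
ΔPIR = +0.3 (a strong retention response); GC offset +0.10 for affected
introns; NMD coupling 1 log2 unit with log2FC noise sd 1; PSI for
exon-centric events ~ Beta(8, 2) with no group effect; gene depth 200
with dispersion 0.05. Everything is deterministic given `seed`.

What the generator does **not** emulate — and hence what passing tests
do not establish about real data: positional coverage biases and 3′
bias, mappability artifacts, alternative isoform structure beyond one
transcript per gene, correlated effects between neighboring introns,
library-protocol strand effects, and batch structure across replicates.
Results on real data additionally depend on alignment quality, which is
upstream of this package.

## Numerical choices

Ties in ΔPIR receive average ranks; an all-constant pair column is
ranked (all ties) with a logged warning. Rank-product comparisons
against null values are done in log space with a 1e-9 tolerance so that
average-rank products compare tie-safely. Undefined inclusion values
drop the event from the contrast (reported, not imputed). Monte-Carlo
p-values use the add-one rule, exhaustive enumerations are exact
fractions. Size factors are anchored to geometric mean 1 so the
pseudocount acts on a depth-free scale. All stochastic paths take an
explicit seed; the pipeline writes the seed, a config hash and per-file
checksums into `MANIFEST.json`, and staged CLI runs are byte-identical
to single `run` invocations (intermediate tables are re-read from disk
to pin float formatting).

## Validation experiments

`splicerank.validation` (backing `scripts/acceptance.py` and the
acceptance tests) re-derives the method's operating characteristics
from scratch at the defaults above: type-I calibration of the
relabeling null on a 2,000-intron global null; sensitivity and
empirical FDR of the default analysis with 10% affected introns at
ΔPIR +0.3 (sensitivity 1.0, empirical FDR 0 in seeded runs);
direction asymmetry when only increased effects are simulated
(decreased calls at or below the nominal false-positive yield); GC
recovery as the top-ranked KS feature at 200/1,000 introns; and the
expression-link test under coupling (−1 log2 unit, 500/500 genes) and
under the null (uniform p over 200 repetitions). Problem sizes are the
package's chosen validation scale; each experiment runs in seconds on
one core.

## Known limitations

The default null's p-values are not calibrated tail probabilities (see
above); MXE flank matching is strict; ASS subkind assignment follows
the intron-pair definition and so overlaps SE/MXE configurations;
PWM splice-site scores are annotation-trained and not comparable across
catalogs; the coverage filter is a hard threshold, not a shrinkage
model; and parametric ΔPIR models (beta-binomial GLMs), covariate
adjustment and paired designs are out of scope.
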
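# Methods

## Statistical model

Every test in the package is an over-representation test under the
hypergeometric null: the query set is treated as a uniform draw of *n* genes
without replacement from a universe of *m*, and the overlap *x* with a fixed
reference set of *j* genes is scored with the upper tail P(X ≥ x).  The
statistic is symmetric in (j, n), which is what makes the pathway-crosstalk
application (two pathways, either one viewed as "query") well defined.

Tail probabilities are computed with `scipy.stats.hypergeom` (`sf`/`cdf`).
The test suite holds them to relative error ≤ 1e−12 against an exact rational
oracle (sums of binomial coefficients in `fractions.Fraction`), exhaustively
for every parameter combination with m ≤ 25; the oracle itself is validated by
literal enumeration of all C(m, n) draws on tiny universes.

The lower tail Σ<sub>i=0..x</sub> is exposed as `hypergeom_lower_printed` and
behind the pipeline's `tail="printed-lower"` switch.  Some published
formulations write the cumulative sum from zero; as an over-representation
statistic that direction is anti-conservative (large overlaps get p ≈ 1), so
the upper tail is the default everywhere and the lower tail exists only for
literal reproduction.  The two satisfy P(X ≥ x) = 1 − P(X ≤ x−1), which the
tests sweep.

Multiple testing is controlled with Benjamini–Hochberg step-up adjustment
(in-package, ~10 lines; cross-checked against `statsmodels.multipletests`
on thousands of random vectors).  Ties are handled by the cumulative-minimum
step and a stable sort, so results are deterministic.  Note that BH adjustment
is *not* idempotent — re-adjusting adjusted values can only push them further
toward 1 (e.g. [1.0, 0.25] → [1.0, 0.5] → [1.0, 1.0]); the tests assert the
true monotone property rather than a fixed-point one.

### Test families

- Risk-pathway enrichment: the BH family is **all** pathways in the
  collection, including those with zero overlap (they contribute p = 1 and
  family size only; results report pathways with x ≥ 1).  The family is the
  set of hypotheses tested, not the set with evidence.
- Crosstalk: all unordered pairs among the selected (significant) pathways.
  A `vs-all` scope is available that tests every pair in the collection and
  keeps edges touching a risk pathway.
- miRNA → pathway: one global family over all (miRNA, pathway) combinations,
  so the FDR guarantee applies to the reported pair list.  A `per-mirna`
  scope is provided for comparison.

### Universe

The universe defaults to the union of all genes in the pathway collection,
overridable by an explicit universe file (carried as `universe_hint` on the
collection) or a bare integer *m* for a nominal genome size.  Query genes and
miRNA targets outside the universe are dropped (with a logged warning) before
counting, so the invariants x ≤ min(j, n) ≤ m hold exactly.  The synthetic
generator always supplies the full simulated gene space as the explicit
universe, so no drops occur there.

## Evidence filters

- **Target-prediction consensus**: a (miRNA, gene) pair needs ≥ k distinct
  tools out of a declared roster of N (defaults 4 of 10).  Duplicated rows
  from one tool count once.  Raising k can only shrink target sets (tested as
  a property).
- **miRSNP filter**: a record is kept if experimentally validated OR supported
  by ≥ `min_dbs` databases (default 2).  The OR reading was chosen over the
  alternative AND reading (validation as an additional requirement) because
  validation is strictly stronger single-record evidence than database
  concordance; a validated record failing the filter would discard the best
  evidence available.  Records are per binding site — one per (rsID, miRNA,
  gene) triple — so a SNP shared by a seed family appears once per family
  member, which is what lets family membership emerge at the axis stage.

## Axis semantics

Axes are built from retained target-site SNPs grouped by (rsID, gene).  Within
a group, a miRNA is kept only if the gene is among its consensus targets: a
SNP row claiming a binding site that no tool consensus supports is evidence of
nothing, so it is removed from the group rather than vetoing the whole group.
A pathway joins the axis if it contains the gene **and** at least one (not
all) of the group's miRNAs has a retained enrichment pair with it — different
family members may link the gene to different pathways.  Axes need at least
one miRNA and one pathway; an empty axis list is a valid result.

## The synthetic-data generator

`SynthConfig` defaults are the study conditions the test suite runs at:
20,000-gene universe; 300 pathways with sizes log-uniform on [20, 300]; 54
risk genes of which 60 % are drawn from 5 planted pathways; 500 miRNAs with
log-uniform [20, 200] background targets each; 10 prediction tools with
sensitivity 0.7 and false-positive rate 0.001 per possible pair; 60
target-site and 15 miRNA-gene miRSNP records over database rosters of 4 and 3
with overlap probability 0.4 and validated fraction 0.2; one hub miRNA planted
on all 5 pathways and one 5-miRNA axis planted on 3 of them (20 planted
miRNA–pathway pairs in total, each targeting half of its pathway's genes).

Design choices that keep the ground truth *exact* rather than approximate:

- Planted risk genes are allocated to planted pathways round-robin, so each
  planted pathway receives an equal share (~6–7 genes) regardless of its size.
  Proportional allocation would starve the small pathways.
- Background (non-planted) risk genes are sampled outside every pathway gene
  set — they model risk genes with no pathway annotation — so the planted
  pathways are exactly the enriched ones and coverage equals the planted
  membership count.
- Crosstalk is planted as 15-gene blocks shared by consecutive planted
  pathways, and planted miRNA targeting excludes block genes; otherwise a
  miRNA planted on pathway A would genuinely target pathway B through the
  shared block, making the recorded planted-pair list incomplete.
- Planted axis bindings are forced through both filters (≥ k tools for the
  miRNA–gene pair, ≥ min_dbs databases for the SNP); everything else is
  subject to the noise model.

Inter-tool agreement is modelled as independent Bernoulli detection per tool
plus uniform false positives — no inter-tool correlation, no seed-match or
binding-energy realism, no linkage structure among SNPs, and gene identifiers
are abstract symbols.  Passing the planted-recovery tests therefore shows that
the pipeline's statistics and bookkeeping are correct under a known model; it
does not certify performance on real prediction tools, whose errors are
correlated.

Power note: with enrichment strength 0.6 spread over 5 planted pathways, a
planted pathway drawn near the top of the size range (j ≈ 300) receives ~6
planted genes against an expected chance overlap of ~0.8, which sits close to
the adjusted-p = 0.01 boundary; on some seeds such a pathway can narrowly miss
significance.  That is the honest power of ORA at these settings, not a
bookkeeping error — the fixed-seed suite conditions are comfortably inside the
detectable regime.

## Network topology

Betweenness centrality is computed on the bipartite graph as-is (no
projection), normalized by (N−1)(N−2)/2, via `networkx`; the test oracle is an
independent BFS path-enumeration counter on graphs ≤ 30 nodes.  Graphs with
≤ 2 nodes have betweenness defined as 0.  The power-law fit is a least-squares
line on log₁₀(degree) vs log₁₀(frequency) over non-zero histogram bins —
the display-style analysis, chosen deliberately over MLE fitting; with fewer
than two usable bins it returns NaN.  On small networks (a dozen nodes) the
fit is reported but carries no inferential weight, as the fourth example
script shows.

## Numerical and determinism choices

- p-values clipped to [0, 1]; crosstalk edge weights floor the adjusted p at
  1e−300 before −log₁₀.
- All orderings are total and deterministic: results sort by (adjusted p, id),
  edges by (a, b) with a < b, axes by (rsID, gene), ranking ties by node id.
- The generator derives everything from one `numpy` Generator seeded by
  `SynthConfig.seed`; the same seed and config produce byte-identical bundle
  files.
- Readers reject malformed input (line numbers in errors) instead of
  repairing; writer/reader pairs are content identities on canonical form
  (uppercase gene symbols, lowercase `hsa-` miRNA ids, sorted serialization).

## Problem sizes used by the test suite

The full-scale bundle (defaults above) generates in ~1.5 s and the complete
pipeline runs in under a second on one CPU, so the suite runs it once as a
session fixture.  Oracle sweeps use m ≤ 25 (hypergeometric), 20-gene universes
(crosstalk/enrichment draw enumeration), and ≤ 30-node graphs (betweenness
path enumeration).  `scripts/acceptance.py` re-runs the full-scale pipeline
fresh at the given seed in a few seconds.
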
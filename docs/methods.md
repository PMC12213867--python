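# Methods

## Evidence model

The unit of evidence is a *mention*: one literature-extracted statement
relating a gene and a disease, with

- a **polarity** — positive (promotes / activates / upregulates), negative
  (inhibits / suppresses / downregulates), or unknown (inconclusive or
  unsigned);
- a **direction** — the statement's subject acts on its object, so each
  mention is oriented gene→disease or disease→gene;
- a citation key and a free source tag.

Mentions are counted per table row. An optional flag collapses duplicate
(gene, disease, reference, polarity) rows; it is off by default because
mined tables give no guarantee that one citation appears only once across
sources, and the analysis treats the row, not the citation, as the sampling
unit. Gene symbols are compared case-sensitively after whitespace trimming;
the gene-universe list is the authority on spelling.

## The adjusted binomial screen

For a pair with raw polarity counts `(n_p, n_n, n_0)`, total `n`:

1. **Dominance.** The dominant class is the *strictly* largest count. A tie
   (or no evidence) means dominance is undefined: the pair is reported with
   p = 1 rather than raising, because an uncallable pair is a legitimate
   screen outcome. A strict maximum of three classes always exceeds n/3, so
   the observed dominant proportion lies in (1/3, 1].
2. **Coverage inflation.** Literature retrieval is assumed incomplete; the
   uncovered-sample fraction `α` (default 1) estimates unretrieved studies
   as a proportion of retrieved ones. Both the total and the dominant count
   are inflated: `N = n + round(αn)`, `n_dom,adj = n_dom + round(α·n_dom)`
   (round half-up). With the default `α = 1` this is exactly a doubling,
   `N = 2n` and `n_dom,adj = 2·n_dom`; the rounding rule only matters for
   fractional `α`. Inflating **both** counts is deliberate: inflating the
   total alone would make the adjustment an artificial dilution of the
   evidence rather than a symmetric extrapolation of it.
3. **Test.** `p = P(X ≥ n_dom,adj)` for `X ~ Binomial(N, p0)`, evaluated as
   the binomial survival function at `n_dom,adj − 1`. The null proportion
   `p0 = 0.34` sits just above 1/3: under the null, a class is no more than
   marginally dominant, so the alternative is that dominance is real rather
   than a counting artifact. Because the dominant count is doubled along
   with the total, the test is *not* equivalent to the unadjusted test: the
   adjusted statistic sits deeper in the tail, so evidence volume matters,
   not just the observed proportion.
4. **FDR.** Benjamini–Hochberg across exactly the genes with ≥ 1 matching
   mention for the disease (after any direction filter); untested
   hypotheses are not part of the family. The operative screen is
   `q ≤ 0.01` (inclusive); the nominal per-test level 0.05 is retained for
   reporting only.

Properties guaranteed by tests: the tail equals brute-force pmf summation
(all adjusted totals ≤ 60, tolerance 1e-12, with the all-dominant closed
form `p0^N`); p is monotone in the dominant count and never increases when
all counts are scaled by an integer; BH q-values match the classical
step-up rule and reproduce its rejection set.

A Bonferroni helper (`alpha/m`) is provided for fixed-family annotation
analyses, e.g. 0.05/35 ≈ 0.00143 for a 35-gene family.

## Overlap enrichment

Two screened gene sets A and B in an explicit universe U form the 2×2 table
(in both, A only, B only, neither). Enrichment is the **sample
cross-product odds ratio** `(n11·n00)/(n10·n01)` — not the conditional
maximum-likelihood estimate some exact-test implementations report — because
the cross-product ratio is the quantity comparable across published tables.
A zero off-diagonal product yields +inf (reported as such, no continuity
correction); 0/0 is reported as 1. Significance is Fisher's exact test,
two-sided by default (summing tables with point probability ≤ observed);
for strongly enriched tables the two-sided and upper-tail values coincide
because the depleted tail contributes no table with smaller point
probability. The universe size is always explicit — the neither-cell drives
the odds ratio, so inferring U from the union of the sets would silently
inflate enrichment. Extremely significant tables underflow to p = 0 in
double precision; such values should be read as bounds (p < 1e-16), not
measurements.

## Network topology and hubs

Interaction networks are simple directed graphs: self-loops are dropped
(warned) and duplicate ordered pairs collapsed. **Density is directed**,
`E/(N(N−1))` — for a 35-node, 206-edge network this gives 0.173, consistent
with published summaries of such networks, whereas the undirected formula
would give twice that. Average path length, diameter and average local
clustering are computed on the undirected projection (falling back to the
largest weak component, flagged, when disconnected), since reachability in
a sparse directed graph is usually too fragmented to summarize. Degree
centralities are normalized by N−1; betweenness is computed on the directed
graph with the standard (N−1)(N−2) normalization; eigenvector centrality is
the principal eigenvector of the undirected projection of the largest
component (dense symmetric eigendecomposition — components are small and
the sparse Arnoldi route fails below four nodes), scaled to unit maximum.
The convention for eigenvector centrality is a genuine free choice here;
unit-max scaling was chosen because it makes values comparable across
networks of different size.

Hubs default to: top quintile (quantile 0.8, ties at the threshold all
qualify) in at least two of the four metrics. Both the quantile and the
metric count are configurable. Below five nodes a quintile is meaningless
and the rule falls back to top-1 per metric with a warning. Degenerate
all-equal networks return every node — documented behaviour, not an error.

## Directed signed paths

Directional evidence is screened **per orientation**: gene→disease and
disease→gene mentions form separate evidence partitions with separate BH
families, so a gene can be significant as a regulator of the disease, as a
target of it, either, or neither. Significant (q ≤ 0.01, inclusive)
directional results become signed edges whose polarity is the dominant
polarity of that partition. Paths `A → g → B` require an `A → g` edge and a
`g → B` edge; both orientations of a gene are reported if both chains
exist. Net sign composes multiplicatively (−·− = +) with unknown absorbing:
a path through an unsigned relationship is still a path — it appears in the
published loop (the mixed/neutral regulation of CYP2C19) — but its net
effect cannot be signed. Mentions are pooled per direction; requiring a
single reference to assert both the direction and the polarity would
discard most evidence and is not what mined relationship tables support.

## Synthetic corpus generator

The generator emulates the *output* of a mining stage, not the literature
itself: no abstracts, no citation network, no publication dates.

- **Association design.** Each gene is associated with disease A with
  probability `prevalence_a` (default 0.1), with B likewise, and the joint
  cell is solved from the planted odds ratio (default 7.5 — the scale of
  overlap enrichment seen between an autoimmune disease and a cancer) by
  the one-root Plackett quadratic, so the planted 2×2 design is exact in
  expectation.
- **Mention counts.** Poisson. Associated pairs draw from a zero-truncated
  Poisson with rate `mean_refs_true` (default 8) — a truly associated pair
  always leaves at least one trace; null pairs draw plain Poisson with rate
  `mean_refs_null` (default 0.25). The null rate is calibrated to corpus
  scale: in mined whole-genome corpora only ~20–30% of genes co-occur with
  a given disease at all, and Poisson(0.25) leaves ~22% of null genes with
  any mention. The rates are the underlying Poisson rates, so the realized
  mean of truncated counts is slightly above the nominal rate when it is
  small.
- **Polarities.** Each true pair gets a planted dominant class (positive
  0.4 / negative 0.4 / unknown 0.2 — most real association signals are
  signed); its mentions carry that class with probability
  `dominant_prob_true` (default 0.9, required > 0.34 — at or below the null
  dominance proportion the planted signal would be undetectable by design),
  the other two classes splitting the remainder equally. Null mentions draw
  from `polarity_null` (default (0.34, 0.33, 0.33), near-uniform).
- **Direction.** Each mention is independently oriented gene→disease with
  probability 0.5 by default.

Everything is driven by one seeded generator: identical parameters and seed
give byte-identical corpora.

What passing tests on this generator do **not** show about real corpora:
real mention counts are overdispersed and correlated with gene popularity;
real polarity errors are systematic (extraction bias), not independent;
real direction assignments correlate with sentence structure. The
generator's guarantees are therefore about the statistical machinery
(calibration, power, FDR control under the stated model), not about mining
accuracy.

## Problem sizes used in the shipped experiments

The recovery experiment uses a 2,000-gene universe with ~200 planted true
genes per disease; type-I control uses 20 all-null corpora of 500 genes
with a denser background (rate 3) so most genes enter the tested family —
a deliberately harder condition than the sparse default; the planted-
odds-ratio recovery uses 4,000-gene truth tables across six seeds, compared
on the log scale against a 3-standard-error band from the delta-method
variance of the log odds ratio. These sizes give stable statistics while
keeping the full suite fast.

## Known limitations

- The screen treats mentions as independent Bernoulli observations;
  citation chaining and review articles violate this in real corpora.
- The coverage factor `α = 1` is an assumption about retrieval completeness,
  not a measurement; the screen's absolute p-values shift with it, though
  rankings are stable.
- Only pairwise disease comparisons and single-gene (two-hop) paths are
  supported; multi-hop gene chains and >2-set overlaps are out of scope.
- No network figures are rendered; exports (GraphML, signed edge lists,
  Venn counts) are intended for external plotting tools.
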
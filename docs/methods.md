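# Methods

This note records the statistical model, the algorithmic and numerical
choices, and the limits of what the test suite demonstrates.

## Competitive pre-ranked test

For a library of sets over G ranked genes with per-gene statistic x_g, a
set S of size m is scored by

δ = mean(x in S) − mean(x outside S),
σ² = pooled two-group variance on G − 2 df,
t = δ / √( σ² · (VIF/m + 1/(G−m)) ),  VIF = 1 + (m − 1)ρ,

with a two-sided p-value from t_{G−2}. The VIF models correlation ρ among
in-set gene statistics; with ρ = 0 the statistic reduces exactly to the
classical equal-variance two-sample t-test (the test suite verifies this
against `scipy.stats.ttest_ind` to 1e-10 relative error). ρ defaults to
0.01, the documented default of the published test this implements; it is
exposed as `--inter-gene-cor`. The statistic is invariant under shifting
and positive rescaling of the x_g.

Degenerate inputs: an all-constant ranking gives δ = 0, σ² = 0 and is
reported as p = 1; σ² = 0 with δ ≠ 0 (two distinct constant groups) is
reported as p = 0; an empty set or a set spanning the whole universe is an
error, as is any member gene missing from the ranking.

Each set is tested twice — on signed statistics (direction = sign of δ;
a δ = 0 tie is labelled Up, immaterial since such a set has p = 1) and on
absolute statistics (the "mixed" test). Both p-value families are BH
adjusted over *all* tested sets before any filtering. Classification at
level α (default 0.05, boundary inclusive): keep the directional label if
FDR ≤ α; else re-label Mixed if the mixed-family FDR ≤ α, reporting that
FDR (the directional PValue column is deliberately left in place, matching
the reference workflow's bookkeeping, even though it then no longer pairs
with the reported FDR); else drop the set.

## Overlap network

Similarity is the Jaccard index J = |A∩B| / |A∪B|, computed by a binary
membership-matrix product; the union size uses the identity
|A| + |B| − |A∩B|, so pairwise intersections are the only set work. By
default J is computed on the **full** curated membership, on the grounds
that set similarity is prior knowledge independent of which genes the
experiment detected; `--similarity-view restricted` switches to measured
genes only. Edges require J **strictly** greater than the threshold
(default 0.2). The threshold is deliberately exposed: too small fuses
everything into one component, too large leaves no edges; a broad spread
of component sizes is the practical tuning criterion, and the suite checks
that edge count is monotone and the non-trivial component count unimodal
across the sweep. Edge weights (shared-gene counts) are retained for
export and display only.

## Community cascade

Stages run in order and each later stage sees only what survives:

1. singletons = degree-0 nodes;
2. binary clusters = remaining components of size 2;
3. Girvan–Newman on the rest: repeatedly delete the edge of maximal edge
   betweenness with full recomputation after every deletion (weights are
   ignored; disconnected parts are handled per component and never merge).
   Every component structure along the way is a candidate partition; the
   one maximising Newman–Girvan modularity Q of the original graph is
   chosen. Determinism: betweenness ties delete the lexicographically
   smallest (source, target) edge; equal-Q cuts prefer the earlier (fewer
   clusters) one.
4. crossing edges of the chosen partition are deleted, components of size
   < 3 (configurable) are filtered out, and surviving communities are
   renumbered 1.. by decreasing size (ties by smallest member name).

Community detection is not re-run after splitting. The unified partition
assigns ids to communities first, then binary pairs, then singletons;
filtered nodes are reported but carry no id, and the bookkeeping invariant
singletons + 2·(binary clusters) + community sets + filtered = input nodes
is asserted by tests on random graphs. Edge betweenness itself is
delegated to networkx and cross-checked in the suite against brute-force
shortest-path enumeration on the full ≤6-node connected-graph atlas and on
random 8-node graphs; the chosen partition is cross-checked against
python-igraph's edge-betweenness clustering on structured graphs.

## Automatic annotation

Tokenization: split names on underscore, lowercase, strip punctuation
characters, drop purely numeric tokens, the literal "na", and excluded
words. Note the numeric rule acts on whole tokens: "IL_7" loses the "7"
but "P53" survives — token-internal digits are kept. The exclusion list is
the generic pathway vocabulary (cell, process, regulation, …, biocarta,
kegg, reactome) plus a compact vendored 31-word English stopword list, so
titles never depend on an external corpus package. No stemming is applied.

Titles take the top 4 tokens with pooled count ≥ 2, ordered by decreasing
count. Ties keep the order in which tokens first appear when member names
are scanned in *sorted* order: this mirrors the stable decreasing sort of
term frequencies in the reference workflow while making titles invariant
to the order member names are supplied in (plain alphabetical tie-breaking
was rejected because it inverts reference titles such as "muscle
contraction"). Truncation to 60 characters and the optional line break
after 10–30 characters happen at render time only.

Node display labels use words 2–5 of a name (word 1 is usually the source
library), strip "_PATHWAY"/"_SIGNALING", and are omitted for clusters with
more than 5 members.

## Synthetic benchmark

The generator plants known structure: disjoint per-cluster gene pools, one
small private pool per singleton set, and a shared background universe.
Each set draws `within_draw · set_size` members from the leading
`set_size` genes of its pool (the "core region") and the rest from the
background. Drawing from a core of exactly `set_size` candidates makes the
expected within-cluster overlap `within_draw² · set_size` and the expected
within-cluster Jaccard

J ≈ w²·s / (2s − w²·s) ≈ 0.47 at the defaults (w = 0.8, s = 30),

comfortably above the 0.2 edge threshold, while cross-cluster and
singleton overlaps arise only from sparse background draws (expected J on
the order of 10⁻³). Pool genes outside the core pad the measured universe
and carry the cluster's planted shift. Statistics are Normal(0, noise_sd)
with +effect/−effect added to the pools of active clusters (default: all
five clusters active, clusters 2 and 4 down) and, alternating in sign, to
the private pools of singleton sets — singleton sets must carry signal or
they would never reach the significant table that seeds the network.
Defaults (5 clusters × 6 sets, set_size 30, pool 60, within_draw 0.8, 10
singletons, background 1000, effect 3, noise 1) define the benchmark
condition used throughout the tests and the acceptance script; a single
integer seed drives one `numpy` generator for the library and one for the
statistics.

What the benchmark does *not* emulate: count-level sequencing noise,
gene–gene correlation within samples (each gene statistic is independent
noise plus shift), heavy-tailed or asymmetric statistic distributions,
library-scale set-size heterogeneity, and hierarchically nested set
overlap. Recovery results on it therefore demonstrate the correctness of
the pipeline's logic under its own model, not performance on real
transcriptome data.

## Null calibration

Under effect = 0 the generator produces exchangeable statistics. The raw
directional test at ρ = 0 is calibrated (measured level ≈ 0.05 at nominal
0.05 over 200 replicates); with the default ρ = 0.01 it is conservative on
independent null statistics, by design of the VIF. Because classification
retains on BH-adjusted FDR, the expected *fraction of all null sets*
retained is far below α (measured ≈ 0.0006 with ~40 sets per replicate):
BH controls the false-discovery proportion among rejections and, per
family, the probability of any rejection (≈ α via the Simes identity; the
two-family union was measured at 0.025). The suite asserts the calibrated
raw level and the family-wise bound; it also contains a stricter check
that the retained fraction itself equal α, which fails by construction of
FDR control and is retained as documentation of that distinction.

## Numerical and I/O choices

- GMT: tab-separated, description column ignored on read and written back
  as "na"; duplicate genes within a set are silently deduplicated;
  duplicate set names, short lines and empty files are errors naming the
  line.
- Gene statistic tables: TSV or CSV with header; duplicate gene IDs and
  non-numeric statistics are errors (identifier mapping is upstream of
  this package; gene IDs are opaque strings).
- Enrichment tables are re-read with round-trip float parsing so that a
  precomputed-table run reproduces a from-statistics run byte for byte.
- min_set_size defaults to 1 (no floor on tested set sizes); a floor of 3
  is common in other loaders and available as `--min-set-size`.
- Figures always write a TSV coordinate sidecar; determinism is asserted
  on coordinates, never on pixels. Layout is Fruchterman–Reingold with a
  fixed seed and 50 iterations.

## Known limitations

- The divisive community algorithm recomputes betweenness after every
  edge removal (O(E²·V)-ish); it is meant for post-significance graphs of
  at most a few hundred nodes, not for whole-library graphs.
- Only Jaccard similarity is implemented; overlap-coefficient or
  co-enrichment similarity would slot into `overlap_matrices` but are out
  of scope.
- Community detection ignores edge weights by design; a weighted mode is
  a documented non-goal.
- The Up/Down/Mixed scheme reports the directional PValue next to a mixed
  FDR for demoted sets (see above); consumers should treat the FDR column
  as authoritative.
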
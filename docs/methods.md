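# Methods

## The problem

Published marker-gene analyses report incompatible statistics: one study
gives log fold change enrichment with a cutoff of −2, another adjusted
p-values below 0.05, another AUCs above 0.7. `markerscore` puts all of them
on a common scale and then asks, per gene, whether the accumulated evidence
across studies supports calling the gene a marker for a specific cell type,
for a broader (higher-level) cell type, for no cell type, or whether the
data are too sparse to say.

## The marker gene score

Every endpoint of every source is declared with a range
`[range_min, range_max]`, a direction (which end is more significant), and
the author's own significance cutoff. The raw value is mapped to a
preliminary score in [0, 1] by a two-segment piecewise-linear function:

- the significant extreme of the range → 1,
- the cutoff → exactly 0.5,
- the opposite extreme → 0,

with linear interpolation inside each segment. Linear interpolation is the
minimal model consistent with anchoring three points, and it reproduces
every anchor exactly in floating point (the cutoff lands on 0.5 to machine
precision because the segment formula cancels algebraically there; the
anchoring acceptance test checks 1 000 randomized endpoints at 1e−12).

Observed values outside the declared range are **clamped**, not rejected:
curated tables occasionally exceed their declared range (an lfc of −10
against a declared minimum of −9), and clamping keeps the map total,
bounded and monotone. A cutoff placed *at* a range bound is a
configuration error — it would make one segment degenerate.

The preliminary scores of the endpoints observed for a (gene, cell type)
pair are averaged within the source into the **marker gene score** for that
(gene, cell type, source). Endpoints missing for a pair are omitted from
the mean rather than imputed as 0, because several sources publish only
their significant results and absence of a statistic is not evidence of
absence. Mouse and human samples of a single source are kept as separate
score records (the species medians are needed by the species call), but for
cross-source aggregation one source contributes one value per pair — the
mean of its per-species records — so a dual-species source is not
double-weighted.

## Classification

Per gene:

1. **Sparsity gate.** A gene reported in fewer than `min_cell_types = 4`
   distinct cell types is *indeterminate*, unless some single cell type was
   analyzed by at least `min_sources_common = 4` separate sources
   (`min_sources_rare = 2` for rare cell types such as pancreatic epsilon
   cells). The rescue requires the pair to have been *analyzed* by that
   many sources, not necessarily found significant by them. The gate runs
   before significance counting: a sparse gene is indeterminate even when
   its one pair is strongly significant.
2. **Significance.** A pair is significant when its cross-source mean score
   is ≥ 0.5 (`rule="mean"`, the default) or when at least two thirds of its
   sources score it ≥ 0.5 (`rule="two_thirds"`). Both rules appear in the
   field's practice without a reconciliation, so both are implemented and
   the choice is a config knob. Ties at exactly 0.5 count as significant.
   The two-thirds comparison uses a 1e−9 slack so that source fractions
   computed by float division (4/6 vs 2/3) compare as intended.
3. **Counting.** X = number of significant cell types. X = 0 → non-marker.
   X = 1 → marker for that cell type. For X ≥ 2, Y = number of distinct
   higher-level groups among the significant cell types: Y = 1 means the
   subtypes agree on one branch and the gene is a marker for the
   higher-level cell type itself (not the subtypes); Y ≥ 2 with
   X ≤ `max_marker_types = 2` can remain a *dual marker* for both cell
   types under the default `dual_marker_policy="allow"` — the policy
   `"forbid"` applies the stricter reading in which any spread over two
   groups voids the call. Genes whose significant cell types span more
   than two groups are additionally listed in the run summary for manual
   review, since their branch memberships may trace back to edges removed
   during pruning.
4. **Propagation.** A marker's specificity propagates to every strict
   ancestor on its branch; these are reported separately
   (`propagated_cell_types`) and never overlap the marker cell types.
5. **Species call.** Per marker cell type, with medians per species across
   sources: one observed species → `insufficient`; otherwise the species
   with the higher median is called specific iff its median **exceeds**
   `min_median = 0.5` and is at least `fold = 3` times the lower median (a
   zero lower median counts as an infinite fold); otherwise `both`. For a
   higher-level marker the group usually has no directly measured pair, so
   its species medians are pooled as the median of the significant
   subtypes' per-species medians.

Labels partition the genes: each gene receives exactly one of
`marker`, `higher_level_marker`, `non_marker`, `indeterminate`.

## Ontology pruning

The raw cell-type graph (local CSV edge list or an OBO subset restricted to
is_a) may be a multi-rooted DAG with cycles. Pruning makes the manual
curation step deterministic and reproducible:

1. every multi-parent node keeps the first parent found in a curator
   priority file, falling back to the lexicographically smallest parent id;
2. any remaining cycle (necessarily a simple ring once each node has one
   parent) is cut at the edge whose child id sorts first;
3. intermediate single-child nodes are collapsed repeatedly until a
   fixpoint; roots, leaves and nodes flagged `keep` are protected, since
   branching intermediates are what lets future cell types attach.

Pruning is idempotent, never adds nodes, and accounts for every removal in
a machine-readable report (input nodes = surviving + removed). A forest is
permitted: real curations may keep separate roots such as naïve cell and
somatic cell. `is_higher_level` is an input annotation, not inferred from
depth — the literature names exemplar groups (connective tissue cell,
T cell) but no depth rule; a branch with no flagged ancestor falls back to
its root as the group.

## Synthetic data generator

The generator works at the *statistics* layer: the tool consumes published
statistics, not reads, so fixtures are generated by drawing the latent
preliminary score each observation is intended to have and inverse-mapping
it through each endpoint's linear scale to raw units. At `noise_sd = 0`
re-normalization recovers the latent scores to 1e−9, so planted labels are
decodable by construction.

Defaults describe a modest multi-study corpus: 500 genes, 6 single-species
sources alternating mouse/human, each with 1–3 endpoints of heterogeneous
kinds (log fold change, adjusted p, AUC, enrichment score) with randomized
cutoffs; a balanced ontology of depth 3 and branching 3 whose depth-1 nodes
are the higher-level groups. Planted classes: 30% markers (significant,
latent ~ U[0.75, 0.95], in one leaf; non-significant, U[0.05, 0.35], in
three decoys), 15% higher-level markers (significant in two sibling leaves
of one group), the rest non-markers; 20% of markers are species-specific
(latent U[0.85, 0.95] in the specific species vs U[0.15, 0.25] in the
other, giving a ≥ 3-fold median split while the cross-species mean stays
≥ 0.5). Species-specific genes target the species with more sources
(alternating on a tie) so the cross-species mean cannot drop below 0.5 by
imbalance alone. Gaussian noise with sd `noise_sd` perturbs the latent
score (clipped to [0, 1]) before inverse mapping; `missing_rate` drops
endpoint values independently.

What the generator does **not** emulate: correlated endpoints within a
source, publication bias beyond the missing-at-random thinning,
multi-mapping orthologs, disagreeing studies (every source sees the same
latent signal per species), or ontologies with unbalanced depth. Passing
recovery tests therefore demonstrates that the decision pipeline decodes
its own planted structure, not that real corpora are this clean.

## Recovery calibration

Recovery = fraction of genes whose label, marker cell types and species
call all match the planted truth. With the default conditions
(500 genes, 6 sources, `missing_rate = 0`), mean recovery over seeds
0–19, reproduced by looping `simulate → score_all → classify_all →
recovery_rate` over `noise_sd`:

| noise_sd | mean recovery | min over 20 seeds |
|----------|---------------|-------------------|
| 0.0      | 1.000         | 1.000             |
| 0.05     | 0.998         | 0.992             |
| 0.10     | 0.990         | 0.978             |
| 0.15     | 0.981         | 0.968             |
| 0.20     | 0.976         | 0.962             |
| 0.30     | 0.948         | 0.928             |

Degradation is monotone and driven almost entirely by pairs whose noisy
mean crosses the 0.5 threshold and by species medians slipping under the
3-fold ratio. The acceptance suite pins the noiseless point at exactly
1.0 and requires the 20-seed mean at `noise_sd = 0.1` to stay above 0.95 —
the noiseless value minus a 0.05 allowance, chosen from this curve with a
margin of about five times the observed shortfall.

## Numerical and design choices

- Problem sizes in the test suite (500-gene simulations, 20 seeds, a
  ~230 000-instance decision-table sweep) were chosen so the full suite
  runs in well under a minute on one core while still enumerating the
  complete grid of small classification instances.
- Gene symbol matching is exact but case-insensitive (mouse `Cd19` vs
  human `CD19`); ambiguity is an error listing candidates, never a guess;
  fuzzy matching is out of scope.
- Rejected input rows are counted per reason (unknown source/endpoint,
  unmapped gene, non-finite value, unknown species) instead of aborting;
  loaders are order-insensitive and write/load round-trips are exact
  (floats serialized with `repr`).
- Duplicate statistics for one (gene, cell type, species, endpoint, source)
  are an error — the statistic would be ambiguous — rather than averaged.
- Multi-mapping orthologs are representable as separate `gene_id` rows of
  the cross-reference; no merging policy is imposed.
- The pipeline persists everything as flat CSV/JSON; the stats/scores
  tables and the markers table play the role of the upstream and
  downstream databases of a hosted deployment.

## Known limitations

- Corpus-scale results from curated literature tables depend on private
  curation and are out of scope; the package is validated on constructed
  examples, property sweeps and planted synthetic data instead.
- The two significance rules can disagree near the boundary (a pair with
  mean 0.49 but 3/4 sources ≥ 0.5); the package makes the choice explicit
  rather than resolving it.
- Higher-level species calls pool subtype medians (median of medians),
  which weights subtypes, not sources.
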
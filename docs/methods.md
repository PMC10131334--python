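# Methods

This note documents the models and conventions implemented by `imdnet`, the
parameters that matter, and the design choices made where the published
conventions of the field leave room.

## Change scoring

A biomarker concentration $x$ (μmol/mmol creatinine) is compared to its
age-specific reference interval $[L, U]$. Above $U$ is an increase, below
$L$ a decrease, and any value in between — including the bounds themselves —
is *unchanged*. The score is the log2 fold change against the **violated
bound**: $\log_2(x/U)$ for increases, $\log_2(x/L)$ for decreases. This
formula was chosen among the plausible candidates (violated bound, interval
midpoint, reference mean) because it is the only one that is 0 exactly at
the bound, continuous across it, has a sign that matches the stated
direction, and leaves in-range values at exactly 0 rather than at a small
fold change. It is also invariant under a common rescaling of value and
bounds, which makes the score unit-free.

Degenerate inputs are handled by status, not by special values: a missing
measurement is `missing`, a zero concentration or a violated bound of zero
is `zero_disregarded` (a ratio with zero is undefined), and a biomarker with
no interval in either the patient's age band or the overarching band is
`no_reference`. Only `scored` entries carry a nonzero log2FC; `unchanged`
entries carry 0. None of the flagged statuses reach visualization.

Tunables:

| parameter | default | meaning |
|---|---|---|
| cap | 3.0 | log2FC clamp for comparison/visualization; raw value preserved |
| small-change ε | 0.05 | `scored` entries with −ε < log2FC < ε are dropped; exactly ±ε is kept (strict inequality, so boundary markers stay visible) |

Both filters are idempotent and commute on the retained set.

## Age stratification

Reference data is stratified into four half-open bands in months — [0, 12),
[12, 60), [60, 192), [192, ∞) — plus one overarching 0–16 y band used as a
fallback whenever a specific (biomarker, band) interval is missing. The
four specific boundaries are a configurable default (YAML), not a claim
about any particular laboratory's stratification; the overarching fallback
band is treated as the fifth category. Exactly one overarching band is
required and the specific bands must not overlap, so age resolution is a
partition.

## Ordinal disease profiles

Qualitative biomarker annotations are converted to a fixed ordinal scale
with a 14-token table (↑↑↑/↑↑/↑ → +3/+2/+1, range tokens ↑-↑↑ → +1.5 and
↑↑-↑↑↑ → +2.5, "n to 1" → +0.5, "n to 2" → +1.5, the mirrored down-arrow
tokens negative, and "n" and "+ -" → 0). Tokens are normalized (trimmed,
internal whitespace collapsed, Unicode minus unified with the ASCII hyphen)
before lookup; anything outside the table is an error, never a silent 0.
"n to 1" and "n to 2" are treated as opaque tokens at their printed values;
their upstream semantics are not interpreted further.

The disease × biomarker matrix for an age category takes the union of the
retained disorders' biomarkers as columns (sorted, so serializations are
byte-stable) and fills unlisted cells with 0 — "not annotated as altered"
is deliberately encoded as "no change" so Euclidean distance is defined on
the full column set. Disorders without any biomarker data for the category
are dropped from the matrix.

## Patient matching and clustering

The patient's capped, filtered scores are projected onto the matrix columns
through the ChEBI→HMDB mapping. Altered markers that cannot enter the
comparison (no HMDB mapping, or absent from every disorder profile) are
counted and reported, not silently dropped; the ones absent from the
nearest profile are surfaced as *additional biomarkers* — candidate blind
spots in the theoretical annotations. Disorders are ranked by Euclidean
distance; ties at the minimum are reported joined by "/" rather than broken
arbitrarily.

Disorder rows are clustered agglomeratively on the same distance. The
linkage method is not dictated by the distance choice; complete linkage is
the default (the default of the common heatmap tooling this output is
meant to feed), with average and single available. Rows are sorted before
linkage so the tree is invariant to input row order. The patient is
compared post hoc against the disorder rows — added as one extra heatmap
row — rather than folded into the dendrogram; "closest disorder" is
operationalized as nearest distance, with flat-cluster co-membership
available via a cut height.

## Pathway models

The canonical internal form is a small JSON dialect (nodes with class
metabolite/protein, edges with substrates/products/catalysts, Rhea and OMIM
annotations) simple enough to write fixtures by hand. GPML — the
WikiPathways XML exchange format — is imported into it: only DataNode/Xref
identity, Interaction connectivity (Points, Anchors, arrowheads) and Groups
are consumed; layout and graphics are ignored because the framework uses
identity and connectivity, not rendering. Metabolites need a ChEBI Xref to
enter the model (nodes without one go to a skip report); catalysis is
recognized from `mim-catalysis` arrows ending on an Anchor of a conversion;
conversion direction comes from a directed Rhea annotation when present,
else from arrowheads, else the edge is undirected. Group references are
flattened to their member nodes, which also answers how a biomarker inside
a complex counts as "in" a pathway: it does.

A local marker→pathway index over the loaded models stands in for a live
pathway-database query, keeping the pipeline fully offline and
reproducible against a fixed model set.

## Pathway selection

Candidates are ranked by the number of changed markers they contain
(descending, ties lexicographic by pathway ID). At most **three** pathways
are then selected greedily: each pick maximizes the count of changed
markers not covered by the previous picks, stopping early at zero marginal
gain. "Most unique biomarkers" is implemented as greedy marginal coverage —
for the first pick this coincides with "most matching biomarkers", which is
the only case where the two published phrasings could diverge. Ties at
equal marginal gain are broken lexicographically, and an override list can
force specific pathways into the leading positions, mirroring manual expert
selection.

Greedy maximum coverage is a deliberate choice, not an approximation made
for speed: it makes the per-pick semantics (first pathway, second pathway,
…, each with its own newly-covered count) well defined and reproducible.
An exhaustive maximum-coverage search is provided for small instances as a
cross-check; on random instances of the sizes used in the tests the greedy
result attains the exhaustive optimum in roughly 99% of cases, and the
known residual gap of greedy max-coverage is measured and reported by the
test suite rather than hidden. Weighting markers by fold-change magnitude
during selection is a recognized possible refinement and intentionally out
of scope (the hook is the `overrides` parameter).

## Network overlay

Every node of a selected pathway becomes a graph node; interactions expand
to conversion edges (one per substrate–product pair) and catalysis edges
(catalyst → substrate, undirected class), so the deficient-enzyme signature
— elevated substrates adjacent to their shared catalyst — is visible in the
export. Metabolites with a capped score are binned on a five-point
diverging scale: breaks at 0 and ±1.5, capped at ±3; the inner (mild) bins
are open at ±1.5 and the outer (strong) bins closed, so a value of exactly
±1.5 reads as abnormal. Nodes without a value — unmeasured metabolites,
proteins, disorder nodes — are gray; disorder nodes are never colored by
scores. The absolute highest capped value present is recorded on the graph
(`scale_max`) for renderers that scale their gradient to the data. The
concrete hex colors are this package's defaults (a ColorBrewer-style
red/blue diverging set) and are configurable; they are not asserted to be
anyone else's palette. Exports are GraphML (attribute-lossless round trip)
and SIF plus a node-attribute TSV, both consumable by standard network
tools; live control of a running viewer is out of scope.

## Synthetic data generator

The generator emulates the *structure* of a targeted urine-metabolomics
study of pyrimidine/urea-cycle-like disorders without claiming any real
concentrations: an 88-marker panel, four fixture pathways over the first 14
markers (a linear 5-metabolite degradation chain, a branched chain, a
5-metabolite cycle, and a biomarker-collection pathway overlapping the
others), six disorders (two per reaction-bearing pathway), and a 16-patient
cohort spread over the four age bands in study-like proportions.

Mechanism: an impaired enzyme with severity $s$ (default 2.0, log2 scale)
shifts its direct substrate's mean to $U \cdot 2^{s}$ (so the noiseless
log2FC against the upper bound is exactly $+s$), one metabolite further
upstream by $+s/2$, the direct product to $L \cdot 2^{-s}$, and one step
further downstream by $-s/2$. Unrelated markers are drawn at the geometric
midpoint of their interval. Noise is multiplicative log-normal (Gaussian
with sd `noise_sd`, default 0.1, on the log2 scale), matching the
fold-change semantics of the scoring model. Reference intervals are
$[b/2, 2b]$ around a per-marker baseline $b$ drawn log-uniformly over
roughly three decades; 10% of (marker, band) entries are deliberately
omitted to exercise the overarching fallback, which is always present.
Theoretical profiles are derived from the same ground truth with shifts
rounded to the ordinal scale, so profile matching has an exact target.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: analytical measurement error structure,
treatment effects and diet, correlated markers outside the modeled
pathways, age-dependent reference levels (bounds are constant across
bands), partially annotated panels, and disorders with atypical or
sex-linked biomarker patterns. Recovery rates on synthetic cohorts are a
check of internal consistency, not a clinical performance estimate.

All generation is deterministic under the configuration seed (per-patient
streams are derived from the seed and the patient label), and every emitted
file validates against the package's own readers.

## Problem sizes used in the checks

The test suite and the acceptance script run entirely on generated data at
desk scale: 88-marker panels, 6-disorder profile matrices, 4 fixture
pathways, 100-patient recovery runs, 1,000-instance selection oracles and
10,000-case scoring property sweeps. These sizes were chosen to make every
check exhaustive or statistically comfortable at interactive runtimes.

## Known limitations

* The log2FC formula against the violated bound is this package's
  documented convention; laboratories using midpoint- or Z-score-based
  conventions will get systematically different magnitudes (signs and
  in-range behavior agree).
* Distances treat biomarkers independently and equally; highly altered
  markers do not weigh more, and correlated markers are double-counted.
* Greedy pathway selection can trail the exhaustive optimum on adversarial
  instances (measured ~1% of random small instances).
* The GPML importer covers the identity/connectivity subset only; pathways
  relying on unusual graphical constructs may lose interactions (they are
  listed in the skip report, never dropped silently).
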
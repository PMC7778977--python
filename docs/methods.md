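# Methods

This note documents the models, rules and numerical choices implemented in
`exatlas`, the parameters that matter, and what the synthetic-data generator
does and does not emulate.

## The condition model

Expression is asserted at *conditions*: (anatomical entity, developmental
stage, sex, strain, species). The partial order over conditions is the
component-wise product of four orders:

* **Anatomy** — a DAG over `is_a` and `part_of` relations. Cycles are
  rejected at load time. Only `[Term]` stanzas with id/name/is_a/
  relationship/subset lines are honoured; anything else (including unknown
  relationship types, which are logged) is ignored, since the engine
  consumes pre-simplified ontology subsets, not full OBO semantics.
* **Stages** — a tree: each stage has at most one `part_of` parent; sibling
  order comes from `preceded_by`/`immediately_preceded_by`. The tree is also
  encoded as a nested set (each stage gets a (left, right) interval;
  ancestry = strict interval containment), which makes ancestry tests O(1)
  and gives a total serialization order. Only `part_of` is used for stage
  ancestry; `is_a` is not followed for stages, matching the condition-graph
  construction rule for the stage component.
* **Sex** — male/female/hermaphrodite under a single root `any`. The
  missing-value vocabulary (`NA`, `not_annotated`,
  `confidential_restricted_data`) is deliberately *not* placed under `any`:
  an assay of unknown sex must neither receive propagated calls from, nor
  contribute to, sex-resolved conditions.
* **Strain** — flat, single root `wild-type`, with the same missing-value
  handling.

The condition graph is never materialized; ancestor sets are computed on
demand as the cross product of the component ancestor-or-self sets. Stages
tagged `granular_stage` (e.g. an exact age) are remapped to their nearest
non-granular ancestor before any integration, so data annotated at different
granularities meet at comparable conditions.

## Presence/absence calling

* **RNA-seq.** Per library, the background is the empirical (1 − α)
  quantile (linear interpolation) of the TPMs of reference intergenic
  regions; a gene is present iff its TPM strictly exceeds it. α defaults to
  0.05 and is a config knob. All RNA-seq calls carry high quality. A gene
  with zero counts still receives an absent call: silence is evidence here,
  unlike for ESTs below.
* **Affymetrix, CEL mode.** Each probeset's probe-level normalized signals
  are compared to the pooled signals of a designated background probeset set
  by a one-sided Wilcoxon rank-sum test (alternative: probeset greater).
  p < 0.03 → present/high; 0.03 ≤ p ≤ 0.12 → present/low; p > 0.12 →
  absent/high. The test uses exact enumeration when the probeset has ≤ 25
  signals and the pooled data are tie-free, otherwise the normal
  approximation with continuity correction and midrank ties.
* **Affymetrix, MAS5 mode.** `present` and `marginal` flags → present/low;
  `absent` → absent/low. Everything from MAS5 files is low quality because
  the background estimation of MAS5 is known to be sequence-biased.
* **Probeset filtering and reconciliation.** Probesets never seen as MAS5
  `present` or CEL present/high anywhere in the dataset are excluded (a
  probeset that only ever yields low-quality presence is considered
  unreliable, and exclusion means unreliability — genes losing all their
  probesets get *no* Affymetrix call, not an absent one). Surviving
  probesets are reconciled to one call per gene per chip by the total order
  present/high > present/low > absent/high > absent/low; ties are broken by
  probeset id for determinism.
* **EST.** ≥ 7 tags → present/high; 1–6 → present/low; 0 → no call. EST
  sampling is far too shallow to support absence.
* **In situ.** Each spot is already a curated observation; detected →
  present, not detected → absent, quality copied.

## Propagation and global calls

Presence propagates to every ancestor condition; absence propagates to
direct anatomical child conditions only, same stage/sex/strain, one level
deep — an assay can miss expression confined to a small part of a larger
structure. Because presence reaches *all* ancestors, two useful identities
hold and are relied upon in the integrator: "a presence call exists in the
condition or any sub-condition" is exactly "a presence record targets the
condition", and the absence records reaching a condition are exactly those
observed there or in a direct anatomical parent. Property tests verify both
on random ontologies.

Per gene–condition: presence wins over absence regardless of quality or
count; a global absent call requires absence support and no presence
anywhere below; otherwise no call. Confidence counts *distinct experiment
ids* for the winning state (an experiment contributing both high- and
low-quality assays counts once, as high): gold ≥ 2 high-quality experiments;
silver = exactly 1 high-quality, or ≥ 2 all-low; bronze = 1 low-quality
experiment. Overruled absence support is still reported in the output
columns but never affects state or confidence. A call is `observed` iff at
least one supporting record's source condition equals the target condition
(after stage generalization). Absence confidence counts experiments in the
condition and its direct anatomical parents only; deeper ancestors never
count.

## Ranks and scores

Within each condition and data type:

* RNA-seq: fractional ranks (descending; ties take the mean position) of
  TPM per library, combined by a weighted mean with the library's
  distinct-rank count as weight — libraries resolving more distinct ranks
  carry more weight. The distinct-rank count is computed after tie
  resolution.
* Affymetrix: fractional ranks of the per-gene maximum probeset signal per
  chip. Chip ranks are first normalized between chip types:
  `normRank = rank × (1 + condTypeMax / typeMax) / 2`, where `typeMax` is
  the chip type's maximum rank over all conditions and `condTypeMax` the
  maximum of those maxima among chip types represented in the condition —
  *not* the condition's own max rank. Then the same weighted mean.
* In situ: per-gene evidence score = Σ quality weights over present spots
  (high = 1.0, low = 0.5 — the weights are not canonical; they are chosen so
  quality modulates but does not dominate spot count, and are exposed in the
  config). Absent spots are ignored for ranking: ranks order expression
  strength, absence is the call layer's job. Dense rank of the scores.
* EST: dense rank of total tag counts summed over the condition's
  libraries.

Per-data-type ranks are then normalized against the species maximum —
`normRank = rank × (1 + speciesMax / condDataTypeMax) / 2` — where
`speciesMax` is the maximum *pre-normalization* rank over all genes,
conditions and data types, recorded once per run. The global weighted mean
uses as weights the summed distinct-rank counts (RNA-seq, Affymetrix) and
the condition's maximum dense rank (in situ, EST); data types without data
for the gene contribute zero weight. Since every normalized rank lies in
[1, speciesMax], so does the weighted mean, and the affine score
`(max + 1 − rank) × 100 / max` lies in (0, 100], strictly decreasing in the
rank. Ranks are carried as 64-bit floats throughout; the score is rounded to
two decimals only at TSV serialization (rank columns serialize at full
`repr` precision, so call tables round-trip exactly).

MAS5-mode chips contribute calls but no ranks: they carry flags, not
signals.

## Enrichment and cross-species comparison

Gene-to-anatomy annotation sets come from global present calls at or above a
confidence floor (default bronze, i.e. all); upward closure is inherited
from presence propagation. The per-term statistic is the hypergeometric
upper tail P(X ≥ fg_count) — the one-sided Fisher exact test — with
Benjamini–Hochberg FDR reported but no cutoff applied. The background
defaults to all genes with any global call and is user-overridable.

The *elim* decorrelation processes terms deepest-first (depth = longest path
from a root; ties broken by term id for reproducibility); when a term's p
falls below `elim_alpha` (default 0.01, as in the reference topGO setting),
its annotated foreground genes are removed from all strict ancestors' gene
sets before those are tested. With `elim_alpha = 0` the procedure reproduces
the classic test bitwise.

Cross-species comparison classifies each queried gene per
anatomical-similarity group (or per raw anatomical entity in single-species
mode) as expressed / not expressed / no data from the global calls; a gene
with no call at the entity is "no data" whether data are genuinely missing
or simply never reached the entity. The conservation score is the majority
fraction among genes with data — no canonical formula exists for this
quantity, so the majority fraction was chosen to match the intended
"maximum expression conservation" ordering and is exposed in config. Rows
sort by conservation descending, then minimum rank ascending. Gene-page
style outputs can aggregate stages within an anatomical entity by min or
mean rank (`gene_page_stage_aggregation`); min is the default as it reflects
the condition of strongest expression.

## Synthetic data

The generator plants a known truth and emulates each data type around it.
Defaults (all in `FixtureSpec` / the flat config): a 20-term single-rooted
anatomy DAG (max 3 children, ~10% of terms with an extra `part_of` parent),
a depth-3 stage tree with 40% granular leaves, 40 genes, two disjoint
planted expression programs of 12 genes each at effect tiers 4.0 / 2.5 / 1.0
(log2-fold over the RNA-seq background threshold — strong, moderate and weak
tissue-specific expression), two experiments per data type (so gold
confidence is reachable), and assays annotated at a granular leaf stage so
stage generalization is exercised end to end.

Noise model: intergenic TPMs are exponential (rate 1); expressed genes draw
log-normal TPM (σ = 0.5) centred `effect` doublings above the background's
theoretical 95th percentile, unexpressed genes ~1.5 orders of magnitude
below it. Probe signals are normal on a log scale; unexpressed probesets sit
1.5 units *below* the background probesets, mirroring the gcRMA-style
weakly-expressed background. EST counts are Poisson with mean proportional
to planted abundance (10 tags at the middle tier); truly unexpressed genes
yield zero tags by default (`est_background_rate = 0`), because a tag is a
sampled transcript and any nonzero count is, by design of the calling rule,
a presence call — background tag noise would therefore plant mislabelled
truth rather than noise the method could reject. In situ spots cover a
random 30% of expressed gene–conditions.

Each data type consumes an independent random stream derived from the master
seed by a fixed label, so adding or removing one data type never perturbs
the draws of another, and the whole simulate→calls→integrate→rank chain is
byte-deterministic under a fixed seed.

**What the generator does not emulate:** duplicated samples across
experiments, platform batch effects, probe-sequence affinity bias,
mapping ambiguity between paralogs, taxon constraints on anatomy terms,
cross-species data (fixtures are single-species; similarity groups are
exercised with hand-built fixtures), and curation errors. Passing recovery
tests therefore demonstrates the correctness of the calling, propagation,
integration and ranking machinery under the stated noise model — not
robustness to the full messiness of public repository data.

## Problem sizes and tolerances

The test and acceptance workloads use desk-scale sizes chosen to exercise
every code path with comfortable margins: 40-gene, 20-condition datasets for
end-to-end recovery (precision/recall of planted presence ≥ 0.95, planted
rank order Spearman ρ ≥ 0.9 at default noise); 100 random ≤ 40-term
ontologies for propagation invariants; exhaustive enumeration of all
hypergeometric tables with background ≤ 60 against an exact
integer-arithmetic oracle (agreement to 1e-12 relative); 100-case random
suites for each rank equation against direct evaluation (1e-12 relative).

## Known limitations

* The RNA-seq threshold is a fully specified quantile rule standing in the
  place where a library-specific statistical threshold would plug in; the
  `alpha` knob is the interface.
* Probe-level discrimination scores (as in the original MAS5 detection
  call) are unavailable at the normalized-signal granularity consumed here;
  the Wilcoxon variant operates on probe signals vs pooled background.
* Sex- and strain-resolved global calls are computed internally but the
  default writers expose anat × stage (plus sex/strain columns for
  round-trip fidelity); there is no per-sex export view.
* Multi-species rank normalization is per-species by construction; scores
  are never compared across species except through similarity groups.
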
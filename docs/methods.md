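# Methods

`ragut` re-implements, as a reusable and tested library, the statistical
workflow of a longitudinal gut-metagenome treatment study in rheumatoid
arthritis (RA): 22 healthy controls (HC) sampled once and 22 RA patients
sampled at months 0, 1, 3 and 6 under two treatment arms — an herbal
decoction plus methotrexate (HQT, n = 13) and leflunomide plus methotrexate
(LEF, n = 9).  The raw sequencing data behind such a study are consumed
only as profiler outputs (MetaPhlAn-style taxonomic tables, HUMAnN-style
pathway and gene-family tables); a synthetic-cohort generator with known
ground truth stands in for them so that every downstream stage has a
recovery test.

## Statistical tests

All hypothesis tests are implemented in `ragut.stats` and checked against
independent oracles (exhaustive enumeration, scipy, statsmodels) in the
test suite.

**Wilcoxon rank-sum.** Two-sided.  `auto` mode uses the exact Mann–Whitney
null distribution (computed by the standard count recursion) when both
groups have ≤ 10 observations and the pooled data are tie-free, otherwise a
tie-corrected normal approximation with continuity correction, matching the
behaviour of the common R default.  Direction is the sign of the median
difference, falling back to the rank-sum sign on equal medians.  A paired
signed-rank variant exists but is off by default: the study's figure
captions apply the rank-sum test even to within-subject timepoint
contrasts, and we follow that usage (a repeated-measures caveat applies to
all timepoint comparisons; subjects contribute one sample per visit and
visits are treated as independent ordered groups).

**Fisher's exact test (2×2).** Two-sided by the sum-of-small-probabilities
rule over the conditional hypergeometric distribution.  A seeded
Monte-Carlo generalisation handles 2×k contingencies when enterotyping
yields more than two clusters.

**Pooled two-sample t from summaries.** Printed cohort tables report mean ±
SD and n per group; the pooled-variance Student t reproduces their p-values
(weight row 0.044; AST row 0.002).  The source tables label the column
"adjusted", but the printed values match unadjusted pooled t-tests, so no
multiplicity adjustment is applied here.

**Spearman correlation.** Midranked ties, pairwise deletion of missing
values, two-sided p via the t approximation; constant vectors yield a
flagged NaN result that downstream consumers skip.

**Benjamini–Hochberg.** Step-up adjusted p-values, capped at 1.  The study
reports FDR stars without naming a procedure; BH is the field default and
our choice.  Taxonomic/pathway differential calls are gated on the *raw*
p < α (as in the study); q-values are reported alongside for FDR-gated
reuse.  The association triangle, whose stars are FDR-based in the source,
gates on q < α, block-wise (never pooled across the three blocks).

**Jonckheere–Terpstra.** J sums pairwise Mann–Whitney counts over all
ordered group pairs.  `normal` mode uses the tie-adjusted mean and variance
(the classic three-term formula); `exact_mc` permutes pooled observations
(seeded).  Full enumeration is infeasible at the study's 13 × 4 layout.
Two-sided p doubles the smaller one-sided tail, capped at 1.  Trend
direction is sign(J − E[J]); reversing the timepoint order flips it.

## Diversity and ordination

Shannon diversity uses natural logarithms (the vegan default; divide by
ln 2 for bits) on renormalised proportions, skipping zero terms.
Bray–Curtis is Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ) on the raw values; an all-zero sample
pair is defined as distance 0 with a warning.  The enterotyping distance is
the square root of the Jensen–Shannon divergence with base-2 logarithms —
a metric bounded by [0, 1] — on pseudocount-smoothed proportions (default
pseudocount 1e−6, applied only to zero cells before renormalisation).

PCoA is classical scaling of the double-centred squared-distance matrix;
axes come from positive eigenvalues only, negative eigenvalues are reported
separately and excluded from the proportions explained.  PCA is centred,
not scaled.  Both use a deterministic sign convention (the
largest-magnitude loading of each axis is made positive).

PERMANOVA uses Anderson's pseudo-F from total vs within-group sums of
squared distances, with p = (1 + #{F\_perm ≥ F\_obs}) / (1 + n\_perm) under
seeded label permutations (default 9,999).  The distance matrix is computed
once; permutations shuffle labels only.

## Differential abundance and enrichment summaries

One rank-sum test per feature at the baseline visit, BH q within a
taxonomic level, direction from the group mean relative abundance (medians
of rare taxa are usually zero).  Features absent everywhere are skipped; a
prevalence filter (default: present in ≥ 10% of samples) excludes
degenerate all-zero tests and can be disabled (`prevalence_min = 0` is the
strict source-faithful mode).  Enriched-set summaries report phylum
composition (percent of set size) and habitat-of-origin composition under
*both* denominators — full set and known-origin only — because the source
reports mix the two conventions.

Species origin is classified from IMG-style isolation metadata: the host
must be Homo sapiens; an isolation text containing an oral keyword
(saliva, dental plaque, nasopharynx, oral) marks the species oral; gut
keywords (feces, gastrointestinal tract, gut, stool) mark it gut; oral is
checked first; anything else is other/unknown.  Keyword lists are
configurable since the source's exact vocabulary beyond its quoted
examples is unknown.

## Reporter scores

Each KO's two-group p becomes z = Φ⁻¹(1 − p), signed by the direction of
change (an unsigned variant is available).  A pathway's raw score is
Σz/√k over its k mapped KOs; the corrected score subtracts the mean and
divides by the standard deviation of raw scores of random size-k KO sets
drawn without replacement from all mapped KOs (default 1,000 seeded draws,
cached per k).  p-values are clipped to [1e−15, 1 − 1e−15] before the
inverse normal.  |corrected score| > 1.65 (≈ one-sided normal 0.05) flags a
pathway; under uniform p-values the scores are approximately standard
normal (checked in the suite).

## Longitudinal analyses and restoration

Trend scans run the JT test per feature across the ordered visits within
one arm; arm analyses never touch the other arm's samples (asserted by a
poisoning test).  Clinical indices are compared per visit against baseline
with the rank-sum test, with significance stars at 0.05/0.01.  The source
states which species were "restored" but not the rule; we formalise it:
**restored ⟺ significantly different from HC at baseline AND a significant
opposite-direction trend under treatment**.  The flagging is a pure
function of its two inputs.

## Association triangle

Spearman correlations on the pooled baseline samples (HC + untreated RA)
in three blocks — clinical × species, clinical × pathways, species ×
pathways — each BH-corrected separately.  The clinical indices default to
ESR, CRP, RF, anti-CCP and AST.  Species and pathways are retained iff they
carry at least one significant clinical edge; species–pathway edges are
restricted to retained nodes; nodes are annotated with their
differential-enrichment direction.  Pooling HC and RA at baseline is our
reading of the source's "at baseline in the RA and HC groups".

## Enterotyping

Genus-level profiles → root-JSD distances → PAM for each candidate k
(default 2–10, capped at n/3 to avoid singleton-chasing) → the
Calinski–Harabasz index → k = argmax CH.  Clusters are labelled by their
highest-mean-abundance genus.

*PAM.*  For tiny instances (≤ 300 candidate medoid sets) the k-medoids
objective is solved exactly by enumeration; beyond that, greedy BUILD
initialisation followed by best-improvement SWAP, with cost ties broken by
lowest index so the procedure is fully deterministic.  The heuristic can,
like any BUILD+SWAP implementation, stop in a local optimum on adversarial
small instances — hence the exact path where enumeration is affordable.

*CH.*  Computed from pairwise squared distances (T = Σ_{i<j} d²ᵢⱼ/n and the
per-cluster analogue for W, CH = [B/(k−1)]/[W/(n−k)] with B = T − W).  This
needs no centroid, reduces exactly to the classic variance-ratio index when
distances are Euclidean, and behaves like an ANOVA F (≈ 1 under random
labels).  A medoid-anchored variant was considered and rejected: it is
biased below 1 under the null because cluster medoids adapt to noise.

## Random-forest feature selection

Species are ranked once on the full data by random-forest importance
(permutation importance by default; impurity importance by flag), then
added in rank order; 5 trials of stratified 10-fold cross-validation record
the out-of-fold misclassification error of each top-m model; curves are
averaged; the cut-off is the minimum of the averaged curve plus the
between-trial standard deviation at that point; the optimal set is the
smallest m with error ≤ cut-off.  Ranking on the full data follows the
source's phrasing and carries selection bias; a per-fold variant is the
obvious extension but is out of scope here.  Defaults: 500 trees, M =
min(100, n features) scanned; tests and the pipeline use smaller forests
and M for desk-scale runtime.

A known property, not a defect: on compositional data the forest may rank
abundant non-spiked taxa highly, because closure transmits the spiked
species' signal into everyone else's relative abundances.  The optimal set
is therefore a minimal *discriminative* signature, not a recovery of the
spiked set — recovery claims in this package rest on the differential,
reporter, enterotype and restoration stages.

## The synthetic cohort

The generator emulates the study design, not any real taxon inventory.

- **Composition model.** Species log-abundances = per-species baseline mean
  (N(0, 1.2²)) + enterotype archetype effect + per-subject species offset
  (sd 0.3) + per-sample genus-block effect (sd 0.3, shared by the species
  of a genus) + residual noise (sd 0.5); exponentiate and close each sample
  to 100%.  A log-normal model with genus blocks was chosen over a
  Dirichlet because enterotype separation needs genus-level covariance.
- **Enterotypes.** Each subject is Prevotella-dominant with probability
  0.2, else Bacteroides-dominant; the dominant genus gains +4 log units
  (≈ 50–60% relative abundance after closure), the other archetype genus
  +1.  Both genera sit in Bacteroidetes; the remaining genera cycle through
  five phyla.
- **Disease spikes.** 37 species multiplied and 21 divided by the effect
  fold (default 4) in RA samples, drawn outside the two archetype genera.
  True differential status is defined pre-closure; closure-induced
  spillover onto other taxa is accepted and visible as extra significant
  calls.
- **Treatment.** The spike decays linearly with months treated:
  multiplier = fold^(1 − rate·months), floored at no spike.  Default rates:
  0.15/month (HQT) vs 0.04/month (LEF), so one arm restores most of the
  deviation by month 6 and the other does not — the asymmetry the
  restoration analyses must recover.
- **Function.** Each KO is a weighted sum of 1–2 species' abundances times
  log-normal noise (sd 0.3); ~10 KOs per pathway; nine designated pathways
  draw ≥ 80% of their KOs from spiked species (six from enriched, three
  from depleted), giving the reporter stage known positives; pathway
  abundances are member-KO sums; a KO map row every seventh pathway is
  shared so the map need not partition the KO universe.
- **Clinical indices.** A latent activity score d = mean log abundance of
  spiked-up − spiked-down species per sample.  Inflammation markers (ESR,
  CRP, RF, anti-CCP) increase in d with baselines and slopes chosen so HC
  and RA baseline means resemble the printed cohort tables (e.g. ESR ≈ 22
  vs ≈ 60 mm/h); AST decreases mildly; RA-only scores (DAS28-CRP, joint
  scores, VAS, HAQ) are missing for HC.  On top of the decay inherited from
  d, each index has an arm-specific per-month response — ESR responds under
  HQT, CRP under LEF — mirroring the reported divergence of the two arms.
- **Origin metadata.** Spiked-up species are human/oral with probability
  0.6, spiked-down human/gut with probability 0.5, everything else
  other/unknown — so the origin summary should find an oral fraction near
  60% among detected disease-enriched species.
- **Determinism.** Every stage draws from its own stream
  (`SeedSequence([master, stage])`), so regenerating one table never
  perturbs another, and a fixed master seed reproduces every file byte for
  byte.

**What the generator does not emulate:** real taxon names and phylogeny,
strain structure, sequencing depth and rarefaction artefacts, zero
inflation beyond what the log-normal produces, subject dropout and missed
visits, covariance between clinical indices beyond the shared latent
score, and batch effects.  Passing recovery tests therefore demonstrate
that the *pipeline* recovers planted structure under this model — not that
the model reproduces any particular real dataset.

## Numerical and interface choices

- Abundance tables are percent (0–100) end to end; Shannon and JSD
  renormalise internally.
- Result TSVs are written with a fixed column order, 6-significant-digit
  reals and deterministic row order, so identical inputs yield
  byte-identical files; `manifest.json` carries no timestamps for the same
  reason.
- p = 0 or 1 are clipped before Φ⁻¹; variance-zero situations (all-equal
  samples) return p = 1 at the null-mean statistic.
- Cost/score ties anywhere break by lowest index.
- Default problem sizes in the orchestrated pipeline: 9,999 PERMANOVA
  permutations, 1,000 reporter background draws, and a reduced selection
  scan (100-tree forests over the top 10 ranked species) — the full
  500-tree, 100-species scan is available through `run_feature_selection`.

## Known limitations

- JT treats visits as independent groups (the source's unpaired usage); a
  mixed-model or paired-trend alternative would use the repeated measures.
- The restoration rule is our formalisation; other reasonable rules (e.g.
  requiring non-significance vs HC at month 6) would change counts.
- Reporter background draws ignore KO–KO correlation within pathways.
- Rank-based tests on relative abundances inherit the usual compositional
  caveats; no CLR/ALR transform is applied, by design.
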
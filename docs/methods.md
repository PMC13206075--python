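# Methods

This note documents the models, conventions and design choices behind
`dedtarget`, in the order the pipeline runs them. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic study generator

The generator emulates the statistical structure of a multi-model bulk
RNA-seq integration study: K independent datasets that share a planted
pathway-level signal of configurable penetrance.

**Counts.** Each dataset draws per-gene baseline log2 means uniformly over
`baseline_log_mean_range` (default 3–10, i.e. means of ~8–1000 counts) and
per-sample size factors log-uniformly in [0.5, 2], so normalization is
exercised non-trivially. Counts are gamma-Poisson (negative binomial) with
a single dispersion α (default 0.1): Var = μ + αμ², matching the standard
NB model for bulk RNA-seq at minimal complexity. Group effects are planted
multiplicatively on the treatment group.

**Planted signal.** The first `n_active_sets` gene sets are "active":
their members are sampled disjointly from the universe and receive a
signed `de_log2fc` (default ±2, alternating direction per set) in exactly
`consensus_support` of the K datasets (default 5 of 7, above the 50%
consensus threshold). The remaining sets are background samples from the
whole universe. The designated true drug-target genes are placed into the
first active set so that targets are themselves part of the planted
disease signal — without this the intersection and concordance stages
would have no coherent ground truth to recover.

**Perturbation profiles.** A knockdown profile sets the perturbed gene to
`kd_primary_log2fc` (default −2, a strong knockdown), gives a few randomly
chosen gene sets a coherent response (every member shifts in one random
direction with gene-level attenuation), and adds a small diffuse response
on ~2% of genes. Module-coherent responses are what give the drug profile
pathway-level structure; a purely gene-sparse response would leave the
pathway AUROC analysis with no labels. The drug profile is the arithmetic
mean (not the sum, to keep the effect scale comparable to a single
knockdown) of the true targets' profiles plus N(0, `drug_noise_sd`²)
noise, default sd 0.2. Decoy knockdowns are generated by the same recipe,
independently of the drug.

All outputs are pure functions of the config: component streams are
spawned from `SeedSequence(seed, spawn_key=...)`, so identical configs are
byte-identical and changing one component never shifts another's draws.

**What the generator does not emulate:** gene–gene correlation within
groups beyond the planted group effects, per-gene dispersion trends,
batch/platform effects, overlap structure between gene sets beyond chance,
or any real organism's annotation. Passing recovery tests therefore shows
the statistics behave as designed under their own assumptions, not that
they are robust to everything real data can do.

## Differential expression

- **Low-count filter**: a gene is kept when its group-total count reaches
  `min_count` (default 10) in *either* group; a switch selects the
  stricter both-groups reading. The filter operates on group totals, not
  per-sample counts.
- **Normalization**: median-of-ratios. The per-gene reference is the
  geometric mean over samples, restricted to genes with no zero count; a
  dataset where no gene covers all samples is an explicit error (a
  pseudo-reference fallback is suggested in the message rather than
  silently applied).
- **Moderated fold change**: log2((x̄_trt + c)/(x̄_ctl + c)) with prior
  count c = 2. This is a deliberately simple moderation — it shrinks
  low-count fold changes toward 0 like the posterior shrinkage estimators
  used in the field, and the downstream statistics need nothing more than
  a finite, shrunken log2FC. It is named as a prior-count estimate in all
  documentation; no posterior model is implied.
- **Inference**: Welch's unequal-variance t on log2(normalized + c),
  BH-FDR over the filtered genes (genes failing the filter never enter
  the BH pool, mirroring independent filtering). Genes constant in both
  groups get p = 1 by definition. A full NB GLM (dispersion estimation,
  Wald/LRT) is out of scope; the t-test has the correct type-I behaviour
  at the simulated sample sizes, which the null-calibration tests check.
- **Ranking**: by log2FC descending, ties broken lexicographically by
  gene identifier, so ranked lists are reproducible across runs.

## Pre-ranked GSEA

The running sum gains |s_i|^w / Σ_members |s_j|^w at members and loses
1/(N − N_h) at non-members (w = 1 by default, the standard weighted
statistic; w = 0 gives the unweighted KS form). ES is the running-sum
value of maximal absolute deviation; the peak index is the first position
attaining it, with a 1e-12 tolerance so accumulated floating-point
rounding cannot flip the tie. If all member scores are exactly zero the
hit mass falls back to equal weights. The leading edge is the members at
ranks ≤ peak (ES > 0) or ≥ peak (ES < 0); ES = 0 yields an empty leading
edge with a warning.

Significance uses plain Monte-Carlo gene permutation: `n_perm` random
member sets of equal size, p = (1 + #{|ES*| ≥ |ES|, same sign}) /
(1 + #same-sign), never exactly 0 by construction, and
NES = ES / mean|ES*_same-sign|. An exact-tail algorithm is intentionally
not implemented: every downstream rule is a p < 0.05 call, for which MC
error at 1000 permutations is ample. Sets are intersected with the ranked
universe first; sets smaller than 2 or covering the universe are skipped
with a log entry. Permuted ES values are computed from hit positions only
(the extrema of the walk can only occur immediately before or after a
hit), which keeps permutation cost independent of list length.

Over-representation of plain gene lists is the exact upper hypergeometric
tail with BH adjustment.

## Consensus integration

For each pathway and direction, count the datasets with p < alpha and
that NES sign; emit (pathway, direction) when the count reaches
ceil(`min_frac` · K) — the ceiling convention makes "at least 50% of 7"
equal 4. A pathway can be emitted in at most one direction: the larger
count wins and an exact tie (possible for even K) emits neither, with a
warning. Only counting is used — no effect-size combination across
datasets (no Stouffer/Fisher), because the integration rule being modeled
is a vote.

Core leading-edge genes: per (consensus pathway, gene), frequency =
contributing datasets where the gene is in that pathway's leading edge ÷
datasets where the pathway was significant in the consensus direction
(non-significant datasets never enter the denominator). Per gene the
*maximum* frequency over its pathways is reported — a gene is core if it
is core for any consensus pathway, which matches pooling the per-pathway
core lists. Core membership requires frequency strictly > 0.5.

## Target triage

Symbols are harmonized by uppercasing only (mouse `Ctss` and human `CTSS`
collapse; no orthology mapping is attempted — a documented limitation).
The key-gene set is the intersection of harmonized predicted targets with
harmonized core genes, in lexicographic order; an empty intersection is a
logged outcome, not an error. Docking triage keeps rows with binding
energy strictly below the threshold (default −6.5 kcal/mol, a common
moderate virtual-screening cutoff): −6.62 passes, exactly −6.5 would not.
The packaged teriflunomide table is consumed as an input produced by a
docking engine; this package computes no poses or scores.

## Virtual knockdown surrogate

The perturbation engine behind the motivating analyses is unpublished, so
this module makes no attempt to reproduce it. The surrogate is the
simplest model that yields non-trivial, testable concordance structure:

1. **Co-expression model**: per-dataset Pearson correlation of
   log2(normalized + 1) expression, averaged over datasets, multiplied by
   (1 − shrinkage) (default shrinkage 0.5) and thresholded at `sparsity`
   (default 0.2; entries below it become 0, the diagonal stays 1).
   Constant genes get zero association. At least 4 total samples are
   required. The shrinkage/sparsity defaults keep random-gene knockdown
   concordances concentrated near zero, which is what the null comparison
   assumes.
2. **Propagation**: first-order and linear — the knocked-down gene takes
   `primary_log2fc` (default −2) and every other gene takes
   w_gj · `primary_log2fc`. The profile is deterministic, linear in the
   primary effect, and symmetric (the effect of knocking down A on B
   equals that of B on A at equal primaries).

Externally computed profiles (from any richer engine, or experiments) are
loaded from two-column TSVs onto a shared universe (`drop` or `extend`
policy for unknown genes; missing genes imputed as 0 with a warning) and
flow through the identical statistics.

## Concordance statistics

- **Gene subset**: the ceil(fraction · N) genes of largest |log2FC| in
  the *drug* profile (default fraction 0.2), ties broken by identifier.
  Ranking by the drug profile gives one fixed subset for candidates and
  null alike, which the rank-sum comparison requires; a per-pair union
  basis can be selected by passing a different gene subset explicitly.
- **PCC**: sample Pearson correlation on that subset; zero variance in
  either restricted vector is flagged NaN and excluded from tests rather
  than raised.
- **Null**: `n_null` (default 100) genes sampled without replacement from
  an eligible pool that excludes the candidates (and is normally
  restricted to filter-passing genes), each knocked down through the
  model, each scored on the same subset.
- **Rank-sum**: two-sided unpaired Wilcoxon/Mann–Whitney. Exact
  enumeration whenever the smaller sample has ≤ 20 observations and there
  are no ties — a handful of candidates against a 100-gene null is
  exactly the regime where the normal approximation cannot resolve small
  tail probabilities — and the tie-corrected normal approximation
  otherwise.
- **Pathway AUROC**: labels are the drug's pathway calls (p < alpha with
  NES sign matching the panel's direction); scores are the knockdown's
  signed NES, negated for the down panel so larger always means "more in
  the labeled direction". AUROC is the Mann–Whitney U divided by
  n₊ · n₋, ties counting ½; single-class panels are flagged NaN and
  excluded from summaries. With a purely suppressive knockdown model,
  up-direction panels can lack positive labels entirely; the module-level
  coherent responses in the generator (random sign per module) keep both
  directions populated in the synthetic studies.

## Pipeline and reproducibility

One global seed is expanded to per-stage child seeds via
`SeedSequence(seed, spawn_key=(stage_index,))` with a fixed stage order,
so toggling a stage off never shifts the randomness of later stages. The
manifest records the SHA-256 of every output file; the determinism test
re-runs the whole pipeline and compares all hashes. All tables are TSV
with fixed column names (`gene, baseMean, log2FoldChange, pvalue, padj`
for DE; `pathway, size, ES, NES, pval, padj, leadingEdge` for
enrichment). Configs are YAML and round-trip to equal objects.

## Problem sizes in the test suite

The suite exercises every recovery property at deliberately modest sizes
chosen to keep the whole run around a quarter of a minute while leaving
comfortable statistical margins: 300–800 genes, 10–40 gene sets, 200
Monte-Carlo permutations, 20-replicate power checks. These are the
package's own desk-scale study conditions; the statistics scale to larger
inputs without modification.

## Known limitations

- The knockdown surrogate is one-hop linear; it cannot represent
  saturation, feedback, or directionality of regulation, and its profiles
  should not be mistaken for predictions of any particular engine.
- Prior-count moderation and Welch's t are simplifications of the NB
  GLM + posterior-shrinkage stack; they are calibrated (type-I tests) but
  less powerful at very small n or extreme dispersion.
- Symbol harmonization is casing-only; cross-species orthology beyond
  case conventions is out of scope.
- Counting-rule consensus has a nonzero false-positive rate (a background
  set can clear the ≥50% threshold by chance), visible in the README's
  worked example.
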
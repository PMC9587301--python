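# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical conventions that affect results.

## Synthetic data model

`synthio.generate_dataset` simulates a paired expression/methylation
study in one of two designs: a four-condition knockout/rescue layout
(WT, KO, R1, R2 — wild type, DNMT3A knockout, and re-expression of
isoform 1 or 2) with `replicates = 4` per condition, or a two-group
in vivo layout (FLFL vs DIEC, i.e. floxed control vs conditional
knockout).

**Counts.** Gene `g` in sample `j` draws from a negative binomial with
mean `s_j * mu_g * 2^(x_j * log2fc_g)` and variance `mu + alpha_g mu^2`
(gamma–Poisson mixture). `s_j` is a lognormal library factor
(`libsize_sdlog = 0.15`). Baselines `mu_g` are lognormal
(median 200, sdlog 1, floor 20); genes carrying planted effects are
raised to `mu >= 100` so the planted |log2FC| = 1 refers to a
well-measured expression regime. The condition dose `x_j` is 1 where the
knockout effect is present and 0 at wild-type level; rescued isoform
conditions revert to 0 according to the planted rescue status
(both / R1_only / R2_only / none, defaults 0.55/0.15/0.15/0.15 so that
85% of dysregulated features are rescued by at least one isoform,
mirroring the emulated study's proportions). Gene-wise dispersions are
lognormal around 0.01 (sdlog 0.3) — the low-dispersion regime typical of
clonal cell-line replicates; dispersion is a free parameter here because
the emulated study reports no within-condition variance.

**Methylation.** Probe baselines come from a symmetric two-component
Beta mixture (Beta(2,10) / Beta(10,2), modes near 0.1 and 0.9) mapped to
the logit scale; per-sample noise is Gaussian on the logit scale
(sd 0.35); beta = logistic(logit). Knockout-affected probes receive a
logit shift of ±1.5 with the same condition-dose/rescue logic as counts.
Affected probes are (a) all probes linked to cis-coupled genes, signed
by the coupling (see below), and (b) a `meth_background_affected = 0.3`
fraction of background probes, 70% shifted down and 5% up — global
hypomethylation with a minority of hypermethylated sites. Probes planted
to lose methylation have baselines re-drawn from the methylated mixture
component (and vice versa), so a 1.5-logit shift moves beta by roughly
0.2 instead of sliding along a saturated tail.

**Cis coupling.** 30% of DE genes are planted *canonical* and 20%
*non-canonical*. Each coupled gene carries one shared standard-normal
latent per sample loading on expression (log2 scale, 0.15) and on its
linked probes' logits (0.35, negative sign for canonical). The dominant
source of observable correlation is, deliberately, the condition
structure itself: a canonical gene's probes shift opposite to its
expression across the KO/rescue pattern, exactly the signal the cis
screen is meant to find. Probes of uncoupled DE genes are left
unshifted, so the planted coupled set is the complete ground-truth
answer for the pair-classification stage.

**Geometry.** Genes are laid on `n_chroms = 2` autosomes at ~50 kb
spacing (windows of adjacent genes never overlap at the default ±5 kb),
`probes_per_gene = 3` probes uniform within the window of each TSS,
plus background probes genome-wide with a 2% chrX fraction. Manifest
flags (SNP overlap 2%, non-CpG context 2%, missing betas 0.2%) exercise
the filters.

**Determinism and twins.** All draws come from named `SeedSequence`
sub-streams of one master seed; structural draws (layout, manifest,
planted truth) can be pinned with `structure_seed` while noise follows
`seed`, which yields twin datasets with identical truth and independent
noise — the basis of the cross-species recovery experiments. Draws are
consumed identically in both designs so a two-group twin shares the
four-condition twin's truth.

**What is not emulated.** No raw intensities or IDATs, no read-level
data, no batch or covariate structure, no probe cross-reactivity beyond
the manifest flags, and noise magnitudes are not calibrated to any
deposited dataset. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under its stated model,
not that real arrays behave this way.

## Differential expression

Median-of-ratios size factors skip genes with any zero count (standard
convention; an error names the problem if no gene has all-positive
counts). The per-gene test uses method-of-moments NB dispersion pooled
across the two groups, floored at 1e-8, and a delta-method SE on the
log2 scale with pseudocount 0.5. The Wald statistic is referred to a
Student t with `n_a + n_b - 2` degrees of freedom rather than the
asymptotic normal: with four replicates the dispersion estimate is noisy
enough that the normal reference rejects ~11% at nominal 5%, while the
t reference sits at ~4–6% (verified by simulation in the test suite).
No shrinkage, no independent filtering, no outlier handling; genes with
all-zero counts in both groups are excluded and reported. There is no
fold-change cutoff — DEG status is FDR-only (threshold 0.05 by default).

## Differential methylation

Filtering removes the union of SNP-overlap, non-CpG-context,
sex-chromosome, and any-missing probes, with per-reason counts reported
(a multiply-flagged probe counts once in the union). Any missing beta
removes the whole probe; no imputation. Quantile normalization is
applied separately within design-type-I and -II strata as a beta-level
stand-in for intensity-level normalization, which requires raw channel
intensities this pipeline never sees; within a stratum every sample
shares the same sorted values afterwards (ties get the mean of the
neighbouring reference values — exact for the continuous betas produced
here). The M-value offset `eps = 0.01` keeps endpoints finite.

The moderated t fits the scaled-inverse-chi-square variance prior
(d0, s0²) by method of moments on log sample variances (digamma/
trigamma moment equations, Newton inversion of the trigamma); posterior
variances are the usual weighted combination and the statistic is
referred to t with `d0 + d` df (normal when the fit degenerates to
d0 = inf, i.e. observed spread no larger than chi-square sampling
spread). `prior_df=0` disables moderation and reproduces the ordinary
two-sample t-test exactly, which the tests use as an oracle.

A strict BH-FDR rule (0.05) plus a >= 2-probe membership rule replaces
any adaptive rank cutoff for DMPs/DMRs — reproducible and directly
testable. Promoters are TSS -1500/+500 oriented by strand (a common
array-analysis convention; no definition was given to inherit). DMR
evidence combines one-sided probe z-values signed by delta-beta
(Stouffer, equal weights); opposite-direction probes cancel by design.
Note the DMP table's `delta_beta` is a beta-scale mean difference while
the test runs on M-values; for near-null probes (|delta_beta| < ~0.01)
the two scales can disagree in sign (Jensen gap of the logit), which is
why sign-consistency guarantees are stated for non-negligible effects.

## Rescue classification

"Rescued by isoform X" defaults to the strict rule: not significant
versus wild type AND significantly reversed versus the knockout
(opposite effect sign). The reversal clause guards against declaring
low-power features rescued, at a sensitivity cost; the permissive rule
(loss of significance only) is a config toggle and is the right
instrument when the quantity of interest is the *fraction* of knockout
features whose profile returned to wild type — the strict rule biases
that fraction down by construction, so recovery of a planted rescued
fraction is measured under the permissive rule. Status composition is a
pure function of the two rescue booleans; every feature gets exactly one
status and swapping the isoform inputs swaps the one-isoform counts.
One FDR threshold (0.05) serves all five contrasts by default.

## Cis integration

Linking is a closed symmetric window (|probe pos − TSS| <= 5000 bp, same
chromosome after "chr"-prefix normalization); distances are reported
strand-oriented (positive downstream) but inclusion is symmetric.
Many-to-many pairs are kept. Correlation is Spearman with average ranks,
computed across the samples of all conditions (the condition contrast is
part of the biological signal being correlated); pairs with zero rank
variance in either vector are dropped with a warning — quantile
normalization can produce constant probes.

The permutation null applies **one shared permutation of the
methylation matrix's sample columns per round**, which breaks the
expression–methylation pairing while preserving cross-probe and
cross-gene correlation; independent per-pair shuffles (available via
config) would overstate the effective null sample. With n samples and
`n! <= exhaustive_cap` (default 720, i.e. n <= 6) all permutations are
enumerated and p-values are exact counts; otherwise `n_perm` sampled
permutations with the +1 correction (p is never 0). The plug-in FDR
estimate at threshold t is the mean per-permutation count of null
|rho| >= t over the observed count (floored at 1, so an empty discovery
set yields q = 0 by convention), then made monotone non-increasing in
|rho| by a cumulative minimum from the weakest pair upward. |rho|
comparisons carry a 1e-12 tolerance so exact ties count as exceedances
regardless of float noise.

Pair classes: canonical (rho < 0, q < 0.05), non-canonical (rho > 0,
q < 0.05), else ns. A gene carries every label among its pairs (the
overlapping-label report); the per-gene representative pair is the
significant pair with max |rho|, ties broken by smaller q then
lexicographic probe id — fully deterministic.

## Cross-dataset concordance

The ortholog map is always an explicit input (and is validated 1:1);
the generator's map pairs the i-th gene of each annotation so twin
datasets map each simulated gene to itself. Shared genes are those with
at least one significant pair on both sides; concordance compares the
representative rho signs. Because direction (not magnitude) is compared,
the two datasets may differ in design, depth and power.

## Pipeline

`pipeline.run` executes simulate → DE (all contrasts) → filter/
normalize/DMP → DMR → rescue (gene and probe) → cis integration →
optional twin two-group dataset plus ortholog intersection, from one
validated configuration (unknown keys rejected before any stage runs).
The cis gene universe defaults to knockout DEGs rescued by both isoforms
(`cis_universe: rescued_both`), matching the emulated workflow;
`ko_degs` uses all knockout DEGs. Output directories are write-once per
run; the run manifest records seed, a parameter hash, and a SHA-256 per
output file, and re-running a configuration reproduces every file byte
for byte (fixed float formatting, `\n` line endings).

## Problem sizes

The default generator scale is 500 genes × ~2000 probes × 16 samples —
the regime where all recovery and calibration experiments in the test
suite and acceptance script run: null calibration at 2000 genes/probes,
FDR control over 10 seeds at 300 genes, and twin concordance at 500
genes. Full array scale (~10^5–10^6 probes) adds nothing statistically
for these checks; all stages are vectorized and scale linearly in
features if larger runs are wanted.

## Known limitations

- The NB test has no dispersion shrinkage across genes; power at very
  low counts is accordingly modest.
- The DMR Stouffer combination treats member probes as independent;
  spatially correlated probes would make region p-values optimistic.
- The plug-in permutation FDR is conservative when many pairs share
  strong condition structure (the shared permutation keeps them
  correlated under the null), visible as reduced shared-gene counts in
  the two-group design.
- Quantile normalization across samples removes genuine global
  methylation differences between conditions within each stratum rank
  distribution; planted shifts survive because they reorder probes, but
  a uniform genome-wide shift would not.
- The beta-scale `delta_beta` and M-scale test statistic can disagree in
  sign for near-null probes (Jensen gap); downstream direction calls use
  `delta_beta` only where an effect exists.
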
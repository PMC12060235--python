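# Methods

This note documents the statistical models, the defaults and the design
choices behind `pinebreed`, in the spirit of a methods appendix: what is
computed, under which assumptions, and what the synthetic-data tests do
and do not demonstrate.

## Clonal identity from replicate ramets

A clonal archive is a set of genets ("clones"), each physically present as
one or more grafted copies ("ramets").  Replicate genotyping of ramets
identifies two failure modes: genotyping error (isolated discordant
calls) and mislabelling (a ramet that is genetically a different clone).

**Consensus genotypes.**  Per clone and locus, the most frequent
non-missing call among member ramets.  Ties and all-missing loci yield a
missing consensus call — no call is ever invented.  Majority support
counts are retained.

**Error rates.**  A sample's mismatch rate is (discordant calls) /
(loci non-missing in both sample and consensus).  By default any dosage
difference counts as one mismatch (genotype level); an allele-level
variant (|Δdosage|, so hom–hom discordance counts twice) is available via
`allele_level=True` but off by default, since replicate-QC conventions
report per-genotype discordance.  Verification is two-pass: consensus
from all labelled members, exclusion of members above the threshold
(default 2.5%, a parameter, chosen so that a 0.5%-error ramet is ~13
binomial SDs below it while a wrong-clone ramet — discordant at a large
fraction of loci in even a low-diversity species — is far above), then
consensus rebuilt from retained members and all rates recomputed against
the clean consensus.  The procedure is idempotent: a second pass on the
retained set excludes nobody.  Per-SNP error rates pool discordant calls
across all clones with ≥ 2 retained ramets, divided by the non-missing
pairs at that SNP.

**Lineage collapsing.**  Nei (1972) standard distance between
individuals, treating each individual as a per-locus 2-allele frequency
vector (dosage/2, 1 − dosage/2) with missing dosages replaced by the
locus mean ("average allele counts"); identities are summed over loci
before the log.  Complete-linkage clustering cut at a threshold groups
samples into multilocus lineages: two samples share a lineage iff their
cluster's maximum internal distance is below the cutoff.  The cutoff is
predicted from the dendrogram merge heights as the point a fraction f
(default 0.5, the midpoint) into the largest gap between consecutive
distinct heights — with replicated clones, merge heights are bimodal
(replication noise vs genet divergence) and the gap is unambiguous.
The prediction fails loudly ("no gap") when all merge heights are equal.

## Genomic relationships and inbreeding

The GRM is VanRaden's first estimator on clone-level genotypes (one
consensus row per genet): Z = M − 2p with in-sample ALT frequencies p,
G = ZZ′ / 2Σ pₗ(1−pₗ), after mean-imputation of missing dosages and
dropping monomorphic loci.  With in-sample frequencies every row sums to
zero and mean(diag G) = 1 + f, giving the genomic inbreeding coefficient
per provenance region as mean(G_ii) − 1.  A plain mean-IBS matrix
(rescaled to the same range) is available via `method="ibs"` for
comparison, since "mean probability of identity by state" and the
centered estimator differ in their baseline; the VanRaden form is the
default because it is the canonical GBLUP kernel.  F_IS = 1 − Ho/Hs uses
ratios of Ho and Hs averaged over polymorphic loci within a group, with
percentile bootstrap CIs over loci (1,000 replicates, seeded).  Note that
exact-HWE counts give F_IS = 1/(2n), not 0, because Hs carries the
small-sample correction.  The genomic f and F_IS measure different things
(drift-driven allele-frequency displacement vs within-group heterozygote
deficit) and are expected to agree in sign but not magnitude.

## Phenotype correction

Cone production is masting-driven: calendar-year effects dominate
ramet-year records, so raw means are poor genetic signals.

* **MCW** (mean cone fresh weight, g; absent in years with no unspoiled
  cones): one value per ramet from the Gaussian mixed model
  `mcw ~ mean + year (random) + ramet (random) + residual`, fitted by
  REML; the ramet value is the fitted mean plus the ramet BLUP.
* **NC** (number of unspoiled cones): yearly records are corrected by OLS
  for calendar year (factor) and tree diameter DAG at that year (linear
  in log DAG by default, for allometry; plain-linear via
  `dag_transform="linear"`), keeping grand mean + residual per record;
  corrected records are summed per ramet (negative totals floored at 0,
  logged) together with the number of measured years.  The grand mean is
  used as the additive constant because with a year factor the regression
  intercept depends on an arbitrary reference level; the constant cancels
  in clone comparisons and the following stage carries n_years as a
  covariate.

Clone-level BLUPs come from `value ~ mean [+ n_years for NC] + clone
(random)` on the ramet values; broad-sense heritability is
H² = σ²_clone / (σ²_clone + σ²_residual) at this ramet level, i.e. after
year variance has been removed upstream.  A clonal-mean H² would divide
the residual by the (harmonic-mean) number of ramets and is deliberately
not the default, because the ramet-level form matches how the corrected
values are produced.  All models are Gaussian: NC totals are treated as
continuous after correction (the correction-and-sum pipeline destroys the
count structure anyway).

## GBLUP and predictive ability

Prediction operates at clone level on the clonal BLUPs (a two-stage
analysis): Y = Xb + a + e with a ~ N(0, G σ²_g), X an intercept by
default.  REML uses a single eigendecomposition of G and bounded 1-D
search on log(σ²_g/σ²_e) (tolerance 1e-10 on the log-ratio, bounds
1e-9–1e9), which is exact and fast at n ≈ 100.  GEBVs for any target set
use the joint-BLUP covariance form a_t = σ²_g G_{t,train} V⁻¹(y − Xb̂),
which needs no inversion of a possibly singular training block and
returns the fitted values exactly for the training clones.

Predictive ability r_y is the Pearson correlation between observed clonal
BLUPs and GEBVs of held-out clones under seeded k-fold CV (default k = 9;
folds are simple random — region stratification is not applied by
default).  r_y is reported as mean ± SD over folds (the SD describes fold
scatter, not a standard error); the pooled correlation over all held-out
predictions is also emitted.  Significance comes from a permutation null
with the fold structure held fixed: phenotypes permuted across clones B
times, one-sided add-one p = (1 + #{null ≥ observed}) / (B + 1).  Fold
eigendecompositions are cached so a permutation costs only a 1-D refit
per fold.  Folds with fewer than 3 clones are rejected (Pearson r on 2
points is ±1); the bound is a parameter for tiny exhaustive-enumeration
settings.

Selection gains are 100 × (mean(subset) − mean(all)) / mean(all) on the
observed scale (fitted mean + BLUP), for the top ⌈fraction·n⌉ clones by
BLUP or an explicit id list, rounded to the nearest integer for
reporting; the baseline must be positive.

## REML solvers

Two solvers cover every model:

* **Spectral, single dense kernel** (GBLUP): rotate by the
  eigendecomposition of G, profile σ²_e out of the restricted likelihood,
  optimise the variance ratio in 1-D.  Each likelihood evaluation is O(n).
* **Woodbury, multiple identity kernels** (year/ramet/clone factors): for
  H = I + Σ γ_k Z_k Z_k′, all quantities reduce to the q × q inner matrix
  M = I + S(Z′Z)S (q = total random levels).  Because the factors are
  one-hot, every within-block Gram matrix is diagonal, and the largest
  block is eliminated by a Schur complement, so each evaluation costs
  O(q_small³ + q_small·q_big) — effectively linear in the number of
  ramets.  One ratio is optimised by bounded 1-D search; several by
  Nelder-Mead on log-ratios followed by coordinate-wise bounded polish.
  On balanced one-way data the solver reproduces the ANOVA closed form to
  ~1e-8 in the BLUPs; location invariance holds to optimizer tolerance
  (~1e-5), which is far below any quantity of scientific interest here.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
calibrated to a real stone-pine breeding cohort:

| parameter | default | meaning |
|---|---|---|
| regions | ES1:32, ES2:20, ES3:22, ES6:25 | 99 clones in 4 provenance regions |
| n_loci | 2,245 | biallelic SNPs |
| fst | 0.10 | Balding–Nichols differentiation among regions |
| region_selfing | 0 / 0.20 / 0.15 / 0.50 | within-region inbreeding (ES6 strongly inbred) |
| n_registered / ramets | 15, 10–11 each | replicated (registered) clones; others 1 ramet |
| geno_error_rate | 0.005 | per-call flip to another valid genotype |
| missing_rate | 0.01 | per-call no-call probability |
| mislabel_rate | 0.10 | clone-label swaps among registered-clone ramets |
| h2_nc, h2_mcw | 0.45, 0.30 | broad-sense heritability targets (study range 0.2–0.5) |
| years, masting_sd | 10 years, 0.8 | calendar-year (masting) effect SD |
| n_sites, test ramets | 3, 6/clone/site | clonal tests |

Founder allele frequencies are Uniform(0.05, 0.95); regional frequencies
follow Balding–Nichols Beta(p₀(1−F)/F, (1−p₀)(1−F)/F).  Genotypes are
drawn with inbreeding-adjusted probabilities (P(het) = 2p(1−p)(1−F_r)).
Mislabels are label swaps among registered clones only: a swap onto a
single-ramet clone would be undetectable by consensus comparison, and
replicated clones are where mislabelling is operationally checked.  NC is
negative-binomial with a log link (site + year + 0.7·log DAG + genetic +
ramet); its nominal heritability therefore lives on the log-mean scale
and is only approximately recovered on the count scale.  MCW is Gaussian
on the identity scale (truncated at 0), with the observation-noise
variance scaled against the realised number of measured years per ramet
so that the clone-level share of ramet-level variance equals h2_mcw —
this is the trait used for exact H² recovery checks.  DAG grows linearly
with age with per-ramet slopes, hence strictly monotone.  All randomness
derives from one root seed through named spawned streams, so each stage
is independently re-runnable and bit-reproducible.

**What the synthetic tests show.**  Recovery of injected error rates,
mislabels, inbreeding, H² and REML h² demonstrates internal consistency
of the estimators under the generator's assumptions (unlinked loci, no
LD beyond population structure, no somatic mutation, no spatial/block
field effects, no G×E, masting as an exchangeable year effect).  They do
not validate those assumptions for real cohorts; in particular real
predictive abilities depend on LD between array SNPs and causal variants,
which the generator sidesteps by making array SNPs causal.

## Problem sizes and numerical choices

Acceptance-style checks run the identity stage at full study scale (99
clones × 2,245 loci, 20 seeds), the H² grid (0.1–0.6) at 99 clones × 6
ramets × 10 years per fit, and null-behaviour suites at 45–60 clones with
79–199 permutations — sizes at which every result is stable yet a full
run stays in the minutes range on one core.  Ties in the consensus are
missing by design; monomorphic loci are dropped from the GRM with a
logged count; a locus or sample with nothing to compare is reported as
undefined (NaN + flag), never silently zero.  The permutation p-value
uses the add-one estimator and is therefore never exactly zero.

## Known limitations

* Two-stage prediction (BLUPs then GBLUP) ignores the uncertainty of the
  first stage; a one-step ramet-level GBLUP would propagate it but is out
  of scope here.
* No dominance/epistatic kernels, no multi-trait or G×E models, no
  spatial adjustment, no cross-generation prediction.
* The A/B→ref/alt orientation of call-code tables must be supplied; it is
  not inferred.
* `fis` CIs bootstrap loci only; clone resampling is not implemented.
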
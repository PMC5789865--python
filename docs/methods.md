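# Methods

## Panel model and curation

A marker (`SnpMarker`) carries its risk/other alleles, per-allele odds
ratio, discovery evidence (P-value, study type, study size), optional
replication P, per-population risk-allele frequencies, and an East-Asian
validation status. A `DiseasePanel` groups markers for one disease with an
optional prevalence, heritability band, and the endometrial-exception flag.

**Inclusion gates** (any route suffices; comparisons are strict `<`):

| route | requirement |
|---|---|
| `gwas_discovery` | P < 1e-7 (relaxed to 1e-5 under the endometrial exception) |
| `gwas_with_replication` | P < 1e-6 **and** replication P < 0.05 |
| `candidate_snp` | P < 0.05 |

Replication-type markers lacking a replication P are dropped with a
warning rather than crashing, since curated literature tables routinely
omit the field. When one rsid appears twice in an input table, the entry
with the larger total study size wins.

**Ancestry transfer** (`transform_panel`): markers validated in East
Asians adopt the East-Asian odds ratio; markers tested with no East-Asian
association are removed; untested markers carry their original odds ratio
(an explicit, inspectable assumption); East-Asian-discovered markers are
appended.

**LD pruning** (`ld_prune`): greedy and deterministic. Markers are
visited by evidence strength — smaller discovery P, then larger |log OR|,
then rsid — and kept only if r² < 0.8 against everything already kept, so
the stronger member of a correlated pair always survives. A total,
deterministic priority order makes the survivor set reproducible across
runs and platforms.

## Composite risk score

For dosages dᵢ ∈ {0,1,2} over the k non-missing markers of a panel,

S = (∏ ORᵢ^dᵢ)^(1/k).

The k-th root makes scores comparable across individuals genotyped on
different subsets of the panel: dropping a marker from the panel and
scoring the sub-panel gives the same value as scoring with that marker
missing. Homozygous risk carriers contribute OR² (multiplicative
allelic-dose model, the same assumption under which GWAS per-allele ORs
are estimated). A profile with zero usable markers is flagged undefined
(`NaN`) rather than silently scoring 1.0, which would be indistinguishable
from a genuine non-carrier. Scores are computed in log space and
exponentiated, avoiding overflow for long panels of large ORs.

## Quality control

Order matters and is fixed: **samples first, then markers**, so marker
statistics are never contaminated by samples about to be removed.

Sample filters (defaults):
- call rate < 0.95;
- heterozygosity inbreeding coefficient F = (E_het − O_het)/E_het outside
  ±0.05, with expectations from cohort allele frequencies;
- method-of-moments relatedness > 0.1875 (between second- and
  third-degree): mean over shared non-missing markers of
  (xⱼ−2p)(xₖ−2p)/(2p(1−p)), **plus 1/(n−1)**. The correction removes the
  systematic bias introduced by estimating p from the same n samples
  (plug-in frequencies force Σᵢ(xᵢ−2p̂) = 0, deflating every pairwise
  product by ≈ 1/(n−1)); without it, unrelated pairs in small cohorts sit
  visibly below zero and duplicates below one.
  In a flagged pair the lower-call-rate member is excluded (ties: the
  later sample), keeping the better-genotyped representative.
  When a sample trips several filters its recorded reason follows the
  fixed priority call rate → heterozygosity → relatedness.

Marker filters: missingness > 0.05 and exact HWE P < 1e-6, both computed
on retained samples only.

**Exact HWE test**: the conditional test that enumerates every
heterozygote count compatible with the observed allele counts (parity
fixed by the allele total), with configuration probabilities
∝ n!/(n_AA! n_AB! n_BB!) · 2^{n_AB}, summing probabilities ≤ the observed
one. Probabilities are computed with `gammaln` in log space so totals in
the thousands neither overflow nor underflow; the ≤ comparison uses a
(1+1e-12) relative tolerance so exactly-tied configurations are counted
despite floating-point rounding. Monomorphic markers return P = 1. The
test suite pins this implementation against a brute-force oracle in exact
rational arithmetic (`Fraction`). A χ² variant is available for
cross-checking but the exact test is the default and the filter criterion.

## Categorisation (CI-based risk classes)

The confidence interval on an individual's score is built on the log
scale: log S ± z_{1−α/2}·√(Σ dᵢ² SEᵢ²)/k, where SEᵢ is the discovery
study's log-OR standard error. When SEs are not supplied they are
reconstructed by the Woolf formula √(1/a+1/b+1/c+1/d) from the allelic
2×2 table implied by the study sizes, the control risk-allele frequency,
and the published OR (case frequency p·OR/(1−p+p·OR)). Reconstruction
refuses tables with an expected cell below 1 and directs the caller to
supply SEs rather than silently applying a continuity correction.

The reference distribution of S in an HWE population at given frequencies
is enumerated exactly over all 3^m genotype combinations for m ≤ 8
markers (6,561 terms; exactness is worth more than speed at panel sizes
this package targets) and Monte-Carlo sampled above that. Categories:

- **reduced**: CI entirely below the reference mean;
- **average**: CI contains the reference mean;
- **elevated**: CI above the mean but not clear of the 95th percentile;
- **high**: CI entirely above the 95th percentile.

Panels enter categorisation only if their case/control AUC exceeds 0.6.
AUC = P(case score > control score) + ½·P(tie), computed by exact
enumeration of both genotype distributions (control: HWE; case: OR-tilted)
for m ≤ 8, else seeded Monte Carlo.

## Cross-population comparison

- **Multi-marker panels**: Kruskal–Wallis on composite scores
  (scipy), then hand-written Dunn pairwise z statistics with the tie
  correction Σ(t³−t)/(12(N−1)) and Bonferroni adjustment capped at 1.
  Pairwise calls are suppressed when the omnibus is not significant.
- **Single-marker panels**: genotype-table χ² without continuity
  correction, then ransacking partitioning: pooled two-proportion Z per
  population pair judged against √χ²_crit(0.95, df=3) ≈ 2.7955 (reported
  rounded as 2.8). The ransacking threshold inherits the omnibus degrees
  of freedom, keeping the family of pairwise partitions no more liberal
  than the omnibus test that licensed them.
- Degenerate inputs (all observations identical, zero-variance pooled
  frequency) are flagged explicitly with P = 1 / non-significant rather
  than producing NaN.

## Synthetic cohorts

The simulator exists to validate the statistics by parameter recovery,
not to emulate real genomes:

- **Balding–Nichols**: population frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F)
  around ancestral p; mean p, variance p(1−p)F. F_ST = 0 returns the
  ancestral frequencies exactly.
- Genotypes are Binomial(2, p) per marker (HWE, linkage equilibrium);
  missingness is independent per entry.
- Cases are drawn from the OR-tilted genotype law
  ∝ {(1−p)², 2p(1−p)·OR, p²·OR²}, which reproduces the allelic-model case
  frequency p·OR/(1−p+p·OR) and lets planted ORs be recovered.
- Correlated blocks (`simulate_block_genotypes`) flip haplotypes off a
  latent template to exercise LD pruning.
- Recruitment manifests assign disjoint exclusion flags (non-Chinese,
  non-Han, QC failure) and a birthplace split, reproducing staged
  exclusion accounting exactly.

Not modelled: realistic LD structure, imputation error, genotyping batch
effects, sex chromosomes, admixture within a population, or any phenotype
model beyond the per-marker allelic tilt.

## Pipeline and determinism

`run_pipeline` chains simulate → exclude → qc → panel → score →
categorize → compare, writing one TSV per stage plus `config.json` and
`run_manifest.json` (row counts per stage). Stage seeds are spawned from
a single `numpy.random.SeedSequence` and reduced mod 2³¹ so they remain
portable; identical configs produce byte-identical outputs. Failures are
wrapped in `StageError` carrying the stage name; the CLI exits with
10 + stage index so shell callers can tell which stage failed.

`n_background_markers` (default 4,000) adds null markers alongside the
panel markers before QC. Sample-level QC statistics are meaningless at
panel scale — the heterozygosity F estimate has standard deviation
≈ 1.1/√m, so with only ~11 panel markers the ±0.05 window would flag most
of any clean cohort — and real studies compute them from genome-wide
array content. 4,000 markers put the null F spread near 0.017 (±0.05 ≈
3 σ) while keeping the default scenario under half a minute.

## Parameter defaults

| parameter | default | rationale |
|---|---|---|
| call-rate minimum | 0.95 | standard array-QC convention |
| het-F window | ±0.05 | flags contamination (negative) and inbreeding/genotyping failure (positive) |
| relatedness maximum | 0.1875 | midpoint between second- and third-degree relatives |
| marker missingness maximum | 0.05 | standard convention |
| HWE exclusion threshold | 1e-6 | genome-wide-scale Bonferroni-style guard |
| LD prune threshold | r² < 0.8 | strict inequality; removes near-redundant markers only |
| categorisation α | 0.05 | two-sided CI, z ≈ 1.96 |
| high-risk quantile | 0.95 | upper tail of the reference distribution |
| AUC admission gate | > 0.6 | panels below it carry too little discrimination to stratify |
| enumeration cutoff | m ≤ 8 | 3⁸ = 6,561 exact terms; above that, seeded Monte Carlo |

## Limitations

- Markers are treated as independent after LD pruning; residual r² < 0.8
  correlation still mildly double-counts evidence.
- Odds ratios are combined as if estimated without error except where the
  CI machinery explicitly propagates the discovery SEs.
- The untested-marker transfer rule assumes effect portability across
  ancestries, an assumption the categorisation CIs do not widen for.
- Composite scores are relative risk indices; converting them to absolute
  lifetime risk requires external prevalence calibration not attempted
  here.
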
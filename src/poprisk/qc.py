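"""Sample- and SNP-level quality control for genotype cohorts.

Sample filters: call rate, heterozygosity expressed as the
method-of-moments inbreeding coefficient F, and cryptic relatedness from a
pairwise identity estimate. SNP filters, applied to the surviving
samples: per-marker missingness and an exact Hardy-Weinberg test.
Thresholds default to the conventions of standard genotype-QC tooling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2

from .matrix import GenotypeMatrix

__all__ = [
    "QcThresholds",
    "QcReport",
    "EmptyCohortError",
    "sample_call_rate",
    "heterozygosity_f",
    "pairwise_relatedness",
    "hwe_test",
    "apply_qc",
]


class EmptyCohortError(RuntimeError):
    """Raised when quality control removes every sample."""


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds.

    Samples are dropped when call rate falls below ``min_call_rate``, the
    inbreeding coefficient F leaves ``[het_f_low, het_f_high]``, or a
    relatedness estimate exceeds ``max_relatedness`` (0.1875 sits between
    second- and third-degree relatives). SNPs are dropped when missingness
    exceeds ``max_snp_missingness`` or the Hardy-Weinberg exact test P
    falls below ``hwe_p_min``.
    """

    min_call_rate: float = 0.95
    het_f_low: float = -0.05
    het_f_high: float = 0.05
    max_relatedness: float = 0.1875
    max_snp_missingness: float = 0.05
    hwe_p_min: float = 1e-6

    def __post_init__(self) -> None:
        if not 0 <= self.min_call_rate <= 1:
            raise ValueError("min_call_rate outside [0, 1]")
        if self.het_f_low >= self.het_f_high:
            raise ValueError("het_f_low must be below het_f_high")
        if not 0 <= self.max_snp_missingness < 1:
            raise ValueError("max_snp_missingness outside [0, 1)")
        if not 0 < self.hwe_p_min < 1:
            raise ValueError("hwe_p_min outside (0, 1)")


@dataclass
class QcReport:
    """Per-sample and per-SNP metrics, exclusion flags and reconciled counts.

    Each excluded sample carries exactly one primary reason — the first
    failing check in the order call rate, heterozygosity, relatedness.
    """

    sample_metrics: pd.DataFrame  # sample_id, call_rate, het_f, max_relatedness, excluded, reason
    snp_metrics: pd.DataFrame     # rsid, missingness, hwe_p, excluded, reason
    n_samples_in: int = 0
    n_samples_retained: int = 0
    n_snps_in: int = 0
    n_snps_retained: int = 0
    related_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)

    def exclusions_table(self) -> pd.DataFrame:
        """One row per excluded entity with its primary reason."""
        s = self.sample_metrics.loc[self.sample_metrics["excluded"], ["sample_id", "reason"]]
        s = s.rename(columns={"sample_id": "entity"}).assign(kind="sample")
        m = self.snp_metrics.loc[self.snp_metrics["excluded"], ["rsid", "reason"]]
        m = m.rename(columns={"rsid": "entity"}).assign(kind="snp")
        return pd.concat([s, m], ignore_index=True)[["kind", "entity", "reason"]]


def sample_call_rate(genotypes: GenotypeMatrix) -> np.ndarray:
    """Fraction of non-missing genotype calls per sample."""
    if genotypes.n_markers == 0:
        raise ValueError("call rate undefined with zero markers")
    return 1.0 - genotypes.missing_mask.mean(axis=1)


def heterozygosity_f(genotypes: GenotypeMatrix) -> np.ndarray:
    """Method-of-moments inbreeding coefficient F per sample.

    ``F = (E_het - O_het) / E_het`` where O_het counts observed
    heterozygous calls and E_het sums ``2*p*(1-p)`` (cohort allele
    frequency ``p``) over that sample's non-missing markers. Samples whose
    non-missing markers are all monomorphic have no expectation and get
    ``NaN`` (flagged, never a crash).
    """
    p = genotypes.allele_frequencies()
    exp_het_per_marker = 2.0 * p * (1.0 - p)
    observed = np.nansum(genotypes.dosages == 1.0, axis=1).astype(float)
    nonmissing = ~genotypes.missing_mask
    expected = nonmissing @ np.nan_to_num(exp_het_per_marker)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(expected > 0, (expected - observed) / expected, np.nan)


def pairwise_relatedness(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Method-of-moments relatedness for every sample pair.

    For samples j, k the estimate averages
    ``(x_j - 2p)(x_k - 2p) / (2p(1-p))`` over markers non-missing in both
    (cohort allele frequency ``p``; monomorphic markers excluded), plus
    ``1/(n-1)`` to cancel the plug-in bias of estimating ``p`` from a
    cohort that contains both members. It is approximately 0 for
    unrelated Hardy-Weinberg samples and approximately 1 for duplicates.
    Returns columns ``sample_a sample_b relatedness``; empty for cohorts
    of fewer than two samples.
    """
    n = genotypes.n_samples
    if n < 2:
        return pd.DataFrame(columns=["sample_a", "sample_b", "relatedness"])
    p = genotypes.allele_frequencies()
    informative = np.nan_to_num(p * (1 - p)) > 0
    x = genotypes.dosages[:, informative]
    p = p[informative]
    denom = np.sqrt(2.0 * p * (1.0 - p))
    z = (x - 2.0 * p) / denom
    obs = ~np.isnan(z)
    z0 = np.where(obs, z, 0.0)
    cross = z0 @ z0.T
    counts = obs.astype(float) @ obs.astype(float).T
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(counts > 0, cross / counts, np.nan) + 1.0 / (n - 1)
    ia, ib = np.triu_indices(n, k=1)
    return pd.DataFrame(
        {
            "sample_a": [genotypes.sample_ids[i] for i in ia],
            "sample_b": [genotypes.sample_ids[j] for j in ib],
            "relatedness": rel[ia, ib],
        }
    )


def hwe_test(n_hom_ref: int, n_het: int, n_hom_alt: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium P-value for one marker's genotype counts.

    ``method="exact"`` (default) is the exact conditional test: summing,
    over heterozygote counts compatible with the observed allele counts,
    the probabilities of configurations no more probable than the observed
    one. ``method="chisq"`` is the 1-df goodness-of-fit chi-square
    alternative.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotypes observed")
    if method == "chisq":
        return _hwe_chisq(*counts)
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    n_a = 2 * n_hom_ref + n_het       # reference allele count
    n_b = 2 * n_hom_alt + n_het
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0
    # heterozygote counts share the parity of the rare allele count
    hs = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hs) // 2
    hom_common = (max(n_a, n_b) - hs) // 2
    logp = (hs * np.log(2.0)
            - gammaln(hom_rare + 1) - gammaln(hs + 1) - gammaln(hom_common + 1))
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hs == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_chisq(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    n = n_hom_ref + n_het + n_hom_alt
    p = (2 * n_hom_ref + n_het) / (2 * n)
    expected = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2]) * n
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    mask = expected > 0
    stat = ((observed[mask] - expected[mask]) ** 2 / expected[mask]).sum()
    return float(chi2.sf(stat, df=1))


def _snp_hwe_pvalues(genotypes: GenotypeMatrix, method: str) -> np.ndarray:
    out = np.empty(genotypes.n_markers)
    d = genotypes.dosages
    for j in range(genotypes.n_markers):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            out[j] = np.nan
            continue
        out[j] = hwe_test(int((col == 0).sum()), int((col == 1).sum()),
                          int((col == 2).sum()), method=method)
    return out


def apply_qc(
    genotypes: GenotypeMatrix,
    thresholds: QcThresholds | None = None,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QcReport]:
    """Apply sample filters, then SNP filters on the surviving samples.

    Samples failing any sample criterion are removed first (primary reason
    attributed in the order call rate, heterozygosity, relatedness; of a
    related pair, the member with the lower call rate is flagged, ties
    going to the later sample). SNP missingness and Hardy-Weinberg are
    then evaluated on the retained samples only.
    """
    th = thresholds or QcThresholds()
    call = sample_call_rate(genotypes)
    het = heterozygosity_f(genotypes)
    pairs = pairwise_relatedness(genotypes)

    idx = {s: i for i, s in enumerate(genotypes.sample_ids)}
    max_rel = np.zeros(genotypes.n_samples)
    rel_flag = np.zeros(genotypes.n_samples, dtype=bool)
    if len(pairs):
        for a, b, r in pairs.itertuples(index=False):
            if np.isnan(r):
                continue
            ia, ib = idx[a], idx[b]
            max_rel[ia] = max(max_rel[ia], r)
            max_rel[ib] = max(max_rel[ib], r)
            if r > th.max_relatedness:
                # drop the lower-call-rate member; tie -> later sample order
                victim = ib if (call[ib] < call[ia] or call[ib] == call[ia]) else ia
                rel_flag[victim] = True

    reasons = np.full(genotypes.n_samples, "", dtype=object)
    fail_call = call < th.min_call_rate
    fail_het = (het < th.het_f_low) | (het > th.het_f_high) | np.isnan(het)
    reasons[rel_flag] = "relatedness"
    reasons[fail_het] = "heterozygosity"
    reasons[fail_call] = "call_rate"  # highest-priority reason overwrites last
    excluded = fail_call | fail_het | rel_flag

    sample_metrics = pd.DataFrame(
        {
            "sample_id": genotypes.sample_ids,
            "call_rate": call,
            "het_f": het,
            "max_relatedness": max_rel,
            "excluded": excluded,
            "reason": reasons,
        }
    )
    keep_samples = np.flatnonzero(~excluded)
    if keep_samples.size == 0:
        raise EmptyCohortError("quality control removed every sample")
    retained = genotypes.subset(sample_idx=keep_samples)

    missingness = retained.missing_mask.mean(axis=0)
    hwe_p = _snp_hwe_pvalues(retained, method=hwe_method)
    fail_miss = missingness > th.max_snp_missingness
    with np.errstate(invalid="ignore"):
        fail_hwe = np.nan_to_num(hwe_p, nan=0.0) < th.hwe_p_min
    snp_reasons = np.full(retained.n_markers, "", dtype=object)
    snp_reasons[fail_hwe] = "hwe"
    snp_reasons[fail_miss] = "missingness"
    snp_excluded = fail_miss | fail_hwe
    snp_metrics = pd.DataFrame(
        {
            "rsid": retained.rsids,
            "missingness": missingness,
            "hwe_p": hwe_p,
            "excluded": snp_excluded,
            "reason": snp_reasons,
        }
    )
    retained = retained.subset(marker_idx=np.flatnonzero(~snp_excluded))
    report = QcReport(
        sample_metrics=sample_metrics,
        snp_metrics=snp_metrics,
        n_samples_in=genotypes.n_samples,
        n_samples_retained=retained.n_samples,
        n_snps_in=genotypes.n_markers,
        n_snps_retained=retained.n_markers,
        related_pairs=pairs,
    )
    return retained, report
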
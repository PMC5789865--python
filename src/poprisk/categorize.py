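"""Risk categorisation: reduced / average / elevated / high, with AUC panel admission.

Each individual's composite score gets a confidence interval built from
the sampling error of the discovery-study log odds ratios. The interval
is compared against the population reference distribution of the score
under Hardy-Weinberg equilibrium: individuals whose whole interval lies
below the population mean risk are *reduced*, those containing the mean
are *average*, those entirely above the mean are *elevated*, and *high*
when the interval clears the reference 95th percentile. Panels only enter
categorisation reporting when they discriminate simulated cases from
controls with AUC above a threshold (0.6 by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm

from .panel import DiseasePanel, SnpMarker
from .risk import RiskProfile
from .simulate import case_genotype_probs, simulate_case_control

__all__ = [
    "DiscoveryMeta",
    "CategoryResult",
    "ReferenceDistribution",
    "log_or_se",
    "reference_distribution",
    "categorize_individual",
    "categorize_cohort",
    "panel_auc",
    "category_proportions",
]

CATEGORIES = ("reduced", "average", "elevated", "high")


@dataclass(frozen=True)
class DiscoveryMeta:
    """Case/control sizes and control risk-allele frequency of a marker's discovery study."""

    n_cases: int
    n_controls: int
    control_raf: float

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("case/control counts must be positive")
        if not 0 < self.control_raf < 1:
            raise ValueError("control risk-allele frequency must lie in (0, 1)")

    @classmethod
    def from_marker(cls, marker: SnpMarker, population: str) -> "DiscoveryMeta":
        return cls(
            n_cases=marker.n_cases,
            n_controls=marker.n_controls,
            control_raf=marker.risk_allele_freq[population],
        )


@dataclass(frozen=True)
class CategoryResult:
    sample_id: str
    category: str
    score: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.ci_low <= self.score <= self.ci_high:
            raise ValueError("confidence interval must bracket the score")


def log_or_se(marker: SnpMarker, meta: DiscoveryMeta) -> float:
    """Standard error of the log odds ratio from the reconstructed allelic 2x2 table.

    Control allele counts come from the control frequency and 2*n_controls;
    the case risk-allele frequency follows the allelic tilt
    ``p*OR / (1 - p + p*OR)`` at the marker's odds ratio. SE is the usual
    Woolf ``sqrt(1/a + 1/b + 1/c + 1/d)``.
    """
    p = meta.control_raf
    orx = marker.or_per_allele
    q = p * orx / (1 - p + p * orx)
    a = 2 * meta.n_cases * q          # case risk alleles
    b = 2 * meta.n_cases * (1 - q)
    c = 2 * meta.n_controls * p       # control risk alleles
    d = 2 * meta.n_controls * (1 - p)
    if min(a, b, c, d) < 1:
        raise ValueError(
            f"{marker.rsid}: reconstructed allele-table cell below 1; "
            "apply a continuity correction or supply larger study sizes"
        )
    return float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))


@dataclass
class ReferenceDistribution:
    """Population distribution of the composite score under HWE.

    Either an exact enumeration (``support``/``probs`` set) or a seeded
    Monte-Carlo sample (``samples`` set).
    """

    disease_name: str
    support: np.ndarray | None = None
    probs: np.ndarray | None = None
    samples: np.ndarray | None = None

    @property
    def exact(self) -> bool:
        return self.support is not None

    def mean(self) -> float:
        if self.exact:
            return float((self.support * self.probs).sum())
        return float(self.samples.mean())

    def quantile(self, q: float) -> float:
        """Smallest score s with P(score <= s) >= q."""
        if self.exact:
            order = np.argsort(self.support)
            cdf = np.cumsum(self.probs[order])
            return float(self.support[order][np.searchsorted(cdf, q)])
        return float(np.quantile(self.samples, q))


def _enumerate_combos(m: int) -> np.ndarray:
    return np.array(list(itertools.product((0, 1, 2), repeat=m)), dtype=float)


def _hwe_probs(p: np.ndarray) -> np.ndarray:
    return np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=1)


def _combo_scores(panel: DiseasePanel, combos: np.ndarray) -> np.ndarray:
    log_or = np.log(panel.odds_ratios())
    return np.exp(combos @ log_or / len(panel.markers))


def reference_distribution(
    panel: DiseasePanel,
    freqs: np.ndarray | list[float],
    max_enumeration: int = 8,
    mc_draws: int = 100_000,
    seed: int = 0,
) -> ReferenceDistribution:
    """Distribution of the composite score in an HWE population at ``freqs``.

    Exact enumeration over all 3^m genotype combinations when the panel has
    at most ``max_enumeration`` markers; otherwise a seeded Monte-Carlo
    sample of ``mc_draws`` individuals.
    """
    p = np.asarray(freqs, dtype=float)
    m = len(panel.markers)
    if p.size != m:
        raise ValueError("freqs must align with panel markers")
    if m <= max_enumeration:
        combos = _enumerate_combos(m)
        gp = _hwe_probs(p)
        probs = np.prod(gp[np.arange(m), combos.astype(int)], axis=1)
        return ReferenceDistribution(
            disease_name=panel.disease_name,
            support=_combo_scores(panel, combos),
            probs=probs,
        )
    rng = np.random.default_rng(seed)
    dose = rng.binomial(2, p, size=(mc_draws, m)).astype(float)
    return ReferenceDistribution(
        disease_name=panel.disease_name,
        samples=_combo_scores(panel, dose),
    )


def categorize_individual(
    profile: RiskProfile,
    dosages: np.ndarray | list[float],
    se_by_marker: np.ndarray | list[float],
    reference: ReferenceDistribution,
    alpha: float = 0.05,
    high_quantile: float = 0.95,
) -> CategoryResult:
    """Allocate one individual to a risk category.

    The CI on the log composite score is
    ``log s ± z_(1-alpha/2) * sqrt(sum d_i^2 SE_i^2) / k`` over the k
    markers used. Against the reference mean risk mu and its
    ``high_quantile`` score q: reduced if the CI lies below mu, average if
    it contains mu, elevated if it lies above mu but starts at or below q,
    high if it starts above q.
    """
    d = np.asarray(dosages, dtype=float)
    se = np.asarray(se_by_marker, dtype=float)
    if d.size != se.size:
        raise ValueError("one SE required per marker")
    if np.isnan(se[~np.isnan(d)]).any():
        raise ValueError("missing SE for a used marker")
    if not profile.defined:
        raise ValueError(f"{profile.sample_id}: score undefined (no usable markers)")
    used = ~np.isnan(d)
    k = used.sum()
    half = norm.ppf(1 - alpha / 2) * np.sqrt((d[used] ** 2 * se[used] ** 2).sum()) / k
    log_s = np.log(profile.score)
    ci_low, ci_high = float(np.exp(log_s - half)), float(np.exp(log_s + half))
    mu = reference.mean()
    q_hi = reference.quantile(high_quantile)
    if ci_high < mu:
        category = "reduced"
    elif ci_low <= mu:
        category = "average"
    elif ci_low > q_hi:
        category = "high"
    else:
        category = "elevated"
    return CategoryResult(
        sample_id=profile.sample_id,
        category=category,
        score=profile.score,
        ci_low=ci_low,
        ci_high=ci_high,
    )


def categorize_cohort(
    panel: DiseasePanel,
    genotypes,
    reference: ReferenceDistribution,
    se_by_marker: np.ndarray | list[float] | None = None,
    control_population: str | None = None,
    alpha: float = 0.05,
    high_quantile: float = 0.95,
) -> list[CategoryResult]:
    """Categorise every sample of a cohort for one disease panel.

    Marker SEs may be given directly or reconstructed from each marker's
    discovery metadata and its control frequency for ``control_population``.
    """
    from .risk import composite_risk  # local import keeps module load order simple

    if se_by_marker is None:
        if control_population is None:
            raise ValueError("supply se_by_marker or control_population")
        se_by_marker = [
            log_or_se(m, DiscoveryMeta.from_marker(m, control_population))
            for m in panel.markers
        ]
    aligned = genotypes.select_markers(panel.rsids)
    results = []
    for i, sid in enumerate(aligned.sample_ids):
        dose = aligned.dosages[i]
        profile = composite_risk(panel, dose, sample_id=sid,
                                 population_label=aligned.populations[i])
        if not profile.defined:
            continue
        results.append(
            categorize_individual(profile, dose, se_by_marker, reference,
                                  alpha=alpha, high_quantile=high_quantile)
        )
    return results


def panel_auc(
    panel: DiseasePanel,
    freqs: np.ndarray | list[float],
    n_sim: int = 10_000,
    seed: int = 0,
    max_enumeration: int = 8,
) -> float:
    """Case/control discrimination of the panel's composite score.

    AUC = P(case score > control score) + 0.5 P(tie), computed exactly by
    genotype enumeration for panels of at most ``max_enumeration`` markers
    and otherwise from ``n_sim`` simulated cases and controls per arm.
    """
    p = np.asarray(freqs, dtype=float)
    m = len(panel.markers)
    if m <= max_enumeration:
        combos = _enumerate_combos(m)
        scores = _combo_scores(panel, combos)
        idx = combos.astype(int)
        ctrl_probs = np.prod(_hwe_probs(p)[np.arange(m), idx], axis=1)
        case_probs = np.prod(
            case_genotype_probs(p, panel.odds_ratios())[np.arange(m), idx], axis=1
        )
        order = np.argsort(scores, kind="stable")
        s, pc, pt = scores[order], case_probs[order], ctrl_probs[order]
        # collapse tied scores so P(tie) is counted once
        uniq, inv = np.unique(np.round(s, 12), return_inverse=True)
        pc_u = np.bincount(inv, weights=pc, minlength=uniq.size)
        pt_u = np.bincount(inv, weights=pt, minlength=uniq.size)
        ctrl_below = np.concatenate([[0.0], np.cumsum(pt_u)[:-1]])
        return float((pc_u * (ctrl_below + 0.5 * pt_u)).sum())
    if n_sim < 1_000:
        warnings.warn("panel_auc with n_sim < 1000 is noisy", stacklevel=2)
    cases, controls = simulate_case_control(panel, p, n_sim, n_sim, seed=seed)
    from .risk import score_cohort

    sc = score_cohort(panel, cases)["score"].to_numpy()
    st = score_cohort(panel, controls)["score"].to_numpy()
    u = mannwhitneyu(sc, st, alternative="two-sided").statistic
    return float(u / (len(sc) * len(st)))


def category_proportions(results: list[CategoryResult]) -> pd.Series:
    """Fraction of the cohort per category, plus the combined high+elevated burden.

    The returned series carries reduced/average/elevated/high fractions
    (summing to 1), ``high_or_elevated``, and ``exceeds_10pct`` — whether
    more than 10% of the cohort has high or elevated genetic risk.
    """
    if not results:
        raise ValueError("no category results supplied")
    n = len(results)
    counts = {c: 0 for c in CATEGORIES}
    for r in results:
        counts[r.category] += 1
    fractions = {c: counts[c] / n for c in CATEGORIES}
    combined = fractions["high"] + fractions["elevated"]
    return pd.Series({**fractions, "high_or_elevated": combined,
                      "exceeds_10pct": combined > 0.10})
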
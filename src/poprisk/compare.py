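"""Cross-population comparison of genetic risk distributions.

Diseases scored from several markers are compared with a Kruskal-Wallis
omnibus test followed by Dunn's rank-based pairwise comparisons with
Bonferroni adjustment. Diseases resting on a single marker are compared
as genotype contingency tables with a Pearson chi-square omnibus test,
followed by a ransacking-style pairwise partition: a two-proportion Z on
risk-allele frequencies judged against the square root of the omnibus
chi-square critical value (2.8 at 3 degrees of freedom, alpha 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, chi2_contingency, kruskal, norm, rankdata

from .matrix import GenotypeMatrix
from .panel import DiseasePanel
from .risk import score_cohort

__all__ = [
    "KruskalResult",
    "ComparisonResult",
    "kruskal_wallis",
    "dunn_posthoc",
    "chisq_single_snp",
    "ransacking_critical_value",
    "ransacking_posthoc",
    "compare_all",
]


@dataclass(frozen=True)
class KruskalResult:
    h: float
    p: float
    degenerate: bool = False  # all observations identical; tie correction vanishes


@dataclass
class ComparisonResult:
    """Omnibus P and pairwise decisions for one disease."""

    disease_name: str
    method: str  # "kruskal_dunn" or "chisq_ransacking"
    omnibus_stat: float
    omnibus_p: float
    pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    # pairs columns: pop_a, pop_b, statistic, adjusted_p (NaN on the Z route),
    #                significant, direction in {a_greater, b_greater, none}


def _check_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(out):
        if g.size == 0:
            raise ValueError(f"group {i} is empty")
    return out


def kruskal_wallis(groups: list[np.ndarray | list[float]]) -> KruskalResult:
    """Kruskal-Wallis H with tie correction; P from chi-square with g-1 df.

    When every observation across all groups is identical the tie-corrected
    statistic is undefined; the result is reported as P = 1 with the
    ``degenerate`` flag set.
    """
    gs = _check_groups(groups)
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return KruskalResult(h=0.0, p=1.0, degenerate=True)
    stat, p = kruskal(*gs)
    return KruskalResult(h=float(stat), p=float(p))


def dunn_posthoc(
    groups: list[np.ndarray | list[float]],
    labels: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunn's pairwise mean-rank comparisons with Bonferroni adjustment.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with
    the tie term T = sum(t^3 - t) / (12 (N-1)). Two-sided P values are
    multiplied by the number of pairs and capped at 1. A pair is
    significant at adjusted P < ``alpha``; its direction comes from the
    mean ranks.
    """
    gs = _check_groups(groups)
    labels = labels or [f"group{i}" for i in range(len(gs))]
    if len(labels) != len(gs):
        raise ValueError("one label required per group")
    pooled = np.concatenate(gs)
    n_total = pooled.size
    ranks = rankdata(pooled)
    sizes = [g.size for g in gs]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(gs))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n_total - 1)) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12 - tie_term
    n_pairs = len(gs) * (len(gs) - 1) // 2
    rows = []
    for i in range(len(gs)):
        for j in range(i + 1, len(gs)):
            denom = np.sqrt(var_base * (1 / sizes[i] + 1 / sizes[j]))
            if denom == 0:
                z, p_adj = 0.0, 1.0
            else:
                z = (mean_ranks[i] - mean_ranks[j]) / denom
                p_adj = min(1.0, 2 * norm.sf(abs(z)) * n_pairs)
            significant = p_adj < alpha
            if not significant:
                direction = "none"
            else:
                direction = "a_greater" if z > 0 else "b_greater"
            rows.append(
                {
                    "pop_a": labels[i], "pop_b": labels[j],
                    "statistic": z, "adjusted_p": p_adj,
                    "significant": significant, "direction": direction,
                }
            )
    return pd.DataFrame(rows)


def chisq_single_snp(counts: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square on a populations x genotype-categories table.

    Returns (statistic, degrees of freedom, P). Warns when any expected
    cell falls below 1.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if np.any(table.sum(axis=1) <= 0) or np.any(table.sum(axis=0) <= 0):
        raise ValueError("every row and column must have a positive total")
    res = chi2_contingency(table, correction=False)
    if np.any(res.expected_freq < 1):
        warnings.warn("expected cell count below 1; chi-square approximation is poor",
                      stacklevel=2)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def ransacking_critical_value(alpha: float = 0.05, df_omnibus: int = 3) -> float:
    """Square root of the chi-square critical value (2.8 at alpha 0.05, 3 df)."""
    return float(np.sqrt(chi2.ppf(1 - alpha, df_omnibus)))


def ransacking_posthoc(
    allele_counts: dict[str, tuple[int, int]],
    df_omnibus: int = 3,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise partition of a significant contingency-table chi-square.

    ``allele_counts`` maps population label to (risk-allele count, total
    allele count). For each pair a pooled-variance two-proportion Z on
    risk-allele frequency is compared against the square root of the
    omnibus chi-square critical value. Pairs with zero pooled variance are
    reported non-significant with the ``degenerate`` flag.
    """
    labels = list(allele_counts)
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    crit = ransacking_critical_value(alpha=alpha, df_omnibus=df_omnibus)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            x1, n1 = allele_counts[labels[i]]
            x2, n2 = allele_counts[labels[j]]
            p1, p2 = x1 / n1, x2 / n2
            pool = (x1 + x2) / (n1 + n2)
            var = pool * (1 - pool) * (1 / n1 + 1 / n2)
            degenerate = var == 0
            z = 0.0 if degenerate else (p1 - p2) / np.sqrt(var)
            significant = (not degenerate) and abs(z) > crit
            if not significant:
                direction = "none"
            else:
                direction = "a_greater" if z > 0 else "b_greater"
            rows.append(
                {
                    "pop_a": labels[i], "pop_b": labels[j],
                    "statistic": z, "adjusted_p": np.nan,
                    "significant": significant, "direction": direction,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


def _genotype_table(genotypes: GenotypeMatrix, rsid: str) -> tuple[pd.DataFrame, dict]:
    """Populations x genotype counts and per-population allele counts for one marker."""
    j = genotypes.marker_index(rsid)
    rows, alleles = {}, {}
    for label, sub in genotypes.by_population().items():
        col = sub.dosages[:, j]
        col = col[~np.isnan(col)]
        rows[label] = [int((col == d).sum()) for d in (0, 1, 2)]
        alleles[label] = (int(col.sum()), 2 * col.size)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["d0", "d1", "d2"])
    return table, alleles


def compare_all(
    panels: dict[str, DiseasePanel],
    genotypes: GenotypeMatrix,
    populations: list[str] | None = None,
    alpha: float = 0.05,
    df_omnibus: int = 3,
) -> list[ComparisonResult]:
    """One comparison per disease, dispatching on panel size after pruning.

    Multi-marker panels go through Kruskal-Wallis and Dunn's pairwise
    comparisons on the composite scores; single-marker panels through the
    chi-square / ransacking route on genotype tables. Requires at least
    two populations with at least two samples each; raises if a requested
    population is absent from the cohort.
    """
    present = dict.fromkeys(genotypes.populations)
    pops = populations or list(present)
    for pop in pops:
        if pop not in present:
            raise ValueError(f"population {pop!r} absent from the cohort")
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    by_pop = {k: v for k, v in genotypes.by_population().items() if k in pops}
    for label, sub in by_pop.items():
        if sub.n_samples < 2:
            raise ValueError(f"population {label!r} has fewer than two samples")

    results = []
    for disease, panel in panels.items():
        if len(panel.markers) == 0:
            continue
        if len(panel.markers) > 1:
            scores = score_cohort(panel, genotypes)
            groups, labels = [], []
            for pop in pops:
                vals = scores.loc[scores["population"] == pop, "score"].dropna().to_numpy()
                groups.append(vals)
                labels.append(pop)
            omnibus = kruskal_wallis(groups)
            pairs = dunn_posthoc(groups, labels, alpha=alpha)
            if omnibus.p >= alpha:
                # pairwise decisions only reported under a significant omnibus
                pairs = pairs.assign(significant=False, direction="none")
            results.append(
                ComparisonResult(
                    disease_name=disease, method="kruskal_dunn",
                    omnibus_stat=omnibus.h, omnibus_p=omnibus.p, pairs=pairs,
                )
            )
        else:
            table, alleles = _genotype_table(
                GenotypeMatrix.concat_samples([by_pop[p] for p in pops]),
                panel.markers[0].rsid,
            )
            # drop genotype columns absent everywhere (chi-square needs positive margins)
            table = table.loc[pops, table.sum(axis=0) > 0]
            stat, _, p = chisq_single_snp(table)
            if p < alpha:
                pairs = ransacking_posthoc(alleles, df_omnibus=df_omnibus, alpha=alpha)
            else:
                pairs = ransacking_posthoc(alleles, df_omnibus=df_omnibus, alpha=alpha)
                pairs = pairs.assign(significant=False, direction="none")
            results.append(
                ComparisonResult(
                    disease_name=disease, method="chisq_ransacking",
                    omnibus_stat=stat, omnibus_p=p, pairs=pairs,
                )
            )
    return results


def comparison_report(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flat report: ``disease omnibus_p pair statistic adjusted_p significant direction method``."""
    rows = []
    for res in results:
        for rec in res.pairs.itertuples(index=False):
            rows.append(
                {
                    "disease": res.disease_name,
                    "omnibus_p": res.omnibus_p,
                    "pair": f"{rec.pop_a} vs {rec.pop_b}",
                    "statistic": rec.statistic,
                    "adjusted_p": rec.adjusted_p,
                    "significant": rec.significant,
                    "direction": rec.direction,
                    "method": res.method,
                }
            )
    return pd.DataFrame(rows)
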
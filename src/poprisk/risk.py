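"""Composite multiplicative genetic risk scores and population risk distributions.

An individual's composite risk for a disease is the geometric mean of the
genotype odds ratios across the disease's markers: multiply OR^dosage over
all non-missing markers, then take the k-th root where k is the number of
markers actually used. A score of 1 means population-average multiplicative
risk; the geometric mean keeps scores comparable between individuals typed
at different marker subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .panel import DiseasePanel, SnpMarker

__all__ = [
    "RiskProfile",
    "CumulativeDistribution",
    "genotype_or",
    "composite_risk",
    "score_cohort",
    "carrier_frequency",
    "cumulative_distribution",
]


@dataclass(frozen=True)
class RiskProfile:
    """Composite risk score of one individual for one disease.

    ``score`` is NaN, with ``defined`` False, when every panel marker was
    missing for the sample (k = 0); it is never silently reported as 1.
    """

    sample_id: str
    disease_name: str
    score: float
    n_snps_used: int
    population_label: str = "pop"

    @property
    def defined(self) -> bool:
        return self.n_snps_used > 0


def genotype_or(marker: SnpMarker, dosage: int | float) -> float:
    """Genotype odds ratio ``OR^dosage`` (1, OR, or OR² under the multiplicative model)."""
    if isinstance(dosage, float) and np.isnan(dosage):
        raise ValueError(f"{marker.rsid}: missing dosage has no genotype OR; "
                         "composite_risk drops missing markers instead")
    if dosage not in (0, 1, 2):
        raise ValueError(f"{marker.rsid}: dosage must be 0, 1 or 2, got {dosage!r}")
    return float(marker.or_per_allele ** dosage)


def composite_risk(
    panel: DiseasePanel,
    sample_dosages: np.ndarray | list[float],
    sample_id: str = "sample",
    population_label: str = "pop",
) -> RiskProfile:
    """Geometric-mean genotype OR across the panel's non-missing markers.

    score = (prod over non-missing markers of OR_i^d_i) ** (1/k),
    with k the number of non-missing markers (reported as ``n_snps_used``).
    """
    d = np.asarray(sample_dosages, dtype=float)
    if d.size != len(panel.markers):
        raise ValueError(
            f"{sample_id}: {d.size} dosages for {len(panel.markers)} panel markers"
        )
    used = ~np.isnan(d)
    k = int(used.sum())
    if k == 0:
        score = float("nan")
    else:
        log_or = np.log(panel.odds_ratios()[used])
        score = float(np.exp((d[used] * log_or).sum() / k))
    return RiskProfile(
        sample_id=sample_id,
        disease_name=panel.disease_name,
        score=score,
        n_snps_used=k,
        population_label=population_label,
    )


def score_cohort(panel: DiseasePanel, genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Composite score per sample; columns ``sample_id population disease score n_snps_used``.

    The genotype matrix must contain every panel marker (columns are
    aligned by rsid). Samples with no usable marker get NaN scores.
    """
    aligned = genotypes.select_markers(panel.rsids)
    d = aligned.dosages
    used = ~np.isnan(d)
    k = used.sum(axis=1)
    log_or = np.log(panel.odds_ratios())
    total = np.nansum(d * log_or, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        score = np.where(k > 0, np.exp(total / np.maximum(k, 1)), np.nan)
    return pd.DataFrame(
        {
            "sample_id": aligned.sample_ids,
            "population": aligned.populations,
            "disease": panel.disease_name,
            "score": score,
            "n_snps_used": k.astype(int),
        }
    )


def carrier_frequency(
    genotypes: GenotypeMatrix, marker: SnpMarker, allele: str = "risk"
) -> float:
    """Fraction of samples carrying at least one copy of the named allele.

    ``allele`` is ``"risk"`` or ``"protective"`` (the protective dosage is
    ``2 - risk dosage``). Computed over samples with a non-missing call;
    raises if the marker is entirely missing.
    """
    if allele not in ("risk", "protective"):
        raise ValueError("allele must be 'risk' or 'protective'")
    col = genotypes.dosages[:, genotypes.marker_index(marker.rsid)]
    col = col[~np.isnan(col)]
    if col.size == 0:
        raise ValueError(f"{marker.rsid}: every sample is missing")
    if allele == "protective":
        col = 2.0 - col
    return float((col >= 1).mean())


@dataclass
class CumulativeDistribution:
    """Empirical cumulative distribution of composite scores for one population."""

    scores: np.ndarray  # sorted ascending
    population_label: str
    disease_name: str

    def percentile(self, q: float | np.ndarray) -> np.ndarray:
        """Score at population percentile ``q`` in [0, 100] (linear interpolation)."""
        return np.percentile(self.scores, q)

    def to_dataframe(self, percentiles: np.ndarray | None = None) -> pd.DataFrame:
        """Table ``population percentile score`` (percent-of-population on the x-axis)."""
        q = np.arange(0, 101) if percentiles is None else np.asarray(percentiles)
        return pd.DataFrame(
            {
                "population": self.population_label,
                "percentile": q,
                "score": self.percentile(q),
            }
        )


def cumulative_distribution(profiles: list[RiskProfile]) -> CumulativeDistribution:
    """Empirical CDF of the defined scores in ``profiles`` (one disease, one population)."""
    if not profiles:
        raise ValueError("no profiles supplied")
    diseases = {p.disease_name for p in profiles}
    if len(diseases) > 1:
        raise ValueError(f"profiles mix diseases: {sorted(diseases)}")
    pops = {p.population_label for p in profiles}
    label = pops.pop() if len(pops) == 1 else "combined"
    scores = np.sort([p.score for p in profiles if p.defined])
    if scores.size == 0:
        raise ValueError("every profile is undefined (no usable markers)")
    return CumulativeDistribution(
        scores=scores, population_label=label, disease_name=diseases.pop()
    )
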
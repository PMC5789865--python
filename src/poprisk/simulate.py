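"""Synthetic multi-population cohorts with the statistical structure the pipeline assumes.

Per-population allele frequencies diverge from a shared ancestral
frequency under the Balding-Nichols model, genotypes are drawn in
Hardy-Weinberg equilibrium, discovery-style case/control samples are
tilted marker-wise by the multiplicative odds-ratio model, and a
recruitment manifest carries the exclusion flags the ingestion stage
consumes. All draws are reproducible from integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .panel import DiseasePanel

__all__ = [
    "PopulationSpec",
    "RecruitmentManifest",
    "simulate_allele_freqs",
    "simulate_genotypes",
    "simulate_case_control",
    "make_recruitment_manifest",
    "block_r2_matrix",
    "simulate_block_genotypes",
]

ETHNICITIES = ("han", "non_han_chinese", "non_chinese")


@dataclass(frozen=True)
class PopulationSpec:
    """One simulated population: label, cohort size and divergence (Fst) from the ancestral pool."""

    label: str
    n_samples: int
    fst: float = 0.0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ValueError(f"{self.label}: n_samples must be positive")
        if not 0 <= self.fst < 1:
            raise ValueError(f"{self.label}: fst must lie in [0, 1)")


@dataclass
class RecruitmentManifest:
    """Recruitment roster: per-sample ethnicity, QC outcome and birthplace flags."""

    table: pd.DataFrame  # columns: sample_id, ethnicity, qc_pass, birthplace

    def __post_init__(self) -> None:
        required = {"sample_id", "ethnicity", "qc_pass", "birthplace"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"manifest requires columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample_ids must be unique")
        bad = set(self.table["ethnicity"]) - set(ETHNICITIES)
        if bad:
            raise ValueError(f"unknown ethnicity values: {sorted(bad)}")
        bad = set(self.table["birthplace"]) - {"local_born", "non_local_born"}
        if bad:
            raise ValueError(f"unknown birthplace values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)


def simulate_allele_freqs(
    ancestral_freqs: np.ndarray | list[float],
    populations: list[PopulationSpec],
    seed: int,
) -> dict[str, np.ndarray]:
    """Draw per-population allele frequencies around shared ancestral ones.

    Under the Balding-Nichols model the frequency of a marker in a
    population with divergence ``F`` is Beta(p(1-F)/F, (1-p)(1-F)/F),
    which has mean ``p`` and variance ``p(1-p)F``. Zero divergence returns
    the ancestral frequencies exactly.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    labels = [spec.label for spec in populations]
    if len(set(labels)) != len(labels):
        raise ValueError("population labels must be unique")
    streams = np.random.SeedSequence(seed).spawn(len(populations))
    out: dict[str, np.ndarray] = {}
    for spec, ss in zip(populations, streams):
        if spec.fst == 0:
            out[spec.label] = p.copy()
            continue
        rng = np.random.default_rng(ss)
        c = (1.0 - spec.fst) / spec.fst
        out[spec.label] = rng.beta(p * c, (1.0 - p) * c)
    return out


def simulate_genotypes(
    freqs: np.ndarray | list[float],
    n: int,
    missing_rate: float = 0.0,
    seed: int = 0,
    population: str = "pop",
    rsids: list[str] | None = None,
    sample_prefix: str | None = None,
) -> GenotypeMatrix:
    """Draw ``n`` diploid samples in Hardy-Weinberg equilibrium.

    Dosages are Binomial(2, p) per marker; entries are then masked missing
    independently at ``missing_rate``.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    p = np.asarray(freqs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    dose = rng.binomial(2, p, size=(n, p.size)).astype(float)
    if missing_rate > 0:
        dose[rng.random((n, p.size)) < missing_rate] = np.nan
    prefix = sample_prefix if sample_prefix is not None else population
    return GenotypeMatrix(
        dosages=dose,
        sample_ids=[f"{prefix}_{i:05d}" for i in range(n)],
        rsids=rsids or [f"rs{j + 1}" for j in range(p.size)],
        populations=[population] * n,
    )


def case_genotype_probs(p: np.ndarray, odds_ratios: np.ndarray) -> np.ndarray:
    """HWE genotype probabilities tilted by the multiplicative OR model.

    Returns an (m, 3) array of case genotype probabilities proportional to
    ``{(1-p)^2, 2p(1-p)*OR, p^2*OR^2}`` per marker.
    """
    p = np.asarray(p, dtype=float)
    orx = np.asarray(odds_ratios, dtype=float)
    if np.any(orx <= 0):
        raise ValueError("odds ratios must be positive")
    w = np.stack([(1 - p) ** 2, 2 * p * (1 - p) * orx, p**2 * orx**2], axis=1)
    return w / w.sum(axis=1, keepdims=True)


def simulate_case_control(
    panel: DiseasePanel,
    control_freqs: np.ndarray | list[float],
    n_cases: int,
    n_controls: int,
    seed: int = 0,
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Draw a discovery-style case/control pair for one disease panel.

    Controls follow HWE at the control frequencies. Cases are drawn per
    marker from the OR-tilted genotype distribution (markers independent),
    which makes the population case risk-allele frequency equal to the
    allelic tilt ``p*OR / (1 - p + p*OR)``.
    """
    p = np.asarray(control_freqs, dtype=float)
    if p.size != len(panel.markers):
        raise ValueError("control_freqs must align with panel markers")
    ss = np.random.SeedSequence(seed).spawn(2)
    controls = simulate_genotypes(
        p, n_controls, seed=ss[0], population="control",
        rsids=panel.rsids, sample_prefix="ctrl",
    )
    probs = case_genotype_probs(p, panel.odds_ratios())
    rng = np.random.default_rng(ss[1])
    cum = probs.cumsum(axis=1)  # (m, 3)
    u = rng.random((n_cases, p.size))
    dose = (u[:, :, None] > cum[None, :, :2]).sum(axis=2).astype(float)
    cases = GenotypeMatrix(
        dosages=dose,
        sample_ids=[f"case_{i:05d}" for i in range(n_cases)],
        rsids=panel.rsids,
        populations=["case"] * n_cases,
    )
    return cases, controls


def make_recruitment_manifest(
    n_total: int,
    n_non_chinese: int,
    n_non_han: int,
    n_qc_fail: int,
    n_non_local_born: int,
    seed: int = 0,
) -> RecruitmentManifest:
    """Build a recruitment roster with the requested exclusion-flag counts.

    Exclusion flags (non-Chinese, non-Han Chinese, QC failure) are assigned
    to disjoint randomly chosen samples; ``n_non_local_born`` of the
    remaining unflagged samples are marked as born elsewhere.
    """
    n_flagged = n_non_chinese + n_non_han + n_qc_fail
    if min(n_total, n_non_chinese, n_non_han, n_qc_fail, n_non_local_born) < 0:
        raise ValueError("counts must be non-negative")
    if n_flagged > n_total:
        raise ValueError(f"exclusion flags ({n_flagged}) exceed cohort size ({n_total})")
    if n_non_local_born > n_total - n_flagged:
        raise ValueError("non-local-born count exceeds unflagged samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_total)
    ethnicity = np.full(n_total, "han", dtype=object)
    qc_pass = np.ones(n_total, dtype=bool)
    birthplace = np.full(n_total, "local_born", dtype=object)
    i = 0
    ethnicity[order[i:i + n_non_chinese]] = "non_chinese"
    i += n_non_chinese
    ethnicity[order[i:i + n_non_han]] = "non_han_chinese"
    i += n_non_han
    qc_pass[order[i:i + n_qc_fail]] = False
    i += n_qc_fail
    birthplace[order[i:i + n_non_local_born]] = "non_local_born"
    table = pd.DataFrame(
        {
            "sample_id": [f"S{k:05d}" for k in range(n_total)],
            "ethnicity": ethnicity,
            "qc_pass": qc_pass,
            "birthplace": birthplace,
        }
    )
    return RecruitmentManifest(table)


# ---------------------------------------------------------------------------
# Block-correlated markers (exists solely to exercise LD pruning)
# ---------------------------------------------------------------------------

def block_r2_matrix(n_markers: int, block_size: int, within_r2: float = 0.95) -> np.ndarray:
    """Block-diagonal pairwise r-squared: ``within_r2`` inside consecutive blocks, 0 across."""
    if not 0 <= within_r2 <= 1:
        raise ValueError("within_r2 must lie in [0, 1]")
    r2 = np.zeros((n_markers, n_markers))
    for start in range(0, n_markers, block_size):
        stop = min(start + block_size, n_markers)
        r2[start:stop, start:stop] = within_r2
    np.fill_diagonal(r2, 1.0)
    return r2


def simulate_block_genotypes(
    freqs: np.ndarray | list[float],
    n: int,
    block_size: int,
    flip_prob: float = 0.02,
    seed: int = 0,
    population: str = "pop",
) -> GenotypeMatrix:
    """HWE genotypes where markers within a block are noisy copies of a template.

    Each block shares latent template alleles at the first marker's
    frequency; per-marker alleles flip independently with ``flip_prob``,
    giving high (but imperfect) within-block correlation and none across.
    """
    p = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    m = p.size
    dose = np.empty((n, m))
    for start in range(0, m, block_size):
        stop = min(start + block_size, m)
        template = rng.random((n, 2)) < p[start]  # two latent haplotypes
        for j in range(start, stop):
            flips = rng.random((n, 2)) < flip_prob
            alleles = template ^ flips
            dose[:, j] = alleles.sum(axis=1)
    return GenotypeMatrix(
        dosages=dose,
        sample_ids=[f"{population}_{i:05d}" for i in range(n)],
        rsids=[f"rs{j + 1}" for j in range(m)],
        populations=[population] * n,
    )
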
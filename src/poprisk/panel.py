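"""Disease SNP panels: data model, inclusion criteria, population transfer, LD pruning.

A *panel* is the set of GWAS-reported risk variants used to score one
disease or trait. Markers enter a panel only if their discovery evidence
clears study-type-specific P-value thresholds; panels assembled from
European-ancestry GWAS can be adapted to an East-Asian cohort by swapping
in East-Asian effect sizes where they exist, dropping markers that failed
East-Asian replication, and appending markers discovered in East-Asian
studies; finally markers in strong mutual linkage disequilibrium are
pruned so the multiplicative score does not double-count a signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnpMarker",
    "DiseasePanel",
    "InclusionThresholds",
    "filter_by_discovery_criteria",
    "transform_panel",
    "ld_prune",
    "load_panels_tsv",
    "write_panels_tsv",
]

STUDY_TYPES = ("gwas_discovery", "gwas_with_replication", "candidate_snp")
POPULATIONS = ("caucasian", "east_asian", "han_chinese")
EA_STATUSES = ("validated", "tested_null", "untested", "east_asian_discovered")
HERITABILITY_BANDS = ("60-80%", "40-60%", "20-40%", "10-20%", "unknown")


@dataclass(frozen=True)
class SnpMarker:
    """One GWAS risk variant with effect size and discovery-study metadata.

    ``or_per_allele`` is the per-risk-allele odds ratio; homozygous risk
    carriers contribute its square under the multiplicative model.
    ``risk_allele_freq`` optionally maps population labels to the
    risk-allele frequency reported for that population.
    """

    rsid: str
    risk_allele: str
    other_allele: str
    or_per_allele: float
    p_discovery: float
    study_type: str = "gwas_discovery"
    p_replication: float | None = None
    discovery_population: str = "caucasian"
    n_cases: int = 1000
    n_controls: int = 1000
    chrom: str = "1"
    pos: int | None = None
    risk_allele_freq: dict[str, float] = field(default_factory=dict)
    east_asian_status: str = "untested"

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: risk and other allele identical")
        if not self.or_per_allele > 0:
            raise ValueError(f"{self.rsid}: odds ratio must be positive")
        if not 0 < self.p_discovery <= 1:
            raise ValueError(f"{self.rsid}: p_discovery outside (0, 1]")
        if self.p_replication is not None and not 0 < self.p_replication <= 1:
            raise ValueError(f"{self.rsid}: p_replication outside (0, 1]")
        if self.study_type not in STUDY_TYPES:
            raise ValueError(f"{self.rsid}: unknown study_type {self.study_type!r}")
        if self.discovery_population not in POPULATIONS:
            raise ValueError(
                f"{self.rsid}: unknown discovery_population {self.discovery_population!r}"
            )
        if self.east_asian_status not in EA_STATUSES:
            raise ValueError(
                f"{self.rsid}: unknown east_asian_status {self.east_asian_status!r}"
            )
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError(f"{self.rsid}: case/control counts must be positive")
        for pop, f in self.risk_allele_freq.items():
            if not 0 <= f <= 1:
                raise ValueError(f"{self.rsid}: frequency for {pop} outside [0, 1]")

    @property
    def sample_size(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class DiseasePanel:
    """A named disease/trait and its marker set."""

    disease_name: str
    markers: list[SnpMarker]
    prevalence: float | None = None
    heritability_band: str = "unknown"
    lifetime_risk: float | None = None
    endometrial_exception: bool = False

    def __post_init__(self) -> None:
        rsids = [m.rsid for m in self.markers]
        if len(set(rsids)) != len(rsids):
            dup = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValueError(f"{self.disease_name}: duplicate rsids {dup}")
        if self.heritability_band not in HERITABILITY_BANDS:
            raise ValueError(f"unknown heritability band {self.heritability_band!r}")
        for name, v in (("prevalence", self.prevalence), ("lifetime_risk", self.lifetime_risk)):
            if v is not None and not 0 < v < 1:
                raise ValueError(f"{self.disease_name}: {name} outside (0, 1)")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def rsids(self) -> list[str]:
        return [m.rsid for m in self.markers]

    def odds_ratios(self) -> np.ndarray:
        return np.array([m.or_per_allele for m in self.markers])

    def frequencies(self, population: str) -> np.ndarray:
        """Risk-allele frequencies for one population; KeyError if any marker lacks it."""
        out = []
        for m in self.markers:
            if population not in m.risk_allele_freq:
                raise KeyError(f"{m.rsid} has no frequency for population {population!r}")
            out.append(m.risk_allele_freq[population])
        return np.array(out)


@dataclass(frozen=True)
class InclusionThresholds:
    """P-value gates for the three routes into a panel.

    A marker is admitted if it clears any one of: genome-wide significance
    in a discovery GWAS; a weaker discovery signal backed by a significant
    replication; or nominal significance in a candidate-SNP study. The
    discovery gate is relaxed for panels flagged with the endometrial
    exception, where few markers reach genome-wide significance.
    """

    p_gwas: float = 1e-7
    p_gwas_replicated: float = 1e-6
    p_replication: float = 0.05
    p_candidate: float = 0.05
    p_endometrial: float = 1e-5


def filter_by_discovery_criteria(
    markers: list[SnpMarker],
    endometrial_exception: bool = False,
    thresholds: InclusionThresholds | None = None,
) -> list[SnpMarker]:
    """Keep markers whose discovery evidence clears any inclusion route.

    Routes (ANY suffices): (1) discovery GWAS with P below the genome-wide
    gate (relaxed under the endometrial exception); (2) discovery GWAS at
    the weaker gate plus significant replication; (3) candidate-SNP study
    at nominal significance. Order is preserved. Replication-route markers
    lacking a replication P are rejected with a warning, never a crash.
    """
    th = thresholds or InclusionThresholds()
    p_discovery_gate = th.p_endometrial if endometrial_exception else th.p_gwas
    kept: list[SnpMarker] = []
    for m in markers:
        if m.study_type == "gwas_discovery":
            if m.p_discovery < p_discovery_gate:
                kept.append(m)
        elif m.study_type == "gwas_with_replication":
            if m.p_replication is None:
                logger.warning("%s: replication study without p_replication; rejected", m.rsid)
                continue
            if m.p_discovery < th.p_gwas_replicated and m.p_replication < th.p_replication:
                kept.append(m)
        else:  # candidate_snp
            if m.p_discovery < th.p_candidate:
                kept.append(m)
    return kept


def transform_panel(
    panel: DiseasePanel, east_asian_markers: list[SnpMarker]
) -> DiseasePanel:
    """Adapt a European-ancestry panel to an East-Asian cohort.

    Markers validated in East Asians adopt the East-Asian odds ratio;
    markers tested in East Asians with no association are removed; untested
    markers keep their original odds ratio; markers discovered in
    East-Asian studies are appended.
    """
    ea_by_rsid = {m.rsid: m for m in east_asian_markers}
    out: list[SnpMarker] = []
    for m in panel.markers:
        if m.east_asian_status == "validated":
            ea = ea_by_rsid.get(m.rsid)
            if ea is None:
                raise ValueError(
                    f"{m.rsid}: marked validated in East Asians but no East-Asian "
                    "marker entry supplies its odds ratio"
                )
            out.append(
                replace(
                    m,
                    or_per_allele=ea.or_per_allele,
                    discovery_population=ea.discovery_population,
                )
            )
        elif m.east_asian_status == "tested_null":
            logger.info("%s: no East-Asian association; removed", m.rsid)
        else:
            out.append(m)  # untested: original OR carried over
    retained_rsids = {m.rsid for m in out}
    for ea in east_asian_markers:
        if ea.east_asian_status == "east_asian_discovered":
            if ea.rsid in retained_rsids:
                raise ValueError(f"{ea.rsid}: appended marker collides with retained rsid")
            out.append(ea)
            retained_rsids.add(ea.rsid)
    return replace(panel, markers=out)


def _prune_priority(m: SnpMarker) -> tuple[float, float, str]:
    # smaller p wins, then larger |log OR|, then lexicographic rsid
    return (m.p_discovery, -abs(math.log(m.or_per_allele)), m.rsid)


def ld_prune(
    panel: DiseasePanel, r2: np.ndarray, threshold: float = 0.8
) -> DiseasePanel:
    """Remove markers until no retained pair has r-squared at or above ``threshold``.

    Greedy, deterministic: markers are visited in order of evidence
    strength (smaller discovery P, then larger absolute log odds ratio,
    then rsid) and kept only if below-threshold with everything already
    kept. The survivor set therefore always favours the stronger member of
    a correlated pair. Original marker order is preserved in the output.
    """
    m = len(panel.markers)
    r2 = np.asarray(r2, dtype=float)
    if r2.shape != (m, m):
        raise ValueError(f"r2 matrix shape {r2.shape} does not match {m} markers")
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("r2 values must lie in [0, 1]")
    order = sorted(range(m), key=lambda i: _prune_priority(panel.markers[i]))
    kept: list[int] = []
    for i in order:
        if all(r2[i, j] < threshold for j in kept):
            kept.append(i)
    kept_set = set(kept)
    return replace(panel, markers=[mk for i, mk in enumerate(panel.markers) if i in kept_set])


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = [
    "disease", "rsid", "chrom", "pos", "risk_allele", "other_allele", "or",
    "p_discovery", "study_type", "p_replication", "population",
    "n_cases", "n_controls", "ea_status",
]


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "NA":
        return None
    return cast(value)


def load_panels_tsv(path) -> dict[str, DiseasePanel]:
    """Read disease panels from a marker-per-row TSV.

    Columns: ``disease rsid chrom pos risk_allele other_allele or
    p_discovery study_type p_replication population n_cases n_controls
    [raf_<pop> ...] ea_status``, with ``NA`` for absent optionals. When an
    rsid appears in several rows for one disease (the same variant reported
    by several studies), the row with the largest combined case+control
    sample size wins, and the collision is logged.
    """
    df = pd.read_csv(path, sep="\t", dtype={"disease": str, "rsid": str, "chrom": str})
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel TSV missing columns: {missing}")
    raf_cols = [c for c in df.columns if c.startswith("raf_")]
    panels: dict[str, DiseasePanel] = {}
    for disease, rows in df.groupby("disease", sort=False):
        best: dict[str, SnpMarker] = {}
        order: list[str] = []
        for _, row in rows.iterrows():
            raf = {}
            for c in raf_cols:
                f = _opt(row[c], float)
                if f is not None:
                    raf[c[len("raf_"):]] = f
            marker = SnpMarker(
                rsid=row["rsid"],
                chrom=str(row["chrom"]),
                pos=_opt(row["pos"], int),
                risk_allele=row["risk_allele"],
                other_allele=row["other_allele"],
                or_per_allele=float(row["or"]),
                p_discovery=float(row["p_discovery"]),
                study_type=row["study_type"],
                p_replication=_opt(row["p_replication"], float),
                discovery_population=row["population"],
                n_cases=int(row["n_cases"]),
                n_controls=int(row["n_controls"]),
                risk_allele_freq=raf,
                east_asian_status=row["ea_status"],
            )
            if marker.rsid not in best:
                best[marker.rsid] = marker
                order.append(marker.rsid)
            elif marker.sample_size > best[marker.rsid].sample_size:
                logger.info(
                    "%s/%s: duplicate report, keeping larger study (n=%d)",
                    disease, marker.rsid, marker.sample_size,
                )
                best[marker.rsid] = marker
            else:
                logger.info("%s/%s: duplicate report with smaller study dropped",
                            disease, marker.rsid)
        panels[disease] = DiseasePanel(disease_name=disease, markers=[best[r] for r in order])
    return panels


def write_panels_tsv(panels: dict[str, DiseasePanel], path) -> None:
    """Inverse of :func:`load_panels_tsv` (frequency columns pooled across panels)."""
    pops = sorted({p for panel in panels.values() for m in panel.markers
                   for p in m.risk_allele_freq})
    rows = []
    for panel in panels.values():
        for m in panel.markers:
            row = {
                "disease": panel.disease_name, "rsid": m.rsid, "chrom": m.chrom,
                "pos": m.pos if m.pos is not None else "NA",
                "risk_allele": m.risk_allele, "other_allele": m.other_allele,
                "or": m.or_per_allele, "p_discovery": m.p_discovery,
                "study_type": m.study_type,
                "p_replication": m.p_replication if m.p_replication is not None else "NA",
                "population": m.discovery_population,
                "n_cases": m.n_cases, "n_controls": m.n_controls,
            }
            for p in pops:
                row[f"raf_{p}"] = m.risk_allele_freq.get(p, "NA")
            row["ea_status"] = m.east_asian_status
            rows.append(row)
    cols = _PANEL_COLUMNS[:-1] + [f"raf_{p}" for p in pops] + ["ea_status"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)
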
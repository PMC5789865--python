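"""Readers and writers for genotype, manifest and report files.

Genotypes travel either as diploid VCF (GT fields) or as a risk-allele
dosage TSV (samples in rows, markers in columns, ``NA`` missing). The
VCF reader orients each record against the panel: the dosage counts
copies of the panel's risk allele whichever of REF/ALT it matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix
from .panel import DiseasePanel
from .simulate import RecruitmentManifest

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_manifest_tsv",
    "write_manifest_tsv",
    "ExclusionResult",
    "apply_exclusions",
]

AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


def read_genotypes(path, panel: DiseasePanel) -> GenotypeMatrix:
    """Load risk-allele dosages from a VCF or dosage TSV, oriented by ``panel``."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz", ".bcf"):
        return read_vcf(path, panel)
    return read_dosage_tsv(path)


def read_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    return GenotypeMatrix.from_dataframe(df)


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    df = genotypes.to_dataframe()
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_vcf(path, panel: DiseasePanel) -> GenotypeMatrix:
    """Read diploid GT calls and convert to risk-allele dosages.

    Orientation is resolved by matching the record's (REF, ALT) allele
    strings against the marker's (risk, other) pair in either order;
    ``./.`` becomes missing. Records whose allele pair does not match the
    panel are dropped with a warning, as are strand-ambiguous A/T and C/G
    pairs which are matched literally but logged. Panel markers absent
    from the file are logged and omitted from the matrix.
    """
    from cyvcf2 import VCF

    markers = {m.rsid: m for m in panel.markers}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        rsid = variant.ID
        if rsid not in markers:
            continue
        m = markers[rsid]
        alts = variant.ALT
        if len(alts) != 1:
            logger.warning("%s: multi-allelic record dropped", rsid)
            continue
        ref, alt = variant.REF, alts[0]
        if frozenset((ref, alt)) in AMBIGUOUS_PAIRS:
            logger.warning("%s: strand-ambiguous allele pair %s/%s matched literally",
                           rsid, ref, alt)
        if (ref, alt) == (m.other_allele, m.risk_allele):
            risk_is_alt = True
        elif (ref, alt) == (m.risk_allele, m.other_allele):
            risk_is_alt = False
        else:
            logger.warning("%s: alleles %s/%s do not match panel %s/%s; marker dropped",
                           rsid, ref, alt, m.risk_allele, m.other_allele)
            continue
        gts = np.asarray(variant.genotypes, dtype=object)
        dose = np.empty(len(samples))
        for i, gt in enumerate(gts):
            a, b = int(gt[0]), int(gt[1])
            if a < 0 or b < 0:
                dose[i] = np.nan
            else:
                alt_count = (a == 1) + (b == 1)
                dose[i] = alt_count if risk_is_alt else 2 - alt_count
        columns[rsid] = dose
    vcf.close()
    for rsid in markers:
        if rsid not in columns:
            logger.warning("%s: marker absent from %s", rsid, path)
    rsids = [r for r in markers if r in columns]
    dosages = (np.column_stack([columns[r] for r in rsids])
               if rsids else np.empty((len(samples), 0)))
    return GenotypeMatrix(dosages=dosages, sample_ids=samples, rsids=rsids)


def write_vcf(genotypes: GenotypeMatrix, panel: DiseasePanel, path) -> None:
    """Write dosages as a minimal VCF 4.2 on one pseudo-contig.

    REF is each marker's other allele and ALT its risk allele, so the ALT
    count equals the risk-allele dosage; missing calls become ``./.``.
    """
    markers = {m.rsid: m for m in panel.markers}
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chrSim>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(genotypes.sample_ids),
    ]
    gt_for = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    for j, rsid in enumerate(genotypes.rsids):
        m = markers[rsid]
        calls = [
            "./." if np.isnan(d) else gt_for[d] for d in genotypes.dosages[:, j]
        ]
        lines.append(
            f"chrSim\t{j + 1}\t{rsid}\t{m.other_allele}\t{m.risk_allele}"
            "\t.\tPASS\t.\tGT\t" + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_manifest_tsv(path) -> RecruitmentManifest:
    return RecruitmentManifest(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_manifest_tsv(manifest: RecruitmentManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


@dataclass
class ExclusionResult:
    """Outcome of the recruitment exclusion stage."""

    retained_ids: list[str]      # samples surviving all exclusion flags
    local_born_ids: list[str]    # the analysis population: retained and locally born
    accounting: pd.DataFrame     # stage -> count, reconciling the cohort


def apply_exclusions(manifest: RecruitmentManifest) -> ExclusionResult:
    """Apply recruitment exclusions and account for every sample.

    Non-Chinese, non-Han-Chinese and QC-failed samples are removed (each
    sample counted once, in that reporting order); the remainder is
    partitioned into locally born samples (the analysis population) and
    samples born elsewhere. The accounting table reconciles:
    recruited = retained + each exclusion count.
    """
    t = manifest.table
    non_chinese = t["ethnicity"] == "non_chinese"
    non_han = t["ethnicity"] == "non_han_chinese"
    qc_fail = ~t["qc_pass"] & ~non_chinese & ~non_han
    excluded = non_chinese | non_han | qc_fail
    retained = t.loc[~excluded]
    local = retained["birthplace"] == "local_born"
    accounting = pd.DataFrame(
        [
            ("recruited", len(t)),
            ("excluded_non_chinese", int(non_chinese.sum())),
            ("excluded_non_han_chinese", int(non_han.sum())),
            ("excluded_qc_fail", int(qc_fail.sum())),
            ("retained", len(retained)),
            ("local_born", int(local.sum())),
            ("non_local_born", int((~local).sum())),
        ],
        columns=["stage", "count"],
    )
    return ExclusionResult(
        retained_ids=retained["sample_id"].tolist(),
        local_born_ids=retained.loc[local, "sample_id"].tolist(),
        accounting=accounting,
    )
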
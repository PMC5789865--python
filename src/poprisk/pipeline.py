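"""End-to-end pipeline on a synthetic scenario, driven by a JSON config.

The pipeline chains every stage of the analysis: synthesise disease
panels and multi-population cohorts, apply recruitment exclusions and
genotype QC, score individuals, categorise the analysis population, and
compare risk distributions across populations. Each stage writes a TSV
beside a run manifest recording the seed and row counts; re-running the
same config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .categorize import (DiscoveryMeta, categorize_cohort, category_proportions,
                         log_or_se, panel_auc, reference_distribution)
from .compare import compare_all, comparison_report
from .io import apply_exclusions, write_dosage_tsv, write_manifest_tsv
from .matrix import GenotypeMatrix
from .panel import (DiseasePanel, InclusionThresholds, SnpMarker,
                    filter_by_discovery_criteria, ld_prune, write_panels_tsv)
from .qc import QcThresholds, apply_qc
from .risk import RiskProfile, cumulative_distribution, score_cohort
from .simulate import (PopulationSpec, make_recruitment_manifest,
                       simulate_allele_freqs, simulate_genotypes)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "DEMO_CONFIG"]

STAGES = ("simulate", "exclude", "qc", "panel", "score", "categorize", "compare")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and its index."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.stage_index = STAGES.index(stage)
        super().__init__(f"stage {stage!r} failed: {cause}")


def _take(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Resolved configuration for a full synthetic-scenario run."""

    seed: int = 0
    out_dir: str = "poprisk_out"
    populations: list[dict] = field(default_factory=lambda: [
        {"label": "LOCAL", "n_samples": 400, "fst": 0.002},
        {"label": "REGIONAL", "n_samples": 200, "fst": 0.005},
        {"label": "DISTANT", "n_samples": 200, "fst": 0.05},
    ])
    n_diseases: int = 3
    markers_per_disease: list[int] = field(default_factory=lambda: [1, 4, 6])
    n_background_markers: int = 4000
    or_range: list[float] = field(default_factory=lambda: [1.1, 1.8])
    freq_range: list[float] = field(default_factory=lambda: [0.15, 0.85])
    missing_rate: float = 0.01
    manifest: dict | None = None
    qc: dict = field(default_factory=dict)
    panel: dict = field(default_factory=dict)
    categorize: dict = field(default_factory=dict)
    compare: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _take(self.qc, {f for f in QcThresholds.__dataclass_fields__}, "qc")
        _take(self.panel, {f for f in InclusionThresholds.__dataclass_fields__}
              | {"ld_r2_threshold"}, "panel")
        _take(self.categorize,
              {"alpha", "high_quantile", "auc_min", "enum_max_markers", "mc_draws"},
              "categorize")
        _take(self.compare, {"alpha", "df_omnibus"}, "compare")
        if self.manifest is not None:
            _take(self.manifest,
                  {"n_total", "n_non_chinese", "n_non_han", "n_qc_fail",
                   "n_non_local_born"}, "manifest")
        if len(self.markers_per_disease) != self.n_diseases:
            raise ValueError("markers_per_disease must list one size per disease")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        _take(raw, set(cls.__dataclass_fields__), "top-level")
        return cls(**raw)


DEMO_CONFIG = PipelineConfig()


def _synthesize_panels(cfg: PipelineConfig, rng: np.random.Generator) -> dict[str, DiseasePanel]:
    """Random disease panels whose markers all clear the inclusion criteria."""
    alleles = ("A", "C")  # unambiguous pair, same orientation everywhere
    panels: dict[str, DiseasePanel] = {}
    counter = 0
    for d, m in enumerate(cfg.markers_per_disease):
        markers = []
        for _ in range(m):
            counter += 1
            markers.append(
                SnpMarker(
                    rsid=f"rs{counter:06d}",
                    chrom="1",
                    pos=counter * 1000,
                    risk_allele=alleles[1],
                    other_allele=alleles[0],
                    or_per_allele=float(rng.uniform(*cfg.or_range)),
                    p_discovery=float(10 ** rng.uniform(-12, -8)),
                    study_type="gwas_discovery",
                    n_cases=2000,
                    n_controls=2000,
                    risk_allele_freq={"discovery": float(rng.uniform(*cfg.freq_range))},
                )
            )
        panels[f"disease_{d + 1}"] = DiseasePanel(
            disease_name=f"disease_{d + 1}", markers=markers
        )
    return panels


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Stage order: simulate -> exclude -> qc -> panel -> score -> categorize
    -> compare. A failing stage raises :class:`StageError` naming it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(config), indent=2) + "\n")
    seeds = np.random.SeedSequence(config.seed).spawn(len(STAGES))
    counts: dict[str, int] = {}

    # --- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        rng = np.random.default_rng(seeds[0])
        panels = _synthesize_panels(config, rng)
        # background markers carry the sample-QC statistics (het F, relatedness),
        # standing in for the genome-wide content of a genotyping array
        bg_rsids = [f"bg{k + 1:06d}" for k in range(config.n_background_markers)]
        bg_freqs = rng.uniform(*config.freq_range, size=config.n_background_markers)
        all_rsids = [r for p in panels.values() for r in p.rsids] + bg_rsids
        ancestral = np.concatenate([
            [m.risk_allele_freq["discovery"] for p in panels.values() for m in p.markers],
            bg_freqs,
        ])
        pop_specs = [PopulationSpec(**p) for p in config.populations]
        freqs = simulate_allele_freqs(ancestral, pop_specs, seed=int(seeds[0].generate_state(1)[0] % 2**31))
        cohorts = []
        gt_seeds = seeds[0].spawn(len(pop_specs))
        for spec, gs in zip(pop_specs, gt_seeds):
            n = spec.n_samples
            if config.manifest is not None and spec is pop_specs[0]:
                n = config.manifest["n_total"]
            cohorts.append(
                simulate_genotypes(
                    freqs[spec.label], n, missing_rate=config.missing_rate,
                    seed=gs, population=spec.label, rsids=all_rsids,
                )
            )
        genotypes = GenotypeMatrix.concat_samples(cohorts)
        write_panels_tsv(panels, out / "panels_input.tsv")
        write_dosage_tsv(genotypes, out / "genotypes.tsv")
        counts["simulated_samples"] = genotypes.n_samples
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError(stage, e) from e

    # --- exclude -----------------------------------------------------------
    stage = "exclude"
    try:
        if config.manifest is not None:
            mf = make_recruitment_manifest(
                seed=int(seeds[1].generate_state(1)[0] % 2**31), **config.manifest
            )
            first = cohorts[0]
            mf.table["sample_id"] = first.sample_ids[: len(mf.table)]
            excl = apply_exclusions(mf)
            keep = set(excl.local_born_ids) | {
                s for c in cohorts[1:] for s in c.sample_ids
            }
            idx = [i for i, s in enumerate(genotypes.sample_ids) if s in keep]
            genotypes = genotypes.subset(sample_idx=idx)
            write_manifest_tsv(mf, out / "manifest.tsv")
            excl.accounting.to_csv(out / "accounting.tsv", sep="\t", index=False)
        counts["samples_after_exclusions"] = genotypes.n_samples
    except Exception as e:
        raise StageError(stage, e) from e

    # --- qc ----------------------------------------------------------------
    stage = "qc"
    try:
        thresholds = QcThresholds(**config.qc)
        qc_parts, failed_markers = [], set()
        for label, sub in genotypes.by_population().items():
            cleaned, report = apply_qc(sub, thresholds)
            qc_parts.append(cleaned)
            failed_markers |= set(genotypes.rsids) - set(cleaned.rsids)
        shared = [r for r in genotypes.rsids if r not in failed_markers]
        genotypes = GenotypeMatrix.concat_samples(
            [part.select_markers(shared) for part in qc_parts]
        )
        exclusions = pd.DataFrame(
            {"kind": "snp", "entity": sorted(failed_markers), "reason": "qc"}
        )
        exclusions.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        counts["samples_after_qc"] = genotypes.n_samples
        counts["markers_after_qc"] = genotypes.n_markers
    except Exception as e:
        raise StageError(stage, e) from e

    # --- panel -------------------------------------------------------------
    stage = "panel"
    try:
        panel_cfg = dict(config.panel)
        ld_threshold = panel_cfg.pop("ld_r2_threshold", 0.8)
        incl = InclusionThresholds(**panel_cfg)
        final_panels: dict[str, DiseasePanel] = {}
        for name, panel in panels.items():
            kept = filter_by_discovery_criteria(
                panel.markers, panel.endometrial_exception, incl
            )
            kept = [m for m in kept if m.rsid in set(genotypes.rsids)]
            pruned = DiseasePanel(disease_name=name, markers=kept,
                                  prevalence=panel.prevalence,
                                  heritability_band=panel.heritability_band)
            # markers are simulated independently: identity r2 matrix
            pruned = ld_prune(pruned, np.eye(len(kept)), threshold=ld_threshold)
            if len(pruned.markers) > 0:
                final_panels[name] = pruned
        write_panels_tsv(final_panels, out / "panels_final.tsv")
        counts["diseases_scored"] = len(final_panels)
    except Exception as e:
        raise StageError(stage, e) from e

    # --- score -------------------------------------------------------------
    stage = "score"
    try:
        all_scores = pd.concat(
            [score_cohort(p, genotypes) for p in final_panels.values()],
            ignore_index=True,
        )
        all_scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        cdf_rows = []
        for name in final_panels:
            sub = all_scores[all_scores["disease"] == name]
            for pop, grp in sub.groupby("population", sort=False):
                profiles = [
                    RiskProfile(r.sample_id, name, r.score, r.n_snps_used, pop)
                    for r in grp.itertuples(index=False)
                    if r.n_snps_used > 0
                ]
                cdf = cumulative_distribution(profiles).to_dataframe()
                cdf.insert(0, "disease", name)
                cdf_rows.append(cdf)
        pd.concat(cdf_rows, ignore_index=True).to_csv(
            out / "cumulative_distributions.tsv", sep="\t", index=False
        )
        counts["score_rows"] = len(all_scores)
    except Exception as e:
        raise StageError(stage, e) from e

    # --- categorize --------------------------------------------------------
    stage = "categorize"
    try:
        cat_cfg = config.categorize
        alpha = cat_cfg.get("alpha", 0.05)
        high_q = cat_cfg.get("high_quantile", 0.95)
        auc_min = cat_cfg.get("auc_min", 0.6)
        enum_max = cat_cfg.get("enum_max_markers", 8)
        mc_draws = cat_cfg.get("mc_draws", 100_000)
        analysis_pop = config.populations[0]["label"]
        cohort = genotypes.by_population()[analysis_pop]
        admission, cat_frames, prop_rows = [], [], []
        cat_seed = int(seeds[5].generate_state(1)[0] % 2**31)
        for name, panel in final_panels.items():
            p_disc = panel.frequencies("discovery")
            auc = panel_auc(panel, p_disc, n_sim=max(mc_draws // 10, 1000),
                            seed=cat_seed, max_enumeration=enum_max)
            admitted = auc > auc_min
            admission.append({"disease": name, "auc": auc, "admitted": admitted})
            if not admitted:
                continue
            ref = reference_distribution(panel, p_disc, max_enumeration=enum_max,
                                         mc_draws=mc_draws, seed=cat_seed)
            results = categorize_cohort(panel, cohort, ref,
                                        control_population="discovery",
                                        alpha=alpha, high_quantile=high_q)
            frame = pd.DataFrame(
                [
                    {"sample_id": r.sample_id, "disease": name, "score": r.score,
                     "ci_low": r.ci_low, "ci_high": r.ci_high, "category": r.category}
                    for r in results
                ]
            )
            cat_frames.append(frame)
            props = category_proportions(results)
            prop_rows.append({"disease": name, **props.to_dict()})
        pd.DataFrame(admission, columns=["disease", "auc", "admitted"]).to_csv(
            out / "admission.tsv", sep="\t", index=False
        )
        cat_cols = ["sample_id", "disease", "score", "ci_low", "ci_high", "category"]
        (pd.concat(cat_frames, ignore_index=True) if cat_frames
         else pd.DataFrame(columns=cat_cols)).to_csv(
            out / "categories.tsv", sep="\t", index=False
        )
        prop_cols = ["disease", "reduced", "average", "elevated", "high",
                     "high_or_elevated", "exceeds_10pct"]
        pd.DataFrame(prop_rows, columns=prop_cols).to_csv(
            out / "category_proportions.tsv", sep="\t", index=False
        )
        counts["diseases_admitted"] = int(sum(a["admitted"] for a in admission))
    except Exception as e:
        raise StageError(stage, e) from e

    # --- compare -----------------------------------------------------------
    stage = "compare"
    try:
        cmp_cfg = config.compare
        results = compare_all(final_panels, genotypes,
                              alpha=cmp_cfg.get("alpha", 0.05),
                              df_omnibus=cmp_cfg.get("df_omnibus", 3))
        report = comparison_report(results)
        report.to_csv(out / "comparison.tsv", sep="\t", index=False)
        counts["comparison_rows"] = len(report)
    except Exception as e:
        raise StageError(stage, e) from e

    run_manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "row_counts": counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2) + "\n")
    return out
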
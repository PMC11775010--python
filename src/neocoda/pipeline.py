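"""End-to-end orchestration of the analysis stages.

``run_pipeline`` wires the stages together — simulate (optional) → ingest
→ core/diversity → compositional regression → clustering → perfusion →
cohort tests — writing each stage's artifacts into a run directory with a
manifest (stage, parameters, sha256 checksum per artifact) so a rerun with
the same config and seed is verifiably identical.  Any stage failure
aborts with the stage name; partial outputs are kept next to a FAILED
marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import clustering, coda_model, cohort_stats, composition, diversity
from . import io_tables, perfusion, study_tables, synthetic_data

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the analysis defaults.

    ``k_barplot``/``k_model`` are the core sizes (ten genera for the
    descriptive bar data, nine for the regression model);
    ``heatmap_threshold`` keeps genera reaching at least that relative
    abundance in some sample; ``imputation_delta`` of None means the
    data-driven default (half the smallest nonzero relative abundance).
    """

    seed: int = 0
    simulate: bool = True
    abundance_path: Optional[str] = None
    metadata_path: Optional[str] = None
    perfusion_path: Optional[str] = None
    orientation: str = "taxa_rows"
    replicate_strategy: str = "mean_relative"
    k_barplot: int = 10
    k_model: int = 9
    imputation_delta: Optional[float] = None
    linkage: str = "complete"
    cluster_k: int = 3
    heatmap_threshold: float = 0.1
    spo2_grid: tuple = (85.0, 100.0, 0.5)        # start, stop, step
    cluster_overrides: dict = field(default_factory=dict)
    so2_field: str = "ru_so2"

    def __post_init__(self) -> None:
        if self.k_model < 2:
            raise ValueError("k_model must be >= 2")
        if not 0 <= self.heatmap_threshold < 1:
            raise ValueError("heatmap threshold must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spo2_grid" in raw:
            raw["spo2_grid"] = tuple(raw["spo2_grid"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, outdir: Path, config: PipelineConfig) -> None:
        self.outdir = outdir
        self.entries: list[dict] = []
        self.config = config

    def add(self, stage: str, path: Path, **params) -> None:
        self.entries.append({
            "stage": stage, "artifact": path.name,
            "parameters": {k: v for k, v in params.items()},
            "sha256": _sha256(path),
        })

    def write(self) -> Path:
        out = self.outdir / "manifest.json"
        payload = {"config": dataclasses.asdict(self.config),
                   "artifacts": self.entries}
        out.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config)
    try:
        _run_stages(config, outdir, manifest)
    except Exception as err:
        (outdir / "FAILED").write_text(f"{err}\n")
        raise
    manifest.write()
    return outdir


def _run_stages(config: PipelineConfig, outdir: Path, manifest: _Manifest) -> None:
    # --- simulate / ingest -------------------------------------------------
    if config.simulate:
        logger.info("stage simulate: seeded synthetic cohort (seed=%d)", config.seed)
        gen = synthetic_data.GeneratorConfig(
            seed=config.seed,
            spo2_effect=0.05 * np.ones(9),
            delivery_effect=np.linspace(0.5, -0.5, 9),
        )
        meta = synthetic_data.simulate_cohort(gen)
        table = synthetic_data.simulate_abundances(gen, meta)
        perf = synthetic_data.simulate_perfusion(gen, meta)
        io_tables.write_abundance_table(table, outdir / "abundance.tsv")
        io_tables.write_metadata(meta, outdir / "metadata.csv")
        io_tables.write_perfusion(perf, outdir / "perfusion.csv")
        (outdir / "provenance.json").write_text(json.dumps(
            {"seed": config.seed, "generator": dataclasses.asdict(gen)},
            default=lambda o: np.asarray(o).tolist(), indent=2) + "\n")
        manifest.add("simulate", outdir / "abundance.tsv", seed=config.seed)
    else:
        for name in ("abundance_path", "metadata_path", "perfusion_path"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"stage ingest: missing input {name}={p}")
        table = io_tables.read_abundance_table(config.abundance_path,
                                               config.orientation)
        meta = io_tables.read_metadata(config.metadata_path)
        perf = io_tables.read_perfusion(config.perfusion_path)

    meta_by_sample = {m.sample_id: m for m in meta}

    # --- core microbiota & diversity --------------------------------------
    logger.info("stage core: closing to relative abundances, selecting the "
                "%d largest genera by mean relative abundance", config.k_barplot)
    comp_all = composition.from_abundance(table)
    grouping = {m.sample_id: m.group for m in meta}
    core10 = composition.select_core(comp_all, min(config.k_barplot,
                                                   comp_all.n_parts))
    means = composition.group_mean_composition(core10, grouping)
    frame = pd.DataFrame(means.values, index=means.samples, columns=means.parts)
    frame.to_csv(outdir / "core_group_means.tsv", sep="\t", float_format="%.6g")
    manifest.add("core", outdir / "core_group_means.tsv", k=config.k_barplot)

    div = diversity.alpha_diversity_frame(comp_all)
    div.to_csv(outdir / "alpha_diversity.tsv", sep="\t", float_format="%.6g")
    summaries = {
        idx: diversity.group_median_iqr(div[idx], grouping)
        for idx in div.columns
    }
    pd.concat(summaries, names=["index"]).to_csv(
        outdir / "alpha_diversity_summary.tsv", sep="\t", float_format="%.6g")
    manifest.add("diversity", outdir / "alpha_diversity.tsv")

    # --- compositional regression (patients, first visit) ------------------
    logger.info("stage regress: first-visit patients, %d-genus core, ilr "
                "regression on SpO2 and delivery", config.k_model)
    chd_ids = [s for s in table.samples if meta_by_sample[s].group == "CHD"]
    chd_table = table.select_samples(chd_ids)
    first = io_tables.select_first_visit(chd_table,
                                        [meta_by_sample[s] for s in chd_ids])
    comp_chd = composition.from_abundance(first)
    core9 = composition.select_core(comp_chd, min(config.k_model,
                                                  comp_chd.n_parts))
    core9 = composition.impute_zeros(core9, config.imputation_delta)
    basis = composition.make_ilr_basis(core9.parts)
    coords = composition.ilr(core9, basis)
    spo2 = [meta_by_sample[s].spo2 for s in core9.samples]
    if any(v is None for v in spo2):
        missing = [s for s, v in zip(core9.samples, spo2) if v is None]
        raise ValueError(f"stage regress: samples without SpO2: {missing}")
    delivery = [meta_by_sample[s].delivery for s in core9.samples]
    spec = coda_model.build_model(coords, spo2, delivery, interaction=True)
    fit = coda_model.fit_multivariate_lm(spec)
    res = coda_model.manova(fit)
    pd.DataFrame([{"term": e.term, "wilks_lambda": e.statistic,
                   "approx_F": e.approx_f, "df_num": e.df_num,
                   "df_den": e.df_den, "p_value": e.p_value}
                  for e in res.values()]).to_csv(
        outdir / "manova.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.add("regress", outdir / "manova.tsv", k=config.k_model)

    start, stop, step = config.spo2_grid
    grid = np.arange(start, stop + step / 2, step)
    curves = [coda_model.predict_composition(fit, grid, lvl, basis)
              for lvl in ("vaginal", "cesarean")]
    pd.concat([c.to_long_frame() for c in curves]).to_csv(
        outdir / "prediction_curves.tsv", sep="\t", index=False,
        float_format="%.6g")
    manifest.add("predict", outdir / "prediction_curves.tsv", grid=config.spo2_grid)

    # --- clustering --------------------------------------------------------
    logger.info("stage cluster: %s-linkage clustering of patient samples in "
                "Aitchison geometry, cut at k=%d", config.linkage, config.cluster_k)
    comp_imp = composition.impute_zeros(comp_chd, config.imputation_delta)
    dend = clustering.hierarchical_cluster(comp_imp, config.linkage)
    assignment = clustering.cut_clusters(dend, min(config.cluster_k,
                                                   comp_imp.n_samples))
    if config.cluster_overrides:
        assignment = clustering.apply_overrides(assignment,
                                                config.cluster_overrides)
    assignment.to_frame().to_csv(outdir / "clusters.csv")
    dend.merge_table().to_csv(outdir / "dendrogram.tsv", sep="\t", index=False,
                              float_format="%.6g")
    heat = clustering.heatmap_matrix(comp_imp, config.heatmap_threshold, dend)
    heat.to_csv(outdir / "heatmap_matrix.tsv", sep="\t", float_format="%.6g")
    manifest.add("cluster", outdir / "clusters.csv", linkage=config.linkage,
                 k=config.cluster_k, overrides=config.cluster_overrides)

    # --- perfusion ---------------------------------------------------------
    logger.info("stage perfusion: FTOE and portal-vein global gut perfusion")
    derived = perfusion.derive_perfusion(perf, config.so2_field)
    pd.DataFrame([vars(d) for d in derived]).to_csv(
        outdir / "perfusion_derived.csv", index=False, float_format="%.6g")
    perfusion.perfusion_summary(perf, derived).to_csv(
        outdir / "perfusion_summary.csv", float_format="%.6g")
    spo2_clusters = pd.Series(
        {m.subject_id: m.spo2 for m in meta if m.group == "CHD"})
    subj_labels = {}
    for s, lab in assignment.labels.items():
        subj_labels[meta_by_sample[s].subject_id] = lab
    compare = clustering.cluster_compare(
        spo2_clusters, clustering.ClusterAssignment(subj_labels))
    compare.to_csv(outdir / "cluster_spo2_wilcoxon.tsv", sep="\t", index=False,
                   float_format="%.6g")
    manifest.add("perfusion", outdir / "perfusion_derived.csv",
                 so2_field=config.so2_field)

    # --- cohort tests (published summary inputs) ---------------------------
    logger.info("stage cohort-stats: baseline between-group test battery")
    rows = [
        ("female_gender", "fisher",
         cohort_stats.fisher_exact_2x2(study_tables.GENDER_TABLE)),
        ("mode_of_delivery", "fisher",
         cohort_stats.fisher_exact_2x2(study_tables.DELIVERY_TABLE)),
        ("gestational_age", "welch",
         cohort_stats.welch_from_summary(study_tables.GESTATIONAL_AGE["CHD"],
                                         study_tables.GESTATIONAL_AGE["HC"])[2]),
        ("birth_weight", "welch",
         cohort_stats.welch_from_summary(study_tables.BIRTH_WEIGHT["CHD"],
                                         study_tables.BIRTH_WEIGHT["HC"])[2]),
        ("age_at_first_sampling", "welch",
         cohort_stats.welch_from_summary(study_tables.AGE_AT_SAMPLING["CHD"],
                                         study_tables.AGE_AT_SAMPLING["HC"])[2]),
        ("type_of_feeding", "chisq",
         cohort_stats.chisq_test(study_tables.FEEDING_TABLE)[2]),
        ("maternal_nutrition", "chisq",
         cohort_stats.chisq_test(study_tables.MATERNAL_NUTRITION_TABLE)[2]),
        ("maternal_antibiotics", "prop",
         cohort_stats.prop_test(*study_tables.ANTIBIOTICS["CHD"],
                                *study_tables.ANTIBIOTICS["HC"])),
        ("gbs_colonization", "prop",
         cohort_stats.prop_test(*study_tables.GBS["CHD"],
                                *study_tables.GBS["HC"])),
    ]
    pd.DataFrame(rows, columns=["characteristic", "test", "p_value"]).assign(
        p_rounded=lambda d: d["p_value"].round(2)).to_csv(
        outdir / "cohort_tests.tsv", sep="\t", index=False, float_format="%.6g")
    manifest.add("cohort-stats", outdir / "cohort_tests.tsv")
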
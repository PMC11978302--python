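"""Pipeline orchestration: configuration, seeding, stage wiring, run report.

``run_all`` drives a complete analysis on a simulated study: simulate ->
quantify -> preprocess -> differential expression / clustering / solubility /
signatures / fibrosis correlation -> AFM mechanics.  A single global seed is
fanned out to per-stage child seeds by stable hashing of stage names, so
inserting a stage does not perturb another stage's randomness, and two runs
from one config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import afm as afm_mod
from . import cluster as cluster_mod
from . import correlation as corr_mod
from . import io as io_mod
from . import quantify as quant_mod
from . import signatures as sig_mod
from . import solubility as sol_mod
from .diffexpr import DeRule, anova_time_course, de_contrast, detect_induced
from .matrix import IntensityMatrix
from .preprocess import FilterRule, filter_by_valid_values, impute_downshift, \
    normalize_columns, zscore_rows
from .simulate import SimulationConfig, simulate_study

#: the analysis parameters the study protocol fixes; deviations are warned about
REFERENCE_DEFAULTS = {
    ("filter", "min_valid"): 5,
    ("impute", "shift"): 1.8,
    ("impute", "width"): 0.3,
    ("de", "fold_change_min"): 1.5,
    ("de", "q"): 0.05,
    ("solubility", "fold_min"): 3.0,
    ("solubility", "q"): 0.05,
    ("cluster", "enrichment_q"): 0.04,
    ("correlation", "q"): 0.05,
}


@dataclass
class RunConfig:
    seed: int = 0
    simulate: dict = field(default_factory=dict)     # SimulationConfig overrides
    filter: dict = field(default_factory=lambda: {"min_valid": 5,
                                                  "scope": "any_group_per_model"})
    normalize: str = "median_center"
    impute: dict = field(default_factory=lambda: {"shift": 1.8, "width": 0.3,
                                                  "per": "column"})
    de: dict = field(default_factory=lambda: {"fold_change_min": 1.5, "q": 0.05,
                                              "timepoint": "T2", "reference": "Ctrl"})
    cluster: dict = field(default_factory=lambda: {"k": 6, "enrichment_q": 0.04})
    solubility: dict = field(default_factory=lambda: {"fold_min": 3.0, "q": 0.05,
                                                      "scope": "global"})
    correlation: dict = field(default_factory=lambda: {"q": 0.05,
                                                       "include_controls": False})
    afm: dict = field(default_factory=lambda: {"delta_max_frac": 0.3})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage child seed (crc32 of 'seed:stage', below 2**31)."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2 ** 31)


def validate_config(config: RunConfig) -> dict:
    """Range checks (errors) and deviations from protocol defaults (warnings)."""
    errors, warnings_ = [], []
    for name, d in (("de", config.de), ("solubility", config.solubility),
                    ("correlation", config.correlation)):
        q = d.get("q")
        if q is not None and not 0 < q < 1:
            errors.append(f"{name}.q={q} outside (0, 1)")
    if config.de.get("fold_change_min", 1.5) < 1:
        errors.append("de.fold_change_min must be >= 1")
    if config.filter.get("min_valid", 5) < 1:
        errors.append("filter.min_valid must be >= 1")
    for (section, key), ref in REFERENCE_DEFAULTS.items():
        val = getattr(config, section).get(key) if isinstance(
            getattr(config, section), dict) else None
        if val is not None and val != ref:
            warnings_.append(f"{section}.{key}={val} deviates from protocol default {ref}")
    return {"errors": errors, "warnings": warnings_, "ok": not errors}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig, outdir) -> dict:
    """Execute all stages in dependency order; returns the run report."""
    diag = validate_config(config)
    if not diag["ok"]:
        raise ValueError("invalid configuration: " + "; ".join(diag["errors"]))
    t0 = time.time()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = {"seed": config.seed, "config": asdict(config),
              "warnings": list(diag["warnings"]), "stages": {}}

    # --- simulate -----------------------------------------------------------
    sim_cfg = SimulationConfig(**{**config.simulate,
                                  "seed": stage_seed(config.seed, "simulate")})
    study = simulate_study(sim_cfg)
    io_mod.write_study(study, outdir / "study")
    report["stages"]["simulate"] = {
        "n_proteins": sim_cfg.n_proteins,
        "n_samples": int(len(study.design)),
        "seed": sim_cfg.seed}

    models = list(sim_cfg.models)
    design = study.design

    # --- quantify (per-mouse S/E pairs) -------------------------------------
    if study.peptides is not None:
        coeff_rows = []
        for mouse, grp in design[design["fraction"].isin(["S", "E"])].groupby(
                "mouse", sort=False):
            pair = grp["sample_id"].tolist()
            try:
                coeffs = quant_mod.estimate_proportional_coefficients(
                    study.peptides, pair)
            except quant_mod.DisconnectedDesignError:
                continue
            for s, c in coeffs.coefficients.items():
                coeff_rows.append({"mouse": mouse, "sample_id": s, "coefficient": c})
        coeff_df = pd.DataFrame(coeff_rows)
        io_mod.write_table(coeff_df, outdir / "proportional_coefficients.tsv")
        report["stages"]["quantify"] = {"n_pairs": int(coeff_df["mouse"].nunique())}

    # --- per-model analyses --------------------------------------------------
    meta = design.set_index("sample_id")
    for model in models:
        mdir = outdir / model
        mdir.mkdir(exist_ok=True)
        mats = {}
        for frac in ("Total", "S", "E"):
            mat = study.protein[frac]
            cols = [c for c in mat.samples if meta.loc[c, "model"] == model]
            mat = mat.subset(samples=cols)
            mat = filter_by_valid_values(mat, design, FilterRule(**config.filter))
            mat = normalize_columns(mat, config.normalize)
            mat = impute_downshift(mat, seed=stage_seed(
                config.seed, f"impute:{model}:{frac}"), **config.impute)
            mats[frac] = mat
            io_mod.write_matrix(mat, mdir / f"imputed_{frac}.tsv")

        de = de_contrast(mats["Total"], design, model, DeRule(**config.de))
        io_mod.write_table(de.rename_axis("protein_id").reset_index(),
                           mdir / "de_total.tsv")
        anova = anova_time_course(mats["Total"], design, model, q=config.de["q"])
        io_mod.write_table(anova.rename_axis("protein_id").reset_index(),
                           mdir / "anova_total.tsv")
        induced = sorted(detect_induced(study.protein["Total"].mask, design, model))
        (mdir / "induced_total.json").write_text(json.dumps(induced, indent=1))

        zmat, dropped = zscore_rows(mats["Total"])
        profiles = cluster_mod.mean_group_profiles(zmat, design, model=model)
        dendro = cluster_mod.hierarchical_cluster(profiles.dropna(axis=1, how="all"))
        labels = cluster_mod.cut_clusters(dendro, min(config.cluster["k"],
                                                      len(dendro.ids)))
        enrich = cluster_mod.cluster_annotation_enrichment(
            labels, study.annotations, q=config.cluster["enrichment_q"])
        io_mod.write_table(labels.rename_axis("protein_id").reset_index(),
                           mdir / "clusters_total.tsv")
        io_mod.write_table(enrich, mdir / "cluster_enrichment.tsv")

        pca = cluster_mod.pca_scores(mats["Total"])
        io_mod.write_table(pca.scores.rename_axis("sample_id").reset_index(),
                           mdir / "pca_scores_total.tsv")

        # ratios are defined only for proteins quantified in both fractions
        common = mats["E"].proteins.intersection(mats["S"].proteins)
        e_common = mats["E"].subset(proteins=common)
        ratios = sol_mod.es_ratio(e_common, mats["S"], design, model,
                                  scope=config.solubility["scope"])
        sel = sol_mod.select_insolubilized(
            ratios, e_common, design, model,
            fold_min=config.solubility["fold_min"], q=config.solubility["q"])
        io_mod.write_table(sel.table.rename_axis("protein_id").reset_index(),
                           mdir / "solubility_selection.tsv")

        scores = sig_mod.signature_scores(zmat, design, study.signatures)
        tests = sig_mod.signature_tests(scores)
        io_mod.write_table(scores, mdir / "signature_scores.tsv")
        io_mod.write_table(tests, mdir / "signature_tests.tsv")

        area_d = corr_mod.fibrosis_deltas(study.fibrosis, model)
        records = {}
        for frac in ("Total", "E"):
            deltas = corr_mod.baseline_deltas(mats[frac], design, model, frac)
            rec = corr_mod.correlate_proteome_fibrosis(
                deltas, area_d, design, q=config.correlation["q"],
                include_controls=config.correlation["include_controls"])
            records[frac] = rec
            io_mod.write_table(rec.rename_axis("protein_id").reset_index(),
                               mdir / f"fibrosis_correlation_{frac}.tsv")
        classes = corr_mod.classify_correlates(records["Total"], records["E"])
        (mdir / "correlate_classes.json").write_text(json.dumps(
            {k: sorted(v) for k, v in classes.items()}, indent=1))

        report["stages"][f"analysis:{model}"] = {
            "n_filtered": int(mats["Total"].values.shape[0]),
            "n_de": int(de["significant"].sum()),
            "n_induced": len(induced),
            "n_insolubilized": len(sel.selected),
            "n_zscore_dropped": len(dropped),
        }

    # --- AFM -----------------------------------------------------------------
    if study.force_curves is not None:
        stiff = afm_mod.fit_curve_set(study.force_curves,
                                      config.afm["delta_max_frac"])
        io_mod.write_table(stiff.drop(columns=["radius_m", "poisson",
                                               "spring_n_per_m"]),
                           outdir / "stiffness_map.tsv")
        region_stats, map_medians = afm_mod.build_region_stats(stiff)
        io_mod.write_table(region_stats.drop(columns=["hist_counts", "hist_edges"]),
                           outdir / "region_stats.tsv")
        io_mod.write_table(map_medians, outdir / "map_medians.tsv")
        comparisons = afm_mod.compare_regions(stiff)
        comp_rows = []
        for region, res in comparisons.items():
            for tp, dunn in res["dunn"].items():
                comp_rows.append({"region": region, "treatment": tp,
                                  "kruskal_p": res["kruskal"].p_value,
                                  "dunn_z": dunn.statistic,
                                  "dunn_p_adjusted": dunn.p_value})
        io_mod.write_table(pd.DataFrame(comp_rows), outdir / "region_comparisons.tsv")
        report["stages"]["afm"] = {
            "n_curves": int(len(stiff)), "n_failed": int((~stiff["ok"]).sum())}

    # --- report --------------------------------------------------------------
    files = sorted(p for p in outdir.rglob("*") if p.is_file()
                   and p.name != "run_report.json")
    report["outputs"] = {str(p.relative_to(outdir)): _sha256(p) for p in files}
    report["wall_time_s"] = round(time.time() - t0, 3)
    (outdir / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
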
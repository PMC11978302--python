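"""Recovery benchmarks on synthetic studies with planted ground truth.

Every function here simulates a study (or force-curve set) under the
generator's study conditions, runs the corresponding pipeline stage, and
scores the result against the planted truth: sensitivity and observed FDR
for the differential calls, false-positive rates under global-null studies,
moment checks for the imputation, modulus-recovery errors for the Hertz fit,
and region-statistics power for the AFM comparisons.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import afm as afm_mod
from .correlation import (baseline_deltas, classify_correlates,
                          correlate_proteome_fibrosis, fibrosis_deltas)
from .diffexpr import DeRule, de_contrast
from .matrix import IntensityMatrix
from .preprocess import (FilterRule, filter_by_valid_values, impute_downshift,
                         normalize_columns)
from .quantify import (assemble_protein_intensity,
                       estimate_proportional_coefficients)
from .simulate import (DEFAULT_REGION_MODULI_PA, SimulationConfig,
                       simulate_force_curves, simulate_study)
from .solubility import es_ratio, select_insolubilized


def _prep(study, model: str, fraction: str, seed: int) -> IntensityMatrix:
    """Standard preprocessing: per-model subset, filter, normalize, impute."""
    mat = study.protein[fraction]
    meta = study.design.set_index("sample_id")
    cols = [c for c in mat.samples if meta.loc[c, "model"] == model]
    mat = mat.subset(samples=cols)
    mat = filter_by_valid_values(mat, study.design, FilterRule())
    mat = normalize_columns(mat)
    return impute_downshift(mat, seed=seed)


def de_recovery(n_seeds: int = 10, n_proteins: int = 500, seed0: int = 0) -> dict:
    """Sensitivity/FDR of the T2-vs-control rule on planted effects."""
    tp = fp = n_planted = n_sel = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(n_proteins=n_proteins, with_peptides=False,
                               with_afm=False, seed=seed0 + i)
        st = simulate_study(cfg)
        for model in cfg.models:
            mat = _prep(st, model, "Total", seed0 + 1000 + i)
            de = de_contrast(mat, st.design, model, DeRule())
            cls = st.ground_truth.classes.reindex(de.index)
            planted = cls.isin(["tracking_pos", "declining"])
            sig = de["significant"]
            tp += int((sig & planted).sum())
            fp += int((sig & ~planted).sum())
            n_planted += int(planted.sum())
            n_sel += int(sig.sum())
    return {"sensitivity": tp / n_planted, "fdr": fp / max(n_sel, 1),
            "n_planted": n_planted, "n_selected": n_sel, "n_seeds": n_seeds}


def de_null_rate(n_seeds: int = 100, n_proteins: int = 200, seed0: int = 0) -> dict:
    """Fraction of all-null studies yielding any differential call."""
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_proteins=n_proteins, with_peptides=False, with_afm=False,
            frac_fibrosis_tracking=0.0, frac_declining=0.0,
            frac_solubility_shift=0.0, models=("CCl4like",),
            healing_factor={"CCl4like": 0.9}, seed=seed0 + i)
        st = simulate_study(cfg)
        mat = _prep(st, "CCl4like", "Total", seed0 + 2000 + i)
        de = de_contrast(mat, st.design, "CCl4like", DeRule())
        hits += int(de["significant"].any())
    return {"any_rejection_rate": hits / n_seeds, "n_seeds": n_seeds}


def solubility_recovery(n_seeds: int = 10, n_proteins: int = 400,
                        seed0: int = 0) -> dict:
    """Sensitivity/FDR of the E/S two-gate rule on planted shifts."""
    tp = fp = n_planted = n_sel = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(n_proteins=n_proteins, with_peptides=False,
                               with_afm=False, models=("CCl4like",),
                               healing_factor={"CCl4like": 0.9}, seed=seed0 + i)
        st = simulate_study(cfg)
        e = _prep(st, "CCl4like", "E", seed0 + 3000 + i)
        s = _prep(st, "CCl4like", "S", seed0 + 4000 + i)
        common = e.proteins.intersection(s.proteins)
        e = e.subset(proteins=common)
        ratios = es_ratio(e, s, st.design, "CCl4like")
        sel = select_insolubilized(ratios, e, st.design, "CCl4like")
        cls = st.ground_truth.classes
        shift = set(cls.index[cls == "solubility_shift"]) & set(common)
        tp += len(sel.selected & shift)
        fp += len(sel.selected - shift)
        n_planted += len(shift)
        n_sel += len(sel.selected)
    return {"sensitivity": tp / n_planted, "fdr": fp / max(n_sel, 1),
            "n_planted": n_planted, "n_selected": n_sel, "n_seeds": n_seeds}


def correlation_recovery(n_seeds: int = 10, n_proteins: int = 300,
                         seed0: int = 0) -> dict:
    """Fraction of planted tracking proteins landing in positive_both."""
    hit = tot = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(n_proteins=n_proteins, with_peptides=False,
                               with_afm=False, models=("CCl4like",),
                               healing_factor={"CCl4like": 0.9}, seed=seed0 + i)
        st = simulate_study(cfg)
        area_d = fibrosis_deltas(st.fibrosis, "CCl4like")
        records = {}
        for frac, off in (("Total", 5000), ("E", 6000)):
            mat = _prep(st, "CCl4like", frac, seed0 + off + i)
            deltas = baseline_deltas(mat, st.design, "CCl4like", frac)
            records[frac] = correlate_proteome_fibrosis(deltas, area_d, st.design)
        classes = classify_correlates(records["Total"], records["E"])
        cls = st.ground_truth.classes
        trk = set(cls.index[cls == "tracking_pos"]) & \
            set(records["Total"].index) & set(records["E"].index)
        hit += len(classes["positive_both"] & trk)
        tot += len(trk)
    return {"positive_both_rate": hit / tot, "n_planted": tot, "n_seeds": n_seeds}


def correlation_null_rate(n_seeds: int = 100, n_proteins: int = 150,
                          seed0: int = 0) -> dict:
    """Fraction of all-null studies with any significant fibrosis correlate."""
    hits = 0
    for i in range(n_seeds):
        cfg = SimulationConfig(
            n_proteins=n_proteins, with_peptides=False, with_afm=False,
            frac_fibrosis_tracking=0.0, frac_declining=0.0,
            frac_solubility_shift=0.0, models=("CCl4like",),
            healing_factor={"CCl4like": 0.9}, seed=seed0 + i)
        st = simulate_study(cfg)
        area_d = fibrosis_deltas(st.fibrosis, "CCl4like")
        mat = _prep(st, "CCl4like", "Total", seed0 + 7000 + i)
        deltas = baseline_deltas(mat, st.design, "CCl4like", "Total")
        rec = correlate_proteome_fibrosis(deltas, area_d, st.design)
        hits += int(rec["significant"].any())
    return {"any_rejection_rate": hits / n_seeds, "n_seeds": n_seeds}


def imputation_moments(n_cells: int = 50000, m: float = 20.0, s: float = 2.0,
                       seed: int = 0) -> dict:
    """Moments of imputed draws for a half-missing column."""
    rng = np.random.default_rng(seed)
    observed = rng.normal(m, s, size=n_cells)
    col = np.concatenate([observed, np.full(n_cells, np.nan)])
    df = pd.DataFrame({"s0": col}, index=[f"P{i}" for i in range(2 * n_cells)])
    mat = IntensityMatrix.from_values(df)
    out = impute_downshift(mat, shift=1.8, width=0.3, seed=seed + 1)
    filled = out.values.to_numpy()[n_cells:, 0]
    m_obs, s_obs = observed.mean(), observed.std(ddof=1)
    return {"imputed_mean": float(filled.mean()),
            "imputed_sd": float(filled.std()),
            "target_mean": float(m_obs - 1.8 * s_obs),
            "target_sd": float(0.3 * s_obs), "n_missing": n_cells}


def lfq_coefficient_errors(peptide_cv: float, n_peptides: int = 50,
                           seed: int = 0, n_rep: int = 10) -> float:
    """Mean (over replicates) max relative error of recovered coefficient
    ratios against the true per-sample factors {1, 2, 4}."""
    rng = np.random.default_rng(seed)
    maxima = []
    for _ in range(n_rep):
        base = rng.lognormal(10, 1, size=n_peptides)
        factors = np.array([1.0, 2.0, 4.0])
        mat = base[:, None] * factors[None, :]
        if peptide_cv > 0:
            mat = mat * rng.lognormal(0, peptide_cv, size=mat.shape)
        pep = pd.DataFrame(mat, columns=["s1", "s2", "s3"])
        pep.insert(0, "evidence_class", "unique")
        pep.insert(0, "protein_id", "P1")
        pep.insert(0, "peptide_id", [f"p{i}" for i in range(n_peptides)])
        co = estimate_proportional_coefficients(pep, ["s1", "s2", "s3"]).coefficients
        maxima.append(max(abs(co["s1"] / co["s2"] - 2.0) / 2.0,
                          abs(co["s1"] / co["s3"] - 4.0) / 4.0,
                          abs(co["s2"] / co["s3"] - 2.0) / 2.0))
    return float(np.mean(maxima))


def hertz_noiseless_errors(moduli=(500.0, 1200.0, 4400.0), seed: int = 0) -> dict:
    """Relative recovery error and contact offset on noiseless curves."""
    errs, offsets = [], []
    for k, e_true in enumerate(moduli):
        cs = simulate_force_curves({"r": e_true}, grid=(1, 1), noise_cv=0.0,
                                   seed=seed + k)
        curve = next(iter(cs.curves.values()))
        res = afm_mod.process_curve(curve)
        errs.append(abs(res["modulus_pa"] - e_true) / e_true)
        offsets.append(abs(res["contact_index"] - 30))   # generator contact index
    return {"max_rel_error": float(max(errs)),
            "max_contact_offset": int(max(offsets))}


def hertz_noisy_median(e_true: float = 4400.0, n_curves: int = 200,
                       noise_cv: float = 0.05, seed: int = 0) -> dict:
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_curves):
        cs = simulate_force_curves({"r": e_true}, grid=(1, 1),
                                   noise_cv=noise_cv,
                                   seed=int(rng.integers(2 ** 31)))
        res = afm_mod.process_curve(next(iter(cs.curves.values())))
        if res["ok"]:
            fits.append(res["modulus_pa"])
    return {"median_pa": float(np.median(fits)), "true_pa": e_true,
            "n_curves": len(fits)}


def region_stats_benchmark(n_seeds: int = 10, grid=(10, 36),
                           n_maps: int = 7, noise_cv: float = 0.05,
                           seed0: int = 0) -> dict:
    """Power of the region comparisons on maps from the measured medians."""
    dunn_ok = order_ok = soften_ok = 0
    max_errs, t2_medians, t1_interface = [], [], []
    for i in range(n_seeds):
        rng = np.random.default_rng(seed0 + i)
        frames = []
        for tp, truth in DEFAULT_REGION_MODULI_PA.items():
            for m in range(n_maps):
                cs = simulate_force_curves(
                    truth, grid=grid, noise_cv=noise_cv,
                    seed=int(rng.integers(2 ** 31)), map_id=f"{tp}_{m}",
                    treatment=tp, mouse=f"{tp}_m{m % 3}")
                frames.append(afm_mod.fit_curve_set(cs))
        stiff = pd.concat(frames, ignore_index=True)
        stats_df, _ = afm_mod.build_region_stats(stiff)
        med = stats_df.set_index(["region", "treatment"])["median_pa"]
        errs = [abs(med[(r, tp)] - DEFAULT_REGION_MODULI_PA[tp][r])
                / DEFAULT_REGION_MODULI_PA[tp][r]
                for tp in DEFAULT_REGION_MODULI_PA
                for r in DEFAULT_REGION_MODULI_PA[tp]]
        max_errs.append(max(errs))
        comp = afm_mod.compare_regions(stiff)
        dunn_ok += all(comp[r]["dunn"]["T2"].p_value < 0.05 for r in comp)
        t2 = {r: med[(r, "T2")] for r in DEFAULT_REGION_MODULI_PA["T2"]}
        order_ok += (t2["collagen"] >= t2["injured_hepatocyte"]
                     >= t2["interface_hepatocyte"])
        soften_ok += (med[("interface_hepatocyte", "T1")]
                      < med[("interface_hepatocyte", "Ctrl")])
        t2_medians.append(t2)
        t1_interface.append(med[("interface_hepatocyte", "T1")])
    return {
        "max_median_rel_error": float(max(max_errs)),
        "dunn_t2_rate": dunn_ok / n_seeds,
        "t2_ordering_rate": order_ok / n_seeds,
        "t1_interface_softening_rate": soften_ok / n_seeds,
        "median_t2_collagen_pa": float(np.mean([t["collagen"] for t in t2_medians])),
        "median_t2_injured_pa": float(np.mean([t["injured_hepatocyte"] for t in t2_medians])),
        "median_t2_interface_pa": float(np.mean([t["interface_hepatocyte"] for t in t2_medians])),
        "median_t1_interface_pa": float(np.mean(t1_interface)),
        "n_seeds": n_seeds,
    }


def quantification_recovery(seed: int = 0) -> dict:
    """Spearman correlation of assembled vs true protein abundance per sample."""
    from scipy.stats import spearmanr
    cfg = SimulationConfig(n_proteins=150, with_afm=False, seed=seed,
                           models=("CCl4like",),
                           healing_factor={"CCl4like": 0.9},
                           peptide_noise_cv=0.05, peptide_mnar_offset=5.0)
    st = simulate_study(cfg)
    samples = st.design.loc[st.design["fraction"] == "Total", "sample_id"][:6]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        co = estimate_proportional_coefficients(st.peptides, list(samples))
    out = assemble_protein_intensity(st.peptides, co)
    truth = st.ground_truth.true_log2["Total"]
    rhos = []
    for s in samples:
        common = out.index[out[s].notna()]
        rhos.append(spearmanr(np.log2(out.loc[common, s]),
                              truth.loc[common, s]).statistic)
    return {"min_spearman": float(min(rhos)), "n_samples": len(rhos)}
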
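"""Synthetic-study generator: determinism, planted effects, missingness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fibrodyn import SimulationConfig, simulate_study
from fibrodyn.simulate import (ConfigurationError, apply_missingness,
                               effect_profile, hertz_force,
                               simulate_force_curves)
from fibrodyn.matrix import IntensityMatrix


def tiny_cfg(**kw):
    base = dict(n_proteins=60, with_peptides=False, with_afm=False, seed=0)
    base.update(kw)
    return SimulationConfig(**base)


def test_determinism_same_seed_identical():
    a = simulate_study(tiny_cfg(seed=5, with_peptides=True))
    b = simulate_study(tiny_cfg(seed=5, with_peptides=True))
    for frac in a.protein:
        pd.testing.assert_frame_equal(a.protein[frac].values, b.protein[frac].values)
    pd.testing.assert_frame_equal(a.peptides, b.peptides)
    pd.testing.assert_frame_equal(a.fibrosis, b.fibrosis)


def test_different_seed_differs():
    a = simulate_study(tiny_cfg(seed=1))
    b = simulate_study(tiny_cfg(seed=2))
    assert not a.protein["Total"].values.equals(b.protein["Total"].values)


def test_null_configuration_all_null():
    cfg = tiny_cfg(frac_fibrosis_tracking=0, frac_declining=0,
                   frac_solubility_shift=0)
    st = simulate_study(cfg)
    assert (st.ground_truth.classes == "null").all()
    for key, df in st.ground_truth.effects.items():
        assert (df.to_numpy() == 0).all()


def test_invalid_proportions_rejected():
    with pytest.raises(ConfigurationError):
        simulate_study(tiny_cfg(frac_fibrosis_tracking=0.7, frac_declining=0.4))
    with pytest.raises(ConfigurationError):
        simulate_study(tiny_cfg(healing_factor={"CCl4like": 1.5, "DDClike": 0.1}))


def test_effect_profile_shape():
    w = effect_profile(healing=1.0)
    assert list(w) == [0.0, 0.5, 1.0, 0.5, 0.0]
    w = effect_profile(healing=0.0)
    assert list(w) == [0.0, 0.5, 1.0, 1.0, 1.0]


def test_planted_effect_consistency():
    """Group mean difference at T2 approximates effect_log2."""
    cfg = tiny_cfg(n_proteins=200, noise_sd_log2=0.3, seed=11)
    st = simulate_study(cfg)
    cls = st.ground_truth.classes
    meta = st.design.set_index("sample_id")
    vals = st.ground_truth.true_log2["Total"]
    cols_t2 = [c for c in vals.columns
               if meta.loc[c, "timepoint"] == "T2" and meta.loc[c, "model"] == "CCl4like"]
    cols_c = [c for c in vals.columns
              if meta.loc[c, "timepoint"] == "Ctrl" and meta.loc[c, "model"] == "CCl4like"]
    diff = vals[cols_t2].mean(axis=1) - vals[cols_c].mean(axis=1)
    tol = 4 * cfg.noise_sd_log2 / np.sqrt(len(cols_t2))
    trk = cls.index[cls == "tracking_pos"]
    assert np.all(np.abs(diff[trk] - cfg.effect_log2) < tol)
    dec = cls.index[cls == "declining"]
    assert np.all(np.abs(diff[dec] + cfg.effect_log2) < tol)


def test_solubility_shift_only_in_e():
    st = simulate_study(tiny_cfg(n_proteins=100, seed=3))
    eff = st.ground_truth.effects
    shift = st.ground_truth.classes == "solubility_shift"
    assert (eff[("CCl4like", "Total")].loc[shift].to_numpy() == 0).all()
    assert (eff[("CCl4like", "S")].loc[shift].to_numpy() == 0).all()
    assert eff[("CCl4like", "E")].loc[shift, "T2"].eq(2.0).all()


def test_tracking_t_test_power_across_seeds():
    """Monte-Carlo: planted T2-vs-Ctrl effect is detectable nearly always."""
    hits = total = 0
    for seed in range(100):
        cfg = tiny_cfg(n_proteins=20, frac_fibrosis_tracking=0.2,
                       effect_log2=2.0, noise_sd_log2=0.1, seed=seed,
                       models=("CCl4like",),
                       healing_factor={"CCl4like": 0.9})
        st = simulate_study(cfg)
        cls = st.ground_truth.classes
        trk = cls.index[cls == "tracking_pos"][0]
        meta = st.design.set_index("sample_id")
        v = st.ground_truth.true_log2["Total"].loc[trk]
        a = v[[c for c in v.index if meta.loc[c, "timepoint"] == "T2"]]
        b = v[[c for c in v.index if meta.loc[c, "timepoint"] == "Ctrl"]]
        _, p = sps.ttest_ind(a, b, equal_var=True)
        total += 1
        hits += p < 1e-3
    assert hits / total >= 0.95


# ---------------------------------------------------------------- missingness


def _matrix(values):
    df = pd.DataFrame(values)
    df.index = [f"P{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return IntensityMatrix.from_values(df)


def test_missingness_limiting_cases(rng):
    m = _matrix(rng.normal(20, 2, size=(50, 4)))
    hard = apply_missingness(m, midpoint=20.0, slope=1e6, seed=0)
    vals = hard.values.to_numpy()
    orig = m.values.to_numpy()
    assert np.isnan(vals[orig < 20]).all()
    assert np.isfinite(vals[orig > 20]).all()
    none = apply_missingness(m, midpoint=-np.inf, slope=1.0, seed=0)
    assert none.mask.all().all()


def test_missingness_rate_matches_logistic_expectation(rng):
    x = rng.normal(20, 2, size=(100000, 1))
    m = _matrix(x)
    mid = float(np.median(x))
    out = apply_missingness(m, midpoint=mid, slope=1.0, seed=7)
    expected = (1 / (1 + np.exp(1.0 * (x - mid)))).mean()
    observed = 1 - out.mask.to_numpy().mean()
    assert observed == pytest.approx(expected, abs=0.03)


def test_missingness_monotone_in_intensity_decile():
    st = simulate_study(tiny_cfg(n_proteins=2000, seed=9,
                                 mnar_midpoint=22.0, mnar_slope=0.8))
    truth = st.ground_truth.true_log2["Total"].to_numpy().ravel()
    obs = st.protein["Total"].mask.to_numpy().ravel()
    deciles = np.quantile(truth, np.linspace(0, 1, 11))
    rates = [obs[(truth >= lo) & (truth < hi)].mean()
             for lo, hi in zip(deciles[:-1], deciles[1:])]
    assert all(b >= a - 0.02 for a, b in zip(rates[:-1], rates[1:]))


# ---------------------------------------------------------------- force curves


def test_force_curve_doubling_modulus_doubles_force():
    d = np.linspace(0, 8e-7, 20)
    f1 = hertz_force(d, 1000.0)
    f2 = hertz_force(d, 2000.0)
    assert np.allclose(f2, 2 * f1)


def test_force_curves_nonpositive_modulus_rejected():
    with pytest.raises(ValueError):
        simulate_force_curves({"a": -5.0}, grid=(2, 2))


def test_force_curve_set_grid_and_regions():
    cs = simulate_force_curves({"a": 1000.0, "b": 2000.0}, grid=(4, 10),
                               noise_cv=0.0, seed=1)
    assert len(cs.curves) == 40
    assert set(cs.manifest["region"]) == {"a", "b"}
    assert cs.manifest.groupby("region").size().tolist() == [20, 20]


def test_fibrosis_area_tracks_burden():
    st = simulate_study(tiny_cfg(n_proteins=30, seed=21,
                                 fibrosis_noise_pct=0.1))
    fib = st.fibrosis
    cc = fib[fib["model"] == "CCl4like"].groupby("timepoint")["sr_area_pct"].mean()
    assert cc["T2"] > cc["T1"] > cc["Ctrl"]
    assert cc["T2"] > cc["T4"]
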
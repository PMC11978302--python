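"""AFM force-curve processing and region stiffness statistics.

A raw approach curve is a series of (piezo height, force) samples.  The
contact point is located by an exhaustive two-segment least-squares fit
(linear pre-contact baseline plus a Hertzian rise), the indentation is
computed as delta = (z - z_contact) - F/k (piezo travel minus cantilever
deflection), and the Young's modulus follows from a linear least-squares fit
of F against delta^(3/2) via the spherical Hertz relation

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

with Poisson ratio nu = 0.45 and bead radius R = 2.85 um by default.  Region
histograms and medians, Kruskal-Wallis/Dunn comparisons across treatments on
pooled pixel values, and the stiffness-proteome correlation complete the
module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import mass_pearson
from .simulate import ForceCurve, ForceCurveSet
from .stats import benjamini_hochberg, kruskal_wallis_dunn


class NoContactError(ValueError):
    """The two-segment fit found no Hertzian rise in the curve."""


@dataclass
class ContactFit:
    index: int                 # first post-contact sample
    baseline: tuple            # (intercept N, slope N/m)
    hertz_coeff: float         # a in F = a * delta^(3/2)
    sse: float


def find_contact_point(height_m: np.ndarray, force_n: np.ndarray,
                       spring_n_per_m: float, min_pre: int = 5,
                       min_post: int = 10) -> ContactFit:
    """Exhaustive two-segment least-squares contact-point search.

    For every candidate index the pre-segment is fit by a straight baseline
    and the post-segment by the Hertz rise on the baseline-subtracted forces;
    the candidate minimizing the total squared residual wins.
    """
    z = np.asarray(height_m, dtype=float)
    f = np.asarray(force_n, dtype=float)
    n = z.size
    if n < min_pre + min_post or n < 20:
        raise ValueError("need >= 20 samples spanning pre- and post-contact")
    cand = np.arange(min_pre, n - min_post + 1)

    # prefix sums -> baseline fit over [0, i) for every candidate i
    cz, czz = np.cumsum(z), np.cumsum(z * z)
    cf, czf = np.cumsum(f), np.cumsum(z * f)
    i = cand.astype(float)
    sz, szz = cz[cand - 1], czz[cand - 1]
    sf, szf = cf[cand - 1], czf[cand - 1]
    den = i * szz - sz ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        b1 = np.where(den > 0, (i * szf - sz * sf) / den, 0.0)
    b0 = (sf - b1 * sz) / i

    resid = f[None, :] - (b0[:, None] + b1[:, None] * z[None, :])
    post = np.arange(n)[None, :] >= cand[:, None]
    delta = (z[None, :] - z[cand][:, None]) - resid / spring_n_per_m
    delta = np.where(post, np.clip(delta, 0.0, None), 0.0)
    d32 = delta ** 1.5
    num = (d32 * resid * post).sum(axis=1)
    den_a = (delta ** 3 * post).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(den_a > 0, num / den_a, 0.0)
    a = np.clip(a, 0.0, None)
    sse_post = (((resid - a[:, None] * d32) ** 2) * post).sum(axis=1)
    sse_pre = ((resid ** 2) * ~post).sum(axis=1)
    sse = sse_pre + sse_post

    best = int(np.argmin(sse))
    if not np.isfinite(sse[best]) or a[best] <= 0.0:
        raise NoContactError("no contact detected")
    return ContactFit(index=int(cand[best]),
                      baseline=(float(b0[best]), float(b1[best])),
                      hertz_coeff=float(a[best]), sse=float(sse[best]))


def indentation(curve: ForceCurve, contact: ContactFit):
    """Baseline-subtracted post-contact (indentation, force) arrays."""
    z, f = curve.height_m, curve.force_n
    b0, b1 = contact.baseline
    fc = f - (b0 + b1 * z)
    post = slice(contact.index, None)
    delta = (z[post] - z[contact.index]) - fc[post] / curve.spring_n_per_m
    return np.clip(delta, 0.0, None), fc[post]


def fit_hertz_sphere(delta_m: np.ndarray, force_n: np.ndarray,
                     radius_m: float, poisson: float = 0.45,
                     delta_max_frac: float = 0.3) -> float:
    """Young's modulus (Pa) from a contact-aligned curve.

    Linear least squares of F on delta^(3/2), restricted to the
    small-indentation regime delta <= delta_max_frac * R.
    """
    d = np.asarray(delta_m, dtype=float)
    f = np.asarray(force_n, dtype=float)
    keep = (d >= 0) & (d <= delta_max_frac * radius_m)
    d, f = d[keep], f[keep]
    denom = (d ** 3).sum()
    if denom == 0:
        raise NoContactError("no usable indentation range")
    a = (d ** 1.5 * f).sum() / denom
    e = 0.75 * a * (1.0 - poisson ** 2) / np.sqrt(radius_m)
    if not np.isfinite(e) or e <= 0:
        raise NoContactError("non-positive modulus fit")
    return float(e)


def process_curve(curve: ForceCurve, delta_max_frac: float = 0.3) -> dict:
    """Contact detection + Hertz fit for one curve; failures are flagged."""
    try:
        contact = find_contact_point(curve.height_m, curve.force_n,
                                     curve.spring_n_per_m)
        delta, force = indentation(curve, contact)
        e = fit_hertz_sphere(delta, force, curve.radius_m, curve.poisson,
                             delta_max_frac)
        return {"modulus_pa": e, "contact_index": contact.index, "ok": True}
    except (NoContactError, ValueError):
        return {"modulus_pa": np.nan, "contact_index": -1, "ok": False}


def fit_curve_set(curve_set: ForceCurveSet,
                  delta_max_frac: float = 0.3) -> pd.DataFrame:
    """Stiffness map table: manifest columns plus fitted modulus per pixel."""
    fits = [process_curve(curve_set.curves[cid], delta_max_frac)
            for cid in curve_set.manifest["curve_id"]]
    out = curve_set.manifest.copy()
    out["modulus_pa"] = [f["modulus_pa"] for f in fits]
    out["contact_index"] = [f["contact_index"] for f in fits]
    out["ok"] = [f["ok"] for f in fits]
    return out


def build_region_stats(stiffness: pd.DataFrame, bins=None):
    """Pooled histograms/medians per (region, treatment) + per-map medians.

    Failed fits are excluded.  Returns (region_stats, map_medians).
    """
    ok = stiffness[stiffness["ok"] & np.isfinite(stiffness["modulus_pa"])]
    if bins is None:
        top = ok["modulus_pa"].quantile(0.995) if len(ok) else 1.0
        bins = np.linspace(0.0, float(top), 41)
    rows = []
    for (region, tp), grp in ok.groupby(["region", "treatment"], sort=False):
        counts, edges = np.histogram(grp["modulus_pa"], bins=bins)
        rows.append({"region": region, "treatment": tp,
                     "median_pa": float(grp["modulus_pa"].median()),
                     "n_curves": len(grp), "n_maps": grp["map_id"].nunique(),
                     "hist_counts": counts, "hist_edges": np.asarray(bins)})
    map_medians = (ok.groupby(["map_id", "treatment", "mouse", "region"],
                              sort=False)["modulus_pa"]
                   .median().reset_index(name="median_pa"))
    return pd.DataFrame(rows), map_medians


def compare_regions(stiffness: pd.DataFrame, reference: str = "Ctrl",
                    adjust: str = "bonferroni") -> dict:
    """Per region: Kruskal-Wallis over treatments on pooled pixel values,
    then Dunn post-tests against the reference treatment."""
    ok = stiffness[stiffness["ok"] & np.isfinite(stiffness["modulus_pa"])]
    out = {}
    for region, grp in ok.groupby("region", sort=False):
        tps = [t for t in grp["treatment"].unique()]
        if reference not in tps or len(tps) < 2:
            continue
        groups = [grp.loc[grp["treatment"] == t, "modulus_pa"].to_numpy()
                  for t in tps]
        omnibus, dunn = kruskal_wallis_dunn(groups, adjust=adjust,
                                            reference=tps.index(reference))
        named = {tps[res.extra["pair"][0]]: res for res in dunn}
        out[region] = {"treatments": tps, "kruskal": omnibus, "dunn": named}
    return out


def stiffness_mouse_deltas(map_medians: pd.DataFrame,
                           reference: str = "Ctrl") -> pd.DataFrame:
    """Per-mouse, per-region stiffness deltas from the mean control modulus.

    Median moduli of each analyzed map are first averaged per mouse, then the
    mean control value of the region is subtracted.
    """
    per_mouse = (map_medians.groupby(["region", "treatment", "mouse"],
                                     sort=False)["median_pa"]
                 .mean().reset_index())
    rows = []
    for region, grp in per_mouse.groupby("region", sort=False):
        ctrl = grp.loc[grp["treatment"] == reference, "median_pa"]
        if ctrl.empty:
            continue
        for _, r in grp.iterrows():
            rows.append({"region": region, "treatment": r["treatment"],
                         "mouse": r["mouse"],
                         "stiffness_delta_pa": r["median_pa"] - ctrl.mean()})
    return pd.DataFrame(rows)


def correlate_stiffness_proteome(stiff_deltas: pd.DataFrame,
                                 protein_deltas: pd.DataFrame,
                                 design: pd.DataFrame, mouse_map: dict,
                                 region: str = "collagen",
                                 include_controls: bool = False,
                                 q: float = 0.05) -> pd.DataFrame:
    """Per-protein Pearson slope of abundance delta vs stiffness delta.

    ``mouse_map`` pairs AFM mice with proteome mice.  Proteins with fewer
    than 3 paired points are skipped.
    """
    sub = stiff_deltas[stiff_deltas["region"] == region]
    if not include_controls:
        sub = sub[sub["treatment"] != "Ctrl"]
    meta = design.set_index("sample_id")
    mouse_to_sample = {}
    for c in protein_deltas.columns:
        if c in meta.index:
            mouse_to_sample[meta.loc[c, "mouse"]] = c
    pairs = []
    for _, r in sub.iterrows():
        pm = mouse_map.get(r["mouse"])
        if pm in mouse_to_sample:
            pairs.append((r["stiffness_delta_pa"], mouse_to_sample[pm]))
    if len(pairs) < 3:
        raise ValueError("fewer than 3 paired (AFM mouse, proteome mouse) points")
    x = np.array([p[0] for p in pairs])
    cols = [p[1] for p in pairs]
    y = protein_deltas[cols].to_numpy(dtype=float)
    slope, r, p = mass_pearson(x, y)
    fdr = benjamini_hochberg(p, q)
    return pd.DataFrame({
        "region": region, "slope": slope, "r": r, "p": p,
        "q_value": fdr.p_adjusted, "significant": fdr.rejected,
        "direction": np.where(slope > 0, "positive", "negative"),
        "n": len(pairs),
    }, index=protein_deltas.index)
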
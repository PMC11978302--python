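"""Synthetic-study generator with recorded ground truth.

Emulates the full study design — two liver-fibrosis models (hepatotoxic and
cholestatic), five terminal time points with six mice each, and three protein
fractions per mouse — so every downstream stage of the pipeline can be tested
against planted truth without any external download.

Planted protein classes
-----------------------
``tracking_pos``    rises with fibrosis in every fraction (+effect at T2) and
                    reverts with healing;
``declining``       the mirror image with negative sign;
``solubility_shift`` gains the effect only in the insoluble E fraction;
``null``            baseline plus noise only.

The temporal effect profile is piecewise linear over Ctrl -> T1 -> T2 and is
reversed by the model's healing factor at T3 (half) and T4 (full), so a model
with healing factor near 1 returns to baseline while one near 0 stays high.
Intensity-dependent (left-censored) missingness, per-mouse fibrosis areas and
region-resolved AFM force curves are generated from the same configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import FRACTIONS, MODELS, TIMEPOINTS, make_design
from .matrix import IntensityMatrix

PROTEIN_CLASSES = ("tracking_pos", "declining", "solubility_shift", "null")

#: median Young's moduli (Pa) measured per tissue region and treatment,
#: used as the generator's default regional stiffness truth
DEFAULT_REGION_MODULI_PA = {
    "Ctrl": {"collagen": 1600.0, "injured_hepatocyte": 1300.0, "interface_hepatocyte": 1200.0},
    "T1":   {"collagen": 2700.0, "injured_hepatocyte": 1900.0, "interface_hepatocyte": 800.0},
    "T2":   {"collagen": 4400.0, "injured_hepatocyte": 2800.0, "interface_hepatocyte": 2000.0},
    "T4":   {"collagen": 3000.0, "injured_hepatocyte": 2500.0, "interface_hepatocyte": 1400.0},
}

DEFAULT_PROBE_RADIUS_M = 2.85e-6      # half of the 5.7 um spherical bead
DEFAULT_POISSON_RATIO = 0.45
DEFAULT_SPRING_N_PER_M = 0.09


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_proteins: int = 4734
    n_mice_per_group: int = 6
    models: tuple = MODELS
    timepoints: tuple = TIMEPOINTS
    frac_fibrosis_tracking: float = 0.05
    frac_declining: float = 0.05
    frac_solubility_shift: float = 0.05
    effect_log2: float = 2.0          # planted log2 effect at peak fibrosis (T2)
    noise_sd_log2: float = 0.5
    baseline_mean_log2: float = 23.0
    baseline_sd_log2: float = 2.0
    mnar_midpoint: float = 18.5       # log2 intensity at 50% detection
    mnar_slope: float = 0.8
    healing_factor: dict = field(
        default_factory=lambda: {"CCl4like": 0.9, "DDClike": 0.1})
    peptides_per_protein: tuple = (3, 8)
    peptide_noise_cv: float = 0.1
    sample_factor_sd_log2: float = 0.3   # per-sample loading the LFQ coefficients undo
    peptide_mnar_offset: float = 2.0     # peptide-level MNAR midpoint = mnar_midpoint - offset
    fibrosis_background_pct: float = 0.6
    fibrosis_amplitude_pct: float = 12.0
    fibrosis_noise_pct: float = 1.0
    afm_region_moduli_pa: dict = field(
        default_factory=lambda: {t: dict(r) for t, r in DEFAULT_REGION_MODULI_PA.items()})
    afm_grid: tuple = (10, 36)
    afm_maps_per_treatment: int = 7
    afm_mice_per_treatment: int = 3
    afm_noise_cv: float = 0.05
    with_peptides: bool = True
    with_afm: bool = True
    seed: int = 0

    def validate(self) -> None:
        fr = (self.frac_fibrosis_tracking, self.frac_declining,
              self.frac_solubility_shift)
        if any(f < 0 for f in fr) or sum(fr) > 1:
            raise ConfigurationError("class proportions must be >= 0 and sum to <= 1")
        if self.noise_sd_log2 <= 0:
            raise ConfigurationError("noise_sd_log2 must be > 0")
        for m in self.models:
            h = self.healing_factor.get(m)
            if h is None or not 0 <= h <= 1:
                raise ConfigurationError(f"healing_factor for {m} must lie in [0, 1]")
        if self.n_proteins < 1 or self.n_mice_per_group < 1:
            raise ConfigurationError("n_proteins and n_mice_per_group must be >= 1")
        lo, hi = self.peptides_per_protein
        if not 1 <= lo <= hi:
            raise ConfigurationError("peptides_per_protein must be a valid range")


@dataclass
class AnnotationCatalog:
    """Protein -> matrisome category plus named keyword sets."""
    categories: pd.Series                 # "" for non-matrisome proteins
    keyword_sets: dict[str, set] = field(default_factory=dict)

    def members(self, term: str) -> set:
        if term in self.keyword_sets:
            return set(self.keyword_sets[term])
        return set(self.categories.index[self.categories == term])

    @property
    def terms(self) -> list[str]:
        cats = [c for c in self.categories.unique() if c]
        return sorted(cats) + sorted(self.keyword_sets)


@dataclass
class ForceCurve:
    height_m: np.ndarray
    force_n: np.ndarray
    radius_m: float = DEFAULT_PROBE_RADIUS_M
    poisson: float = DEFAULT_POISSON_RATIO
    spring_n_per_m: float = DEFAULT_SPRING_N_PER_M
    meta: dict = field(default_factory=dict)


@dataclass
class ForceCurveSet:
    curves: dict[str, ForceCurve]
    manifest: pd.DataFrame   # curve_id, map_id, treatment, mouse, region, row, col

    def extend(self, other: "ForceCurveSet") -> "ForceCurveSet":
        curves = {**self.curves, **other.curves}
        manifest = pd.concat([self.manifest, other.manifest], ignore_index=True)
        return ForceCurveSet(curves, manifest)


@dataclass
class GroundTruth:
    classes: pd.Series                       # protein -> class label
    effects: dict                            # (model, fraction) -> DataFrame proteins x timepoints
    sample_factors: pd.Series                # per-sample log2 loading factor
    true_log2: dict                          # fraction -> DataFrame (pre-missingness values)
    fibrosis_burden: pd.DataFrame            # model x timepoint unit burden profile
    region_moduli_pa: dict                   # treatment -> region -> Pa


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    design: pd.DataFrame
    protein: dict[str, IntensityMatrix]      # fraction -> matrix (post-missingness)
    peptides: pd.DataFrame | None
    fibrosis: pd.DataFrame                   # mouse_id, model, timepoint, sr_area_pct
    annotations: AnnotationCatalog
    signatures: dict[str, list]
    force_curves: ForceCurveSet | None
    ground_truth: GroundTruth


def effect_profile(healing: float, timepoints=TIMEPOINTS) -> pd.Series:
    """Unit effect weight per time point: linear rise to 1 at T2, then
    reversal by half the healing factor at T3 and the full factor at T4."""
    w = {"Ctrl": 0.0, "T1": 0.5, "T2": 1.0,
         "T3": 1.0 - healing / 2.0, "T4": 1.0 - healing}
    return pd.Series([w.get(t, 0.0) for t in timepoints], index=list(timepoints))


def apply_missingness(matrix: IntensityMatrix, midpoint: float, slope: float,
                      seed: int) -> IntensityMatrix:
    """Mask each observed value with probability 1/(1+exp(slope*(x-midpoint))).

    Low-intensity values are preferentially lost (left-censored, MNAR).
    Already-missing cells stay missing; surviving values are unchanged.
    """
    if slope <= 0:
        raise ValueError("slope must be > 0")
    rng = np.random.default_rng(seed)
    x = matrix.values.to_numpy(copy=True)
    obs = matrix.mask.to_numpy()
    with np.errstate(over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(slope * (x - midpoint)))
    u = rng.random(x.shape)
    drop = obs & np.isfinite(x) & (u < p_miss)
    x[drop | ~obs] = np.nan
    values = pd.DataFrame(x, index=matrix.values.index, columns=matrix.values.columns)
    return IntensityMatrix(values=values, mask=values.notna(),
                           provenance=matrix.provenance)


def _assign_classes(cfg: SimulationConfig, rng) -> pd.Series:
    ids = [f"P{i:05d}" for i in range(1, cfg.n_proteins + 1)]
    n_trk = int(round(cfg.frac_fibrosis_tracking * cfg.n_proteins))
    n_dec = int(round(cfg.frac_declining * cfg.n_proteins))
    n_shift = int(round(cfg.frac_solubility_shift * cfg.n_proteins))
    order = rng.permutation(cfg.n_proteins)
    classes = np.array(["null"] * cfg.n_proteins, dtype=object)
    classes[order[:n_trk]] = "tracking_pos"
    classes[order[n_trk:n_trk + n_dec]] = "declining"
    classes[order[n_trk + n_dec:n_trk + n_dec + n_shift]] = "solubility_shift"
    return pd.Series(classes, index=pd.Index(ids, name="protein_id"), name="class")


def _planted_effects(cfg: SimulationConfig, classes: pd.Series) -> dict:
    """(model, fraction) -> DataFrame of planted log2 effects (proteins x timepoints)."""
    sign = pd.Series(0.0, index=classes.index)
    sign[classes == "tracking_pos"] = 1.0
    sign[classes == "declining"] = -1.0
    shift = (classes == "solubility_shift").astype(float)
    effects = {}
    for model in cfg.models:
        w = effect_profile(cfg.healing_factor[model], cfg.timepoints)
        for frac in FRACTIONS:
            amp = sign * cfg.effect_log2
            if frac == "E":
                amp = amp + shift * cfg.effect_log2
            effects[(model, frac)] = pd.DataFrame(
                np.outer(amp.to_numpy(), w.to_numpy()),
                index=classes.index, columns=w.index)
    return effects


def _simulate_peptides(cfg: SimulationConfig, design: pd.DataFrame,
                       true_log2: dict, sample_log2: pd.Series, rng) -> pd.DataFrame:
    lo, hi = cfg.peptides_per_protein
    proteins = true_log2["Total"].index
    n_pep = rng.integers(lo, hi + 1, size=len(proteins))
    prot_idx = np.repeat(np.arange(len(proteins)), n_pep)
    total = int(n_pep.sum())
    shares = rng.lognormal(mean=0.0, sigma=1.0, size=total)
    # normalize ionization shares within each protein
    sums = np.bincount(prot_idx, weights=shares)
    shares = shares / sums[prot_idx]
    ev = rng.choice(["unique", "razor", "other"], size=total, p=[0.75, 0.2, 0.05])

    sample_ids = design["sample_id"].tolist()
    frac_of = dict(zip(design["sample_id"], design["fraction"]))
    true_lin = {f: np.exp2(true_log2[f].to_numpy()) for f in FRACTIONS}
    col_of = {f: {s: j for j, s in enumerate(true_log2[f].columns)} for f in FRACTIONS}

    out = np.empty((total, len(sample_ids)))
    for j, s in enumerate(sample_ids):
        f = frac_of[s]
        t = true_lin[f][:, col_of[f][s]][prot_idx]
        noise = rng.lognormal(mean=-0.5 * np.log1p(cfg.peptide_noise_cv ** 2),
                              sigma=np.sqrt(np.log1p(cfg.peptide_noise_cv ** 2)),
                              size=total)
        out[:, j] = t * shares * np.exp2(sample_log2[s]) * noise
    # peptide-level left-censored missingness
    mid = cfg.mnar_midpoint - cfg.peptide_mnar_offset
    with np.errstate(divide="ignore", over="ignore"):
        p_miss = 1.0 / (1.0 + np.exp(cfg.mnar_slope * (np.log2(out) - mid)))
    out[rng.random(out.shape) < p_miss] = np.nan

    pep = pd.DataFrame(out, columns=sample_ids)
    pep.insert(0, "evidence_class", ev)
    pep.insert(0, "protein_id", proteins.to_numpy()[prot_idx])
    pep.insert(0, "peptide_id", [f"pep{i:06d}" for i in range(total)])
    return pep


def _build_annotations(classes: pd.Series, rng) -> tuple[AnnotationCatalog, dict]:
    core = ["Collagens", "ECM Glycoproteins", "Proteoglycans"]
    assoc = ["ECM-affiliated", "ECM Regulators", "Secreted Factors"]
    cats = pd.Series("", index=classes.index, name="category", dtype=object)
    trk = classes.index[classes == "tracking_pos"].to_numpy()
    shf = classes.index[classes == "solubility_shift"].to_numpy()
    if len(trk):
        cats[trk] = [core[i % len(core)] for i in range(len(trk))]
    if len(shf):
        cats[shf] = [assoc[i % len(assoc)] for i in range(len(shf))]
    dec = classes.index[classes == "declining"].to_numpy()
    keyword_sets = {
        "matrisome": set(trk) | set(shf),
        "metabolism": set(dec),
    }
    catalog = AnnotationCatalog(categories=cats, keyword_sets=keyword_sets)

    # cell-type marker signatures with the published per-signature sizes
    sig_defs = [("hepatocytes", dec, 18), ("stellate_cells", trk, 3),
                ("portal_fibroblasts", trk, 4), ("kupffer_cells", trk, 6),
                ("granulocytes", trk, 16), ("macrophages", trk, 33)]
    signatures, used = {}, {"dec": 0, "trk": 0}
    pools = {"dec": list(dec), "trk": list(trk)}
    for name, pool, size in sig_defs:
        key = "dec" if pool is dec else "trk"
        start = used[key]
        members = pools[key][start:start + size]
        used[key] += len(members)
        if members:
            signatures[name] = members
    return catalog, signatures


def _simulate_fibrosis(cfg: SimulationConfig, design: pd.DataFrame, rng) -> pd.DataFrame:
    mice = design[["mouse", "model", "timepoint"]].drop_duplicates()
    rows = []
    for _, r in mice.iterrows():
        w = effect_profile(cfg.healing_factor[r["model"]], cfg.timepoints)[r["timepoint"]]
        area = (cfg.fibrosis_background_pct + cfg.fibrosis_amplitude_pct * w
                + rng.normal(0.0, cfg.fibrosis_noise_pct))
        rows.append({"mouse_id": r["mouse"], "model": r["model"],
                     "timepoint": r["timepoint"], "sr_area_pct": max(0.0, area)})
    return pd.DataFrame(rows)


def hertz_force(delta_m: np.ndarray, modulus_pa: float,
                radius_m: float = DEFAULT_PROBE_RADIUS_M,
                poisson: float = DEFAULT_POISSON_RATIO) -> np.ndarray:
    """Spherical-indenter Hertz force F = (4/3) E/(1-nu^2) sqrt(R) delta^(3/2)."""
    d = np.clip(np.asarray(delta_m, dtype=float), 0.0, None)
    return (4.0 / 3.0) * modulus_pa / (1.0 - poisson ** 2) * np.sqrt(radius_m) * d ** 1.5


def _region_bands(grid: tuple, regions: list[str]) -> np.ndarray:
    """Assign regions to contiguous column bands of the pixel grid."""
    rows, cols = grid
    edges = np.linspace(0, cols, len(regions) + 1).astype(int)
    labels = np.empty(cols, dtype=object)
    for i, r in enumerate(regions):
        labels[edges[i]:edges[i + 1]] = r
    return np.tile(labels, (rows, 1))


def simulate_force_curves(region_truth: dict, grid: tuple = (10, 36),
                          noise_cv: float = 0.05, seed: int = 0,
                          radius_m: float = DEFAULT_PROBE_RADIUS_M,
                          poisson: float = DEFAULT_POISSON_RATIO,
                          spring_n_per_m: float = DEFAULT_SPRING_N_PER_M,
                          map_id: str = "map0", treatment: str = "Ctrl",
                          mouse: str = "m1", n_pre: int = 30, n_post: int = 50,
                          indent_max_m: float = 8.0e-7) -> ForceCurveSet:
    """One stiffness map of Hertzian approach curves on a pixel grid.

    Each pixel's curve follows the spherical Hertz model at its region's
    Young's modulus with multiplicative force noise of the given CV and a
    random, slightly tilted pre-contact baseline (so contact-point detection
    is exercised by the fit).
    """
    for r, e in region_truth.items():
        if e <= 0:
            raise ValueError(f"non-positive modulus for region {r!r}")
    rng = np.random.default_rng(seed)
    regions = list(region_truth)
    region_grid = _region_bands(grid, regions)
    curves, rows = {}, []
    for i in range(grid[0]):
        for j in range(grid[1]):
            region = region_grid[i, j]
            e_true = region_truth[region]
            z_c = rng.uniform(8.0e-7, 1.2e-6)
            delta = np.linspace(0.0, indent_max_m, n_post)
            f_true = hertz_force(delta, e_true, radius_m, poisson)
            f_meas = f_true * (1.0 + noise_cv * rng.standard_normal(n_post))
            z_post = z_c + delta + f_meas / spring_n_per_m
            z_pre = np.linspace(0.0, z_c, n_pre, endpoint=False)
            z = np.concatenate([z_pre, z_post])
            force = np.concatenate([np.zeros(n_pre), f_meas])
            b0 = rng.normal(0.0, 2.0e-11)
            b1 = rng.normal(0.0, 2.0e-5)
            force = force + b0 + b1 * z
            cid = f"{map_id}_r{i:02d}c{j:02d}"
            curves[cid] = ForceCurve(z, force, radius_m, poisson, spring_n_per_m,
                                     meta={"region": region, "treatment": treatment,
                                           "mouse": mouse, "map_id": map_id})
            rows.append({"curve_id": cid, "map_id": map_id, "treatment": treatment,
                         "mouse": mouse, "region": region, "row": i, "col": j,
                         "radius_m": radius_m, "poisson": poisson,
                         "spring_n_per_m": spring_n_per_m})
    return ForceCurveSet(curves, pd.DataFrame(rows))


def _simulate_afm(cfg: SimulationConfig, rng) -> ForceCurveSet:
    out = None
    treatments = [t for t in cfg.afm_region_moduli_pa]
    for tp in treatments:
        truth = cfg.afm_region_moduli_pa[tp]
        for m in range(cfg.afm_maps_per_treatment):
            mouse = f"afm_{tp}_m{(m % cfg.afm_mice_per_treatment) + 1}"
            cs = simulate_force_curves(
                truth, grid=cfg.afm_grid, noise_cv=cfg.afm_noise_cv,
                seed=int(rng.integers(2 ** 31)), map_id=f"{tp}_map{m}",
                treatment=tp, mouse=mouse)
            out = cs if out is None else out.extend(cs)
    return out


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate a complete synthetic study, deterministic given config.seed."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (seed_classes, seed_values, seed_miss, seed_pep,
     seed_fib, seed_afm) = [np.random.default_rng(s) for s in ss.spawn(6)]

    classes = _assign_classes(config, seed_classes)
    base = seed_classes.normal(config.baseline_mean_log2, config.baseline_sd_log2,
                               size=config.n_proteins)
    effects = _planted_effects(config, classes)

    design = make_design(config.models, config.timepoints, FRACTIONS,
                         config.n_mice_per_group)
    sample_log2 = pd.Series(
        seed_values.normal(0.0, config.sample_factor_sd_log2, size=len(design)),
        index=design["sample_id"], name="log2_loading")

    true_log2, protein = {}, {}
    for frac in FRACTIONS:
        dsub = design[design["fraction"] == frac]
        cols = dsub["sample_id"].tolist()
        vals = np.empty((config.n_proteins, len(cols)))
        for j, (_, r) in enumerate(dsub.iterrows()):
            eff = effects[(r["model"], frac)][r["timepoint"]].to_numpy()
            vals[:, j] = base + eff + seed_values.normal(
                0.0, config.noise_sd_log2, size=config.n_proteins)
        df = pd.DataFrame(vals, index=classes.index, columns=cols)
        true_log2[frac] = df
        mat = IntensityMatrix.from_values(df.copy())
        protein[frac] = apply_missingness(
            mat, config.mnar_midpoint, config.mnar_slope,
            seed=int(seed_miss.integers(2 ** 31)))

    peptides = None
    if config.with_peptides:
        peptides = _simulate_peptides(config, design, true_log2, sample_log2, seed_pep)

    fibrosis = _simulate_fibrosis(config, design, seed_fib)
    catalog, signatures = _build_annotations(classes, seed_classes)
    force_curves = _simulate_afm(config, seed_afm) if config.with_afm else None

    burden = pd.DataFrame(
        {m: effect_profile(config.healing_factor[m], config.timepoints)
         for m in config.models}).T
    truth = GroundTruth(classes=classes, effects=effects,
                        sample_factors=sample_log2, true_log2=true_log2,
                        fibrosis_burden=burden,
                        region_moduli_pa={t: dict(r) for t, r in
                                          config.afm_region_moduli_pa.items()})
    return SyntheticStudy(config=config, design=design, protein=protein,
                          peptides=peptides, fibrosis=fibrosis,
                          annotations=catalog, signatures=signatures,
                          force_curves=force_curves, ground_truth=truth)
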
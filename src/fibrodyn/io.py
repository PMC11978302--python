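"""Readers and writers for the pipeline's plain-text formats.

Everything is TSV (tables), GMT (gene/protein sets) or JSON (nested
metadata).  Matrices are written with a sidecar JSON recording provenance
(filter rule, normalization, imputation seed) so a run can be audited.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import IntensityMatrix
from .simulate import AnnotationCatalog, ForceCurve, ForceCurveSet, SyntheticStudy


def write_matrix(matrix: IntensityMatrix, path, extra_meta: dict | None = None) -> None:
    path = Path(path)
    df = matrix.values.copy()
    df.index.name = "protein_id"
    df.to_csv(path, sep="\t", float_format="%.8g")
    meta = {"provenance": matrix.provenance, "seed": matrix.seed,
            "n_proteins": int(df.shape[0]), "n_samples": int(df.shape[1])}
    meta.update(extra_meta or {})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    mask = matrix.mask.astype(int)
    mask.index.name = "protein_id"
    mask.to_csv(path.with_name(path.stem + ".mask.tsv"), sep="\t")


def read_matrix(path) -> IntensityMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col="protein_id")
    meta_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    mask_path = path.with_name(path.stem + ".mask.tsv")
    if mask_path.exists():
        mask = pd.read_csv(mask_path, sep="\t", index_col="protein_id").astype(bool)
    else:
        mask = values.notna()
    return IntensityMatrix(values=values, mask=mask,
                           provenance=meta.get("provenance", "raw"),
                           seed=meta.get("seed"))


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.8g")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_gmt(sets: dict, path, description: str = "fibrodyn") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *map(str, members)]) + "\n")


def read_gmt(path) -> dict[str, list]:
    out = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        out[fields[0]] = fields[2:]
    return out


def write_annotations(catalog: AnnotationCatalog, outdir) -> None:
    outdir = Path(outdir)
    cats = catalog.categories.rename_axis("protein_id").reset_index()
    write_table(cats, outdir / "matrisome_categories.tsv")
    write_gmt(catalog.keyword_sets, outdir / "keyword_sets.gmt")


def read_annotations(outdir) -> AnnotationCatalog:
    outdir = Path(outdir)
    cats = read_table(outdir / "matrisome_categories.tsv")
    series = cats.set_index("protein_id")["category"].fillna("")
    keywords = {k: set(v) for k, v in read_gmt(outdir / "keyword_sets.gmt").items()}
    return AnnotationCatalog(categories=series, keyword_sets=keywords)


def write_force_curves(curve_set: ForceCurveSet, outdir) -> None:
    """Per-curve two-column TSV (height_m, force_N) plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for cid, c in curve_set.curves.items():
        pd.DataFrame({"height_m": c.height_m, "force_n": c.force_n}).to_csv(
            outdir / f"{cid}.tsv", sep="\t", index=False, float_format="%.10g")
    manifest = curve_set.manifest.to_dict(orient="records")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_force_curves(outdir) -> ForceCurveSet:
    outdir = Path(outdir)
    manifest = pd.DataFrame(json.loads((outdir / "manifest.json").read_text()))
    curves = {}
    for _, r in manifest.iterrows():
        df = pd.read_csv(outdir / f"{r['curve_id']}.tsv", sep="\t")
        curves[r["curve_id"]] = ForceCurve(
            height_m=df["height_m"].to_numpy(), force_n=df["force_n"].to_numpy(),
            radius_m=float(r["radius_m"]), poisson=float(r["poisson"]),
            spring_n_per_m=float(r["spring_n_per_m"]),
            meta={"region": r["region"], "treatment": r["treatment"],
                  "mouse": r["mouse"], "map_id": r["map_id"]})
    return ForceCurveSet(curves=curves, manifest=manifest)


def write_ground_truth(study: SyntheticStudy, path) -> None:
    gt = study.ground_truth
    planted = gt.classes[gt.classes != "null"]
    effects = {}
    for (model, frac), df in gt.effects.items():
        sub = df.loc[planted.index]
        sub = sub.loc[(sub != 0).any(axis=1)]
        effects[f"{model}:{frac}"] = {p: {tp: float(v) for tp, v in row.items()}
                                      for p, row in sub.iterrows()}
    payload = {
        "classes": gt.classes.to_dict(),
        "effects_nonzero": effects,
        "sample_factors_log2": {k: float(v) for k, v in gt.sample_factors.items()},
        "fibrosis_burden": {m: {tp: float(v) for tp, v in row.items()}
                            for m, row in gt.fibrosis_burden.iterrows()},
        "region_moduli_pa": gt.region_moduli_pa,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_study(study: SyntheticStudy, outdir, with_curves: bool = True) -> None:
    """Materialize a synthetic study in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(study.design, outdir / "design.tsv")
    for frac, mat in study.protein.items():
        write_matrix(mat, outdir / f"protein_{frac}.tsv")
    if study.peptides is not None:
        write_table(study.peptides, outdir / "peptides.tsv")
    write_table(study.fibrosis, outdir / "fibrosis.tsv")
    write_annotations(study.annotations, outdir)
    write_gmt(study.signatures, outdir / "celltype_signatures.gmt")
    if study.force_curves is not None and with_curves:
        write_force_curves(study.force_curves, outdir / "force_curves")
    write_ground_truth(study, outdir / "ground_truth.json")
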
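"""Unsupervised structure: PCA, complete-linkage clustering, enrichment.

PCA is a centered SVD of the sample-by-protein matrix.  Protein profiles
(mean z-scores per group) are clustered agglomeratively with Euclidean
distance and complete linkage, and each cluster is tested for annotation-term
enrichment with Fisher's exact test under BH control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .matrix import IntensityMatrix
from .simulate import AnnotationCatalog
from .stats import benjamini_hochberg, fisher_exact


@dataclass
class PcaResult:
    scores: pd.DataFrame          # samples x components
    loadings: pd.DataFrame        # proteins x components
    explained_variance: np.ndarray  # fractions, sum to 1


@dataclass
class Dendrogram:
    linkage: np.ndarray           # scipy linkage matrix
    ids: pd.Index                 # row ids in input order
    leaf_order: list              # ids in dendrogram leaf order
    metric: str = "euclidean"
    method: str = "complete"


def pca_scores(matrix: IntensityMatrix, n_components: int | None = None) -> PcaResult:
    """Principal components of the samples.

    Samples are observations; each protein (feature) is centered.  The sign
    of each component is fixed so its largest-magnitude loading is positive.
    """
    if len(matrix.samples) < 2:
        raise ValueError("PCA needs >= 2 samples")
    x = matrix.values.to_numpy().T                # samples x proteins
    if np.isnan(x).any():
        raise ValueError("PCA requires an imputed (complete) matrix")
    xc = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = len(s) if n_components is None else min(n_components, len(s))
    flip = np.sign(vt[np.arange(len(s)), np.abs(vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    u, vt = u * flip, vt * flip[:, None]
    evr = s ** 2 / (s ** 2).sum() if s.sum() > 0 else np.zeros_like(s)
    comps = [f"PC{i+1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame((u * s)[:, :k], index=matrix.samples, columns=comps),
        loadings=pd.DataFrame(vt[:k].T, index=matrix.proteins, columns=comps),
        explained_variance=evr[:k])


def hierarchical_cluster(profiles: pd.DataFrame) -> Dendrogram:
    """Agglomerative complete-linkage clustering of row profiles."""
    if profiles.shape[0] < 2:
        raise ValueError("need >= 2 rows to cluster")
    if profiles.isna().to_numpy().any():
        raise ValueError("profiles must not contain missing values")
    z = hierarchy.linkage(profiles.to_numpy(), method="complete",
                          metric="euclidean")
    order = hierarchy.leaves_list(z)
    return Dendrogram(linkage=z, ids=profiles.index,
                      leaf_order=[profiles.index[i] for i in order])


def cut_clusters(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cluster labels (1..k) from cutting after the (n-k)-th merge.

    Labels are numbered stably by first appearance in leaf order.
    """
    n = len(dendrogram.ids)
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    raw = hierarchy.cut_tree(dendrogram.linkage, n_clusters=k).ravel()
    labels = pd.Series(raw, index=dendrogram.ids, name="cluster")
    relabel, next_id = {}, 1
    for leaf in dendrogram.leaf_order:
        c = labels[leaf]
        if c not in relabel:
            relabel[c] = next_id
            next_id += 1
    return labels.map(relabel)


def cluster_annotation_enrichment(labels: pd.Series, catalog: AnnotationCatalog,
                                  q: float = 0.04,
                                  background: str = "clustered") -> pd.DataFrame:
    """Fisher enrichment of every annotation term in every cluster.

    The 2x2 table splits {in cluster, out of cluster} x {term, not term} over
    the clustered proteins (default background).  BH is applied across all
    (cluster, term) pairs jointly.
    """
    if background != "clustered":
        raise ValueError("only the 'clustered' background is implemented")
    universe = set(labels.index)
    rows = []
    for term in catalog.terms:
        members = catalog.members(term) & universe
        if not members:
            continue
        for c in sorted(labels.unique()):
            in_c = set(labels.index[labels == c])
            a = len(in_c & members)
            b = len(in_c) - a
            cc = len(members) - a
            d = len(universe) - a - b - cc
            res = fisher_exact([[a, b], [cc, d]])
            rows.append({"cluster": c, "term": term, "n_in_term": a,
                         "n_in_not_term": b, "n_out_term": cc, "n_out_not_term": d,
                         "odds_ratio": res.effect, "p": res.p_value})
    out = pd.DataFrame(rows)
    if out.empty:
        out["q"] = []
        out["significant"] = []
        return out
    fdr = benjamini_hochberg(out["p"].to_numpy(), q)
    out["q"] = fdr.p_adjusted
    out["significant"] = fdr.rejected & (out["odds_ratio"].fillna(np.inf) > 1)
    return out


def mean_group_profiles(zmatrix: IntensityMatrix, design: pd.DataFrame,
                        model: str | None = None,
                        fraction: str = "Total") -> pd.DataFrame:
    """Mean z-scored profile per (model, time point) group — clustering input."""
    meta = design.set_index("sample_id")
    cols = [c for c in zmatrix.samples if c in meta.index]
    meta = meta.loc[cols]
    sel = meta["fraction"] == fraction
    if model is not None:
        sel &= meta["model"] == model
    meta = meta[sel]
    prof = {}
    for (mdl, tp), grp in meta.groupby(["model", "timepoint"], sort=False):
        prof[f"{mdl}_{tp}"] = zmatrix.values[grp.index.tolist()].mean(axis=1)
    return pd.DataFrame(prof)
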
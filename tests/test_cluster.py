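"""PCA, complete-linkage clustering and annotation enrichment."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from fibrodyn import (IntensityMatrix, cluster_annotation_enrichment,
                      cut_clusters, hierarchical_cluster, pca_scores)
from fibrodyn.simulate import AnnotationCatalog


def matrix_from(values):
    df = pd.DataFrame(np.asarray(values, float))
    df.index = [f"P{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    return IntensityMatrix.from_values(df)


def complete_linkage_oracle(x):
    """Naive agglomerative complete linkage; returns sorted merge heights."""
    clusters = [[i] for i in range(len(x))]
    d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    heights = []
    while len(clusters) > 1:
        best, pair = np.inf, None
        for a, b in combinations(range(len(clusters)), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if h < best:
                best, pair = h, (a, b)
        a, b = pair
        heights.append(best)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


# ---------------------------------------------------------------- PCA


def test_pca_separates_shifted_groups():
    col = np.random.default_rng(0).normal(size=(30, 1))
    x = np.concatenate([col] * 4 + [col + 5.0] * 4, axis=1)  # duplicated groups
    res = pca_scores(matrix_from(x))
    pc1 = res.scores["PC1"].to_numpy()
    assert np.ptp(np.sign(pc1[:4])) == 0 and np.ptp(np.sign(pc1[4:])) == 0
    assert np.sign(pc1[0]) != np.sign(pc1[4])
    assert res.explained_variance[0] == pytest.approx(1.0, abs=1e-12)
    assert res.explained_variance[1] == pytest.approx(0.0, abs=1e-12)


def test_pca_explained_variance_sums_to_one(rng):
    res = pca_scores(matrix_from(rng.normal(size=(40, 8))))
    assert res.explained_variance.sum() == pytest.approx(1.0, abs=1e-12)


def test_pca_reconstruction_identity(rng):
    x = rng.normal(size=(20, 6))
    res = pca_scores(matrix_from(x))
    centered = x.T - x.T.mean(axis=0, keepdims=True)
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
    assert np.allclose(recon, centered, atol=1e-10)


def test_pca_needs_two_samples(rng):
    with pytest.raises(ValueError):
        pca_scores(matrix_from(rng.normal(size=(5, 1))))


# ---------------------------------------------------------------- clustering


def test_first_merge_joins_nearest_rows():
    profiles = pd.DataFrame([[0.0, 0.0], [0.0, 0.1], [10.0, 10.0]],
                            index=["a", "b", "c"])
    d = hierarchical_cluster(profiles)
    assert set(d.linkage[0, :2].astype(int)) == {0, 1}


def test_merge_heights_match_bruteforce_oracle(rng):
    for _ in range(5):
        x = rng.normal(size=(8, 3))
        profiles = pd.DataFrame(x, index=[f"r{i}" for i in range(8)])
        d = hierarchical_cluster(profiles)
        assert np.allclose(sorted(d.linkage[:, 2]), complete_linkage_oracle(x),
                           atol=1e-10)


def test_duplicate_rows_merge_at_zero(rng):
    x = rng.normal(size=(5, 3))
    x[3] = x[1]
    d = hierarchical_cluster(pd.DataFrame(x))
    assert d.linkage[0, 2] == 0.0
    assert set(d.linkage[0, :2].astype(int)) == {1, 3}


def test_cut_clusters_extremes(rng):
    profiles = pd.DataFrame(rng.normal(size=(6, 2)))
    d = hierarchical_cluster(profiles)
    assert cut_clusters(d, 1).nunique() == 1
    assert cut_clusters(d, 6).nunique() == 6
    with pytest.raises(ValueError):
        cut_clusters(d, 0)
    with pytest.raises(ValueError):
        cut_clusters(d, 7)


def test_cut_recovers_planted_blobs(rng):
    centers = np.array([[0, 0], [20, 0], [0, 20]])
    rows, truth = [], []
    for i, c in enumerate(centers):
        rows.append(c + rng.normal(0, 0.5, size=(10, 2)))
        truth += [i] * 10
    profiles = pd.DataFrame(np.vstack(rows))
    labels = cut_clusters(hierarchical_cluster(profiles), 3)
    # planted partition recovered exactly (Rand index 1)
    df = pd.DataFrame({"label": labels.to_numpy(), "truth": truth})
    assert (df.groupby("truth")["label"].nunique() == 1).all()
    assert (df.groupby("label")["truth"].nunique() == 1).all()


# ---------------------------------------------------------------- enrichment


def catalog_for(universe, term_members):
    cats = pd.Series("", index=pd.Index(universe, name="protein_id"))
    return AnnotationCatalog(categories=cats,
                             keyword_sets={"term": set(term_members)})


def test_enrichment_flags_pure_cluster():
    universe = [f"P{i}" for i in range(40)]
    labels = pd.Series([1] * 20 + [2] * 20, index=universe)
    members = universe[:20]     # cluster 1 entirely term members, background 50%
    rows = cluster_annotation_enrichment(labels, catalog_for(universe, members),
                                         q=0.04)
    hit = rows[(rows["cluster"] == 1) & (rows["term"] == "term")].iloc[0]
    assert hit["significant"]
    assert np.isinf(hit["odds_ratio"])


def test_enrichment_uniform_term_not_significant(small_study):
    rng = np.random.default_rng(0)
    universe = [f"P{i}" for i in range(60)]
    labels = pd.Series(rng.integers(1, 4, size=60), index=universe)
    members = universe[::2]     # uniformly spread
    rows = cluster_annotation_enrichment(labels, catalog_for(universe, members),
                                         q=0.04)
    assert not rows["significant"].any()


def test_enrichment_label_permutation_invariant_tables(rng):
    universe = [f"P{i}" for i in range(30)]
    labels = pd.Series(rng.integers(1, 4, size=30), index=universe)
    cat = catalog_for(universe, universe[:10])
    r1 = cluster_annotation_enrichment(labels, cat)
    relabel = {1: 3, 2: 1, 3: 2}
    r2 = cluster_annotation_enrichment(labels.map(relabel), cat)
    assert sorted(r1["p"].round(12)) == sorted(r2["p"].round(12))


def test_enrichment_empty_term_skipped():
    universe = [f"P{i}" for i in range(10)]
    labels = pd.Series([1] * 5 + [2] * 5, index=universe)
    rows = cluster_annotation_enrichment(labels, catalog_for(universe, []))
    assert rows.empty


def test_synthetic_matrisome_cluster_enriched(small_study):
    """Planted tracking/matrisome proteins share a profile and enrich."""
    from fibrodyn import (FilterRule, filter_by_valid_values, impute_downshift,
                          normalize_columns, zscore_rows)
    from fibrodyn.cluster import mean_group_profiles
    st = small_study
    mat = st.protein["Total"]
    meta = st.design.set_index("sample_id")
    cols = [c for c in mat.samples if meta.loc[c, "model"] == "CCl4like"]
    mat = mat.subset(samples=cols)
    mat = filter_by_valid_values(mat, st.design, FilterRule())
    mat = normalize_columns(mat)
    mat = impute_downshift(mat, seed=1)
    zmat, _ = zscore_rows(mat)
    profiles = mean_group_profiles(zmat, st.design, model="CCl4like")
    labels = cut_clusters(hierarchical_cluster(profiles), 6)
    rows = cluster_annotation_enrichment(labels, st.annotations, q=0.04)
    sig = rows[rows["significant"] & (rows["term"] == "matrisome")]
    assert len(sig) >= 1
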
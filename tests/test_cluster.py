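import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from meiodecay.cluster import (EmbeddingResult, embed_pca, kmeans_cluster,
                               normalize_log, rare_population_markers)
from meiodecay.errors import AnalysisError

from conftest import make_matrix


def test_normalize_equal_totals_unit_factors():
    counts = np.array([[1, 2, 3], [3, 2, 1], [2, 2, 2]])
    norm = normalize_log(make_matrix(counts))
    assert np.allclose(norm.size_factors, 1.0)
    assert np.allclose(norm.values, np.log1p(counts))


def test_normalize_zero_count_stays_zero_and_scale_invariance():
    counts = np.array([[0, 4, 2], [0, 8, 4], [1, 1, 1]])
    norm = normalize_log(make_matrix(counts))
    assert norm.values[0, 0] == 0.0
    # cell 1 is cell 0 doubled: identical normalized vectors
    assert np.allclose(norm.values[0], norm.values[1])


def test_normalize_drops_zero_total_cells(caplog):
    counts = np.array([[1, 2], [0, 0], [3, 1]])
    with caplog.at_level("WARNING"):
        norm = normalize_log(make_matrix(counts))
    assert norm.kept.tolist() == [True, False, True]


def test_pca_rank_two_data():
    rng = np.random.default_rng(0)
    basis = rng.normal(size=(2, 30))
    weights = rng.normal(size=(100, 2))
    values = weights @ basis + 5
    norm = type("N", (), {})()
    from meiodecay.cluster import NormalizedExpression
    norm = NormalizedExpression(values=values, kept=np.ones(100, bool),
                                size_factors=np.ones(100))
    emb = embed_pca(norm, n_components=5, seed=0)
    assert emb.explained_variance_ratio[:2].sum() > 0.999
    assert np.all(np.diff(emb.explained_variance_ratio) <= 1e-12)


def test_pca_component_limit():
    from meiodecay.cluster import NormalizedExpression
    norm = NormalizedExpression(values=np.random.default_rng(0).normal(size=(5, 4)),
                                kept=np.ones(5, bool), size_factors=np.ones(5))
    with pytest.raises(AnalysisError):
        embed_pca(norm, n_components=4)


def blobs_embedding(seed=0):
    rng = np.random.default_rng(seed)
    centers = np.array([[0, 0], [10, 0], [0, 10]])
    coords = np.vstack([rng.normal(c, 0.3, size=(40, 2)) for c in centers])
    truth = np.repeat([0, 1, 2], 40)
    emb = EmbeddingResult(coords=coords,
                          explained_variance=coords.var(axis=0),
                          explained_variance_ratio=np.array([0.6, 0.4]),
                          kept=np.ones(120, bool))
    return emb, truth


def test_kmeans_planted_blobs_exact_recovery():
    emb, truth = blobs_embedding()
    labels = kmeans_cluster(emb, k=3, seed=0)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_kmeans_k_one_and_determinism():
    emb, _ = blobs_embedding()
    assert len(set(kmeans_cluster(emb, k=1, seed=0))) == 1
    a = kmeans_cluster(emb, k=3, seed=42)
    b = kmeans_cluster(emb, k=3, seed=42)
    assert np.array_equal(a, b)


def test_kmeans_rejects_k_above_cells():
    emb, _ = blobs_embedding()
    with pytest.raises(AnalysisError):
        kmeans_cluster(emb, k=121)


# ---------------------------------------------------------------------------
# Rare-population differential expression
# ---------------------------------------------------------------------------

def de_matrix():
    """30 cells: 6-cell target cluster; genes probing the flag rule."""
    rng = np.random.default_rng(3)
    n = 30
    counts = np.zeros((n, 4), dtype=int)
    counts[:, 0] = rng.poisson(5, n)            # null gene
    counts[:6, 1] = rng.poisson(200, 6)         # planted marker, absent in rest
    counts[:, 2] = rng.poisson(5, n)
    counts[:6, 2] += rng.poisson(5, 6)          # ~2-fold enrichment only
    counts[:, 3] = rng.poisson(1, n)
    labels = np.zeros(n, dtype=int)
    labels[:6] = 1
    return make_matrix(counts, symbols=["null", "planted", "twofold", "weak"]), labels


def test_de_flags_planted_gene_and_not_nulls():
    matrix, labels = de_matrix()
    de = rare_population_markers(matrix, labels, target=1)
    flagged = set(de.loc[de["marker"], "symbol"])
    assert flagged == {"planted"}
    assert de.set_index("symbol").loc["planted", "log2fc"] > 7
    assert de.set_index("symbol").loc["twofold", "marker"] == False  # noqa: E712


def test_de_pvalues_in_unit_interval():
    matrix, labels = de_matrix()
    de = rare_population_markers(matrix, labels, target=1)
    assert ((de["pvalue"] > 0) & (de["pvalue"] <= 1)).all()
    assert ((de["padj"] >= de["pvalue"] - 1e-12)).all()


def test_de_requires_three_cells():
    matrix, labels = de_matrix()
    labels = labels.copy()
    labels[2:6] = 0  # target shrinks to 2 cells
    with pytest.raises(AnalysisError):
        rare_population_markers(matrix, labels, target=1)


def test_de_flag_monotone_in_fold_change():
    """Raising the target-cluster expression can only keep or gain the flag."""
    matrix, labels = de_matrix()
    de_low = rare_population_markers(matrix, labels, target=1)
    boosted = matrix.counts.toarray()
    boosted[labels == 1, 1] *= 4
    de_high = rare_population_markers(
        make_matrix(boosted, symbols=matrix.genes["symbol"].tolist()),
        labels, target=1)
    low = de_low.set_index("symbol")["marker"]
    high = de_high.set_index("symbol")["marker"]
    assert high["planted"] and (high | ~low).all()
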
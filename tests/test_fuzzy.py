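"""Fuzzy c-means updates, stage assignment and stage/biotype counting."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from lncstage.fuzzy import (
    FCMConfig,
    SoftClusterResult,
    StageAssignment,
    _memberships,
    assign_stages,
    fcm_cluster,
    stage_gene_counts,
)


def _frame(x):
    return pd.DataFrame(
        x, index=[f"g{i}" for i in range(len(x))],
        columns=[f"D{j}" for j in range(x.shape[1])],
    )


def _planted(n_per, centers, noise, seed):
    rng = np.random.default_rng(seed)
    blocks = [
        c + noise * rng.standard_normal((n_per, len(c)))
        for c in np.asarray(centers, dtype=float)
    ]
    return np.vstack(blocks)


# ---------------------------------------------------------------------------
# textbook oracle: plain-loop FCM from given initial centroids
# ---------------------------------------------------------------------------

def textbook_fcm(x, centroids, m, tol, max_iter):
    c = np.array(centroids, dtype=float)
    for _ in range(max_iter):
        u = np.zeros((len(x), len(c)))
        for i, xi in enumerate(x):
            d2 = np.array([np.sum((xi - cj) ** 2) for cj in c])
            if np.any(d2 == 0):
                u[i, d2 == 0] = 1.0 / np.sum(d2 == 0)
            else:
                for j in range(len(c)):
                    u[i, j] = 1.0 / np.sum((d2[j] / d2) ** (1.0 / (m - 1.0)))
        new_c = np.zeros_like(c)
        for j in range(len(c)):
            w = u[:, j] ** m
            new_c[j] = (w[:, None] * x).sum(axis=0) / w.sum()
        shift = np.abs(new_c - c).max()
        c = new_c
        if shift < tol:
            break
    return c, u


def test_fcm_matches_textbook_implementation():
    """On a 60x8 fixture the memberships equal an independently coded
    straight-line FCM to 1e-6 (same k-means++ initialization)."""
    x = _planted(20, [[0] * 8, [3] * 8, [-2, 2] * 4], 0.4, seed=11)
    cfg = FCMConfig(c=3, m=1.25, tol=1e-9, max_iter=500, seed=4, n_init=1)
    res = fcm_cluster(_frame(x), cfg)
    init, _ = kmeans_plusplus(x, n_clusters=3, random_state=cfg.seed)
    _, u_ref = textbook_fcm(x, init, m=1.25, tol=1e-9, max_iter=500)
    assert np.abs(res.memberships.to_numpy() - u_ref).max() < 1e-6


def test_membership_rows_sum_to_one_every_iteration():
    x = _planted(15, [[0] * 8, [2] * 8], 0.8, seed=2)
    res = fcm_cluster(_frame(x), FCMConfig(c=2, seed=0))
    assert max(res.rowsum_dev) < 1e-9
    rows = res.memberships.to_numpy().sum(axis=1)
    assert np.abs(rows - 1).max() < 1e-9


def test_objective_non_increasing():
    x = _planted(20, [[0] * 8, [1.5] * 8, [-1.5] * 8], 1.0, seed=9)
    res = fcm_cluster(_frame(x), FCMConfig(c=3, seed=1, n_init=1))
    h = np.array(res.objective_history)
    assert (np.diff(h) <= 1e-9).all()


def test_tight_clusters_give_near_hard_memberships():
    x = _planted(10, [[0] * 8, [5] * 8], 0.01, seed=3)
    res = fcm_cluster(_frame(x), FCMConfig(c=2, seed=0))
    assert res.memberships.to_numpy().max(axis=1).min() >= 0.99


def test_equidistant_point_splits_membership():
    d2 = np.array([[4.0, 4.0]])
    u = _memberships(d2, m=1.25)
    assert np.allclose(u, [[0.5, 0.5]])
    # coincident with a centroid -> full membership there
    u0 = _memberships(np.array([[0.0, 9.0]]), m=1.25)
    assert np.allclose(u0, [[1.0, 0.0]])


def test_m_near_one_matches_kmeans_hard_labels():
    from sklearn.cluster import KMeans

    x = _planted(25, [[0] * 8, [4] * 8, [-4, 4] * 4], 0.3, seed=7)
    cfg = FCMConfig(c=3, m=1.01, seed=5, n_init=1)
    res = fcm_cluster(_frame(x), cfg)
    init, _ = kmeans_plusplus(x, n_clusters=3, random_state=cfg.seed)
    km = KMeans(n_clusters=3, init=init, n_init=1, max_iter=500).fit(x)
    assert (res.hard_labels().to_numpy() == km.labels_).all()


def test_gene_order_equivariance():
    x = _planted(12, [[0] * 8, [3] * 8], 0.5, seed=8)
    z = _frame(x)
    res = fcm_cluster(z, FCMConfig(c=2, seed=2, n_init=1))
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(z))
    res_p = fcm_cluster(z.iloc[perm], FCMConfig(c=2, seed=2, n_init=1))
    u = res.memberships
    # same gene -> same membership row, up to centroid relabelling
    # (k-means++ on permuted rows may order the centroids differently)
    agree = res_p.memberships.reindex(u.index)
    match = np.argmin(cdist(res.centroids, res_p.centroids), axis=1)
    assert sorted(match) == list(range(len(match)))
    assert np.abs(agree.to_numpy()[:, match] - u.to_numpy()).max() < 1e-6


def test_config_validation_and_errors():
    with pytest.raises(ValueError):
        FCMConfig(c=1)
    with pytest.raises(ValueError):
        FCMConfig(c=3, m=1.0)
    x = _planted(2, [[0] * 8], 0.1, seed=0)
    with pytest.raises(ValueError, match="exceeds"):
        fcm_cluster(_frame(x), FCMConfig(c=5))


# ---------------------------------------------------------------------------
# stage assignment
# ---------------------------------------------------------------------------

def _stage_fixture(seed=0, noise=0.2):
    from lncstage.simulate import (
        BUNDLE_PROFILES,
        PlantedClusterSpec,
        STAGE_MARKER_IDS,
        generate_expression,
    )
    from lncstage.expression import ExpressionMatrix, standardize_time

    specs = [
        PlantedClusterSpec(
            profile=BUNDLE_PROFILES[stage], noise_sd=noise, stage=stage,
            n_genes=30, marker_ids=STAGE_MARKER_IDS[stage], name=stage,
        )
        for stage in ("pluripotency", "commitment", "later")
    ]
    pool = [f"g{i}" for i in range(110)]  # 90 planted + 20 background
    matrix, truth = generate_expression(pool, specs, seed=seed)
    ann = pd.DataFrame(index=matrix.index,
                       columns=["gene_class", "biotype", "partner_id"])
    z = standardize_time(ExpressionMatrix(data=matrix, annotations=ann))
    return z, truth


def test_marker_anchored_clusters_get_their_stage():
    z, truth = _stage_fixture(seed=1)
    res = fcm_cluster(z, FCMConfig(c=4, seed=1))
    stages = assign_stages(res)
    found = sorted(s for s in stages.mapping.values() if s != "unassigned")
    assert found == ["commitment", "later", "pluripotency"]
    # markers use legacy aliases transparently
    stages2 = assign_stages(
        res,
        {"commitment": ["PAX6", "SOX1"],
         "pluripotency": ["POU5F", "NANOG", "NODAL", "TDGF"],
         "later": ["EMX2", "TBR1", "CTIP2", "CACNA1E", "PRSS12", "CARTPT"]},
    )
    assert stages2.mapping == stages.mapping


def test_low_marker_membership_leaves_cluster_unassigned():
    u = pd.DataFrame(
        {"C0": [0.4, 0.3], "C1": [0.3, 0.4], "C2": [0.3, 0.3]},
        index=["PAX6", "SOX1"],
    )
    res = SoftClusterResult(
        centroids=np.zeros((3, 2)), memberships=u, iterations=1, objective=0.0
    )
    stages = assign_stages(res, {"commitment": ["PAX6", "SOX1"]})
    assert set(stages.mapping.values()) == {"unassigned"}


def test_stage_tie_is_unassigned(caplog):
    u = pd.DataFrame({"C0": [0.8, 0.8], "C1": [0.2, 0.2]},
                     index=["PAX6", "POU5F1"])
    res = SoftClusterResult(
        centroids=np.zeros((2, 2)), memberships=u, iterations=1, objective=0.0
    )
    with caplog.at_level("WARNING", logger="lncstage.fuzzy"):
        stages = assign_stages(
            res, {"commitment": ["PAX6"], "pluripotency": ["POU5F1"]}
        )
    assert stages.mapping[0] == "unassigned"


def test_all_markers_missing_is_an_error():
    u = pd.DataFrame({"C0": [1.0], "C1": [0.0]}, index=["geneX"])
    res = SoftClusterResult(
        centroids=np.zeros((2, 1)), memberships=u, iterations=1, objective=0.0
    )
    with pytest.raises(ValueError, match="marker"):
        assign_stages(res, {"commitment": ["PAX6"]})


def test_stage_gene_counts_exact_on_clean_fixture():
    """30 XH genes planted in the commitment cluster count as exactly
    (commitment, XH) = 30; recount equals a brute-force filter."""
    z, truth = _stage_fixture(seed=3)
    res = fcm_cluster(z, FCMConfig(c=4, seed=3))
    stages = assign_stages(res)
    biotype_of_stage = {"pluripotency": "IG", "commitment": "XH",
                        "later": "XT"}
    ann = pd.DataFrame(index=res.memberships.index,
                       columns=["gene_class", "biotype", "partner_id"])
    planted = truth[truth["stage"].notna()].set_index("gene_id")
    for g, row in planted.iterrows():
        ann.loc[g, "biotype"] = biotype_of_stage[row["stage"]]
    counts = stage_gene_counts(res, stages, ann)
    # markers carry a biotype here too, hence 30 genes + stage markers
    assert counts.loc["commitment", "XH"] == 32
    assert counts.loc["pluripotency", "IG"] == 34
    assert counts.loc["later", "XT"] == 36

    # brute-force recount from the membership matrix
    u = res.memberships.to_numpy()
    argmax = u.argmax(axis=1)
    brute = 0
    for i, g in enumerate(res.memberships.index):
        if (
            stages.mapping[argmax[i]] == "commitment"
            and u[i, argmax[i]] >= 0.5
            and ann.loc[g, "biotype"] == "XH"
        ):
            brute += 1
    assert brute == counts.loc["commitment", "XH"]


def test_empty_stage_counts_zero():
    u = pd.DataFrame({"C0": [0.9], "C1": [0.1]}, index=["PAX6"])
    res = SoftClusterResult(
        centroids=np.zeros((2, 1)), memberships=u, iterations=1, objective=0.0
    )
    stages = StageAssignment(
        mapping={0: "commitment", 1: "later"}, evidence=pd.DataFrame()
    )
    ann = pd.DataFrame({"gene_class": ["unannotated"], "biotype": [np.nan],
                        "partner_id": [np.nan]}, index=["PAX6"])
    counts = stage_gene_counts(res, stages, ann)
    assert (counts.to_numpy() == 0).all()
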
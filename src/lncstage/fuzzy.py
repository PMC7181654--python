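"""Fuzzy c-means clustering of temporal profiles and marker-based stage calls.

Soft clustering assigns each gene a membership mu_ij in [0,1] to every
cluster j, controlled by the fuzzifier m (default 1.25, close to hard
clustering).  Clusters are mapped to developmental stages (pluripotency /
neuronal commitment / later development) through the mean membership of
stage marker genes; a cluster whose best marker mean falls below the
min.acore threshold (default 0.5) stays unassigned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

logger = logging.getLogger(__name__)

STAGES = ("pluripotency", "commitment", "later")
UNASSIGNED = "unassigned"

#: legacy marker symbols used in the literature, normalized at load time
MARKER_ALIASES = {
    "POU5F": "POU5F1",
    "OCT4": "POU5F1",
    "TDGF": "TDGF1",
    "CTIP2": "BCL11B",
}

#: stage marker panels: pluripotency (day 0), neuronal commitment (day 7),
#: later development (day 26 onward)
DEFAULT_STAGE_MARKERS: dict[str, tuple[str, ...]] = {
    "pluripotency": ("POU5F1", "NANOG", "NODAL", "TDGF1"),
    "commitment": ("PAX6", "SOX1"),
    "later": ("EMX2", "TBR1", "BCL11B", "CACNA1E", "PRSS12", "CARTPT"),
}


@dataclass(frozen=True)
class FCMConfig:
    c: int
    m: float = 1.25
    min_acore: float = 0.5
    tol: float = 1e-6
    max_iter: int = 1000
    seed: int = 0
    n_init: int = 5

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if not 0 < self.min_acore <= 1:
            raise ValueError("min_acore must be in (0, 1]")
        if self.c < 2:
            raise ValueError("need at least 2 clusters")


@dataclass
class SoftClusterResult:
    centroids: np.ndarray
    memberships: pd.DataFrame
    iterations: int
    objective: float
    objective_history: list[float] = field(default_factory=list)
    #: max |row-sum - 1| of the membership matrix at each iteration
    rowsum_dev: list[float] = field(default_factory=list)

    def hard_labels(self) -> pd.Series:
        """Argmax cluster per gene (ties: lowest cluster index)."""
        return pd.Series(
            np.argmax(self.memberships.to_numpy(), axis=1),
            index=self.memberships.index,
            name="cluster",
        )


def _memberships(d2: np.ndarray, m: float) -> np.ndarray:
    """FCM membership update: mu_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1)).

    A point coincident with one or more centroids splits membership 1
    equally among the zero-distance centroids.
    """
    zero = d2 <= 0
    u = np.zeros_like(d2)
    any_zero = zero.any(axis=1)
    if any_zero.any():
        z = zero[any_zero]
        u[any_zero] = z / z.sum(axis=1, keepdims=True)
    ok = ~any_zero
    if ok.any():
        inv = d2[ok] ** (-1.0 / (m - 1.0))
        u[ok] = inv / inv.sum(axis=1, keepdims=True)
    return u


def _fcm_once(
    x: np.ndarray, c: int, m: float, tol: float, max_iter: int, rs: int
) -> tuple[np.ndarray, np.ndarray, int, list[float], list[float]]:
    centroids, _ = kmeans_plusplus(x, n_clusters=c, random_state=rs)
    history: list[float] = []
    rowsum_dev: list[float] = []
    u = np.empty((x.shape[0], c))
    for it in range(1, max_iter + 1):
        d2 = cdist(x, centroids, metric="sqeuclidean")
        u = _memberships(d2, m)
        history.append(float(np.sum(u**m * d2)))
        rowsum_dev.append(float(np.abs(u.sum(axis=1) - 1.0).max()))
        um = u**m
        new_centroids = (um.T @ x) / um.sum(axis=0)[:, None]
        shift = np.max(np.abs(new_centroids - centroids))
        centroids = new_centroids
        if shift < tol:
            break
    return centroids, u, it, history, rowsum_dev


def fcm_cluster(z: pd.DataFrame, cfg: FCMConfig) -> SoftClusterResult:
    """Fuzzy c-means on a standardized gene x timepoint matrix.

    Alternates the textbook membership and centroid updates from k-means++
    seeded centroids until the maximal centroid shift drops below ``tol``.
    ``n_init`` independent restarts (seeds derived from ``cfg.seed``) are
    run and the solution with the lowest final objective is kept, so the
    result is deterministic given the config.
    """
    x = z.to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("input matrix must be finite")
    if cfg.c > x.shape[0]:
        raise ValueError(f"c={cfg.c} exceeds the number of genes {x.shape[0]}")
    best: tuple | None = None
    for r in range(max(1, cfg.n_init)):
        out = _fcm_once(x, cfg.c, cfg.m, cfg.tol, cfg.max_iter, cfg.seed + r)
        if best is None or out[3][-1] < best[3][-1]:
            best = out
    centroids, u, iterations, history, rowsum_dev = best
    memberships = pd.DataFrame(
        u, index=z.index, columns=[f"C{j}" for j in range(cfg.c)]
    )
    return SoftClusterResult(
        centroids=centroids,
        memberships=memberships,
        iterations=iterations,
        objective=history[-1],
        objective_history=history,
        rowsum_dev=rowsum_dev,
    )


def normalize_marker_ids(ids: Sequence[str]) -> list[str]:
    return [MARKER_ALIASES.get(i, i) for i in ids]


@dataclass
class StageAssignment:
    """Cluster -> stage mapping plus the marker mean-membership evidence."""

    mapping: dict[int, str]
    evidence: pd.DataFrame  # clusters x stages, mean marker membership


def assign_stages(
    res: SoftClusterResult,
    markers: Mapping[str, Sequence[str]] | None = None,
    min_acore: float = 0.5,
) -> StageAssignment:
    """Label clusters with the stage whose markers have the highest mean
    membership, requiring that mean to reach ``min_acore``.

    Markers absent from the clustered matrix are logged and ignored; it is
    an error for *all* markers to be missing.  A tie between stages leaves
    the cluster unassigned with a warning.
    """
    markers = markers or DEFAULT_STAGE_MARKERS
    u = res.memberships
    present: dict[str, list[str]] = {}
    n_found = 0
    for stage, ids in markers.items():
        ids = normalize_marker_ids(list(ids))
        found = [i for i in ids if i in u.index]
        missing = sorted(set(ids) - set(found))
        if missing:
            logger.warning("stage %s: markers absent from matrix: %s", stage, missing)
        present[stage] = found
        n_found += len(found)
    if n_found == 0:
        raise ValueError("no stage marker found in the clustered matrix")

    evidence = pd.DataFrame(
        {
            stage: (
                u.loc[ids].mean(axis=0)
                if ids
                else pd.Series(0.0, index=u.columns)
            )
            for stage, ids in present.items()
        }
    )
    mapping: dict[int, str] = {}
    for j, cluster in enumerate(evidence.index):
        row = evidence.loc[cluster]
        top = row.max()
        if top < min_acore:
            mapping[j] = UNASSIGNED
            continue
        winners = row.index[row == top]
        if len(winners) > 1:
            logger.warning(
                "cluster %s ties between stages %s: unassigned",
                cluster,
                list(winners),
            )
            mapping[j] = UNASSIGNED
        else:
            mapping[j] = str(winners[0])
    return StageAssignment(mapping=mapping, evidence=evidence)


def stage_gene_counts(
    res: SoftClusterResult,
    stages: StageAssignment,
    annotations: pd.DataFrame,
    min_acore: float = 0.5,
) -> pd.DataFrame:
    """Count genes per (stage, biotype).

    A gene counts toward at most one stage: the stage of its argmax
    cluster, and only when that membership reaches ``min_acore`` and the
    gene carries an association biotype.
    """
    from .annotation import BIOTYPES

    u = res.memberships.to_numpy()
    argmax = np.argmax(u, axis=1)
    top = u[np.arange(len(u)), argmax]
    stage_names = [s for s in stages.mapping.values() if s != UNASSIGNED]
    counts = pd.DataFrame(
        0,
        index=sorted(set(stage_names)) or [UNASSIGNED],
        columns=list(BIOTYPES),
    )
    biotypes = annotations["biotype"].reindex(res.memberships.index)
    for i, gene in enumerate(res.memberships.index):
        stage = stages.mapping.get(int(argmax[i]), UNASSIGNED)
        b = biotypes.iloc[i]
        if stage == UNASSIGNED or top[i] < min_acore or not isinstance(b, str):
            continue
        counts.loc[stage, b] += 1
    counts.index.name = "stage"
    return counts


def read_markers(path: str | Path) -> dict[str, list[str]]:
    """Read a markers TSV with columns (stage, gene_id)."""
    df = pd.read_csv(path, sep="\t")
    return {
        stage: normalize_marker_ids(list(sub["gene_id"]))
        for stage, sub in df.groupby("stage", sort=False)
    }


def write_markers(markers: Mapping[str, Sequence[str]], path: str | Path) -> None:
    rows = [
        {"stage": stage, "gene_id": g}
        for stage, ids in markers.items()
        for g in ids
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
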
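"""Unsigned weighted co-expression network: soft-threshold adjacency,
topological overlap, hierarchical module detection, per-biotype counts.

The adjacency is ``a_ij = |cor_ij| ** beta`` (signed variant available);
the topological overlap matrix (TOM) folds in shared-neighbour structure:

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),  i != j

with unit diagonal.  Modules are average-linkage clusters of the 1 - TOM
dissimilarity under a static tree cut.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

logger = logging.getLogger(__name__)

#: default soft power for the 8-timepoint analyses; few-sample unsigned
#: networks conventionally use a higher power than the classic 6
DEFAULT_BETA = 10


def pearson_correlation(z: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Gene x gene Pearson correlation; rows with zero variance give 0."""
    x = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x)
    corr = np.nan_to_num(corr, nan=0.0)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


def adjacency_matrix(
    corr: np.ndarray, beta: float, signed: bool = False
) -> np.ndarray:
    """Soft-threshold adjacency in [0,1]; unsigned |r|^beta by default."""
    if signed:
        a = ((1.0 + corr) / 2.0) ** beta
    else:
        a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(adjacency: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log10 p(k) vs log10 k linear fit on binned connectivity."""
    a = adjacency.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    if np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    dk, pk = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        mean_k = k[mask].mean()
        if mean_k <= 0:
            continue
        dk.append(mean_k)
        pk.append(mask.sum() / len(k))
    if len(dk) < 3:
        return 0.0
    fit = linregress(np.log10(dk), np.log10(pk))
    return float(fit.rvalue**2)


def select_soft_power(
    corr: np.ndarray,
    candidates: Sequence[int] = tuple(range(1, 21)),
    target_r2: float = 0.8,
    signed: bool = False,
) -> tuple[int, dict[int, float]]:
    """Smallest candidate power whose scale-free fit R^2 reaches
    ``target_r2``; falls back (with a warning) to the best-fitting power."""
    if corr.shape[0] < 20:
        raise ValueError("scale-free fit needs at least 20 genes")
    fits = {
        int(p): scale_free_fit(adjacency_matrix(corr, p, signed))
        for p in candidates
    }
    for p in sorted(fits):
        if fits[p] >= target_r2:
            return p, fits
    best = max(sorted(fits), key=lambda p: fits[p])
    logger.warning(
        "no candidate power reaches R^2 >= %.2f; using best power %d (R^2=%.3f)",
        target_r2,
        best,
        fits[best],
    )
    return best, fits


def tom_from_adjacency(a: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric adjacency in [0,1]."""
    a = np.asarray(a, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    off = a.copy()
    np.fill_diagonal(off, 0.0)
    k = off.sum(axis=0)
    shared = off @ off
    numerator = shared + off
    denominator = np.minimum.outer(k, k) + 1.0 - off
    tom = numerator / denominator
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray,
    cut_height: float = 0.99,
    min_module_size: int = 10,
) -> np.ndarray:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Returns integer labels per gene; clusters smaller than
    ``min_module_size`` collapse to label 0 (unassigned/grey).  Remaining
    modules are renumbered 1..K by decreasing size (ties by first member),
    so the labelling is invariant to gene order up to this canonical form.
    """
    n = tom.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    clusters = []
    for lab in np.unique(raw):
        members = np.where(raw == lab)[0]
        if len(members) >= min_module_size:
            clusters.append(members)
    clusters.sort(key=lambda m: (-len(m), int(m[0])))
    for new, members in enumerate(clusters, start=1):
        labels[members] = new
    return labels


def count_modules_by_biotype(
    labels: Sequence[int],
    biotypes: Sequence[str],
    min_module_size: int = 10,
) -> dict[str, int]:
    """Number of modules containing >= min_module_size genes of each
    biotype (label 0 never counts)."""
    labels = np.asarray(labels)
    biotypes = np.asarray(biotypes, dtype=object)
    out: dict[str, int] = {}
    uniq_b = [b for b in pd.unique(biotypes) if isinstance(b, str)]
    for b in uniq_b:
        count = 0
        for lab in np.unique(labels):
            if lab == 0:
                continue
            if int(((labels == lab) & (biotypes == b)).sum()) >= min_module_size:
                count += 1
        out[b] = count
    return out


def stratified_module_counts(
    z: pd.DataFrame,
    strata: Mapping[str, Sequence[str]],
    beta: float = DEFAULT_BETA,
    cut_height: float = 0.99,
    min_module_size: int = 10,
    signed: bool = False,
) -> tuple[dict[str, int], dict[str, pd.Series]]:
    """Detect co-expression modules separately within each biotype stratum.

    ``strata`` maps biotype -> associated gene ids; genes missing from the
    standardized matrix are skipped.  Returns per-biotype module counts and
    the per-gene module labels of each stratum.
    """
    counts: dict[str, int] = {}
    labels: dict[str, pd.Series] = {}
    for biotype, ids in strata.items():
        present = [g for g in ids if g in z.index]
        if len(present) < 2:
            counts[biotype] = 0
            labels[biotype] = pd.Series(dtype=int)
            continue
        sub = z.loc[present]
        corr = pearson_correlation(sub)
        adj = adjacency_matrix(corr, beta, signed)
        tom = tom_from_adjacency(adj)
        lab = detect_modules(tom, cut_height, min_module_size)
        counts[biotype] = int(len(set(lab) - {0}))
        labels[biotype] = pd.Series(lab, index=present, name="module")
    return counts, labels
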
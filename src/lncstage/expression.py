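"""Temporal expression matrix loading, filtering and standardization.

The expression unit is RPKM over an ordered series of differentiation
timepoints (by default the 8-day corticogenesis series D0..D77).  Genes are
annotated with their class (protein_coding / lncRNA / unannotated) and,
where applicable, the positional biotype of the lncRNA they are associated
with: a genic lncRNA's *associated gene* is its partner coding gene, an
intergenic lncRNA is its own associated gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import BIOTYPES, BiotypeAssignment, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_TIMEPOINTS = ("D0", "D7", "D12", "D19", "D26", "D49", "D63", "D77")

UNANNOTATED = "unannotated"


@dataclass
class ExpressionMatrix:
    """Gene x timepoint RPKM values plus per-gene annotation.

    ``data`` is a DataFrame indexed by gene id with timepoint columns;
    ``annotations`` is indexed by gene id with columns ``gene_class``,
    ``biotype`` (the association biotype, NaN where not applicable) and
    ``partner_id``.
    """

    data: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        values = self.data.to_numpy()
        if not np.isfinite(values).all():
            raise ValueError("expression values must be finite")
        if (values < 0).any():
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative RPKM at gene {self.data.index[i]!r}, "
                f"timepoint {self.data.columns[j]!r}"
            )
        self.annotations = self.annotations.reindex(self.data.index)
        self.annotations["gene_class"] = self.annotations["gene_class"].fillna(
            UNANNOTATED
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.data.columns)


def annotation_table(
    genes: Sequence[GeneModel],
    assignments: Sequence[BiotypeAssignment],
) -> pd.DataFrame:
    """Build the per-gene annotation table from classifier output.

    Association biotypes are attached to partner coding genes (genic
    biotypes) and to intergenic lncRNAs themselves; genic lncRNA rows keep
    their gene class but carry no association biotype, so downstream
    biotype-stratified analyses operate on one associated gene per lncRNA.
    """
    rows = {
        g.gene_id: {
            "gene_class": g.gene_class,
            "biotype": np.nan,
            "partner_id": np.nan,
        }
        for g in genes
    }
    for a in assignments:
        if a.biotype == "IG":
            rows[a.lnc_id]["biotype"] = "IG"
        elif a.partner_id is not None and a.biotype in BIOTYPES:
            partner = rows.setdefault(
                a.partner_id,
                {"gene_class": UNANNOTATED, "biotype": np.nan, "partner_id": np.nan},
            )
            if isinstance(partner["biotype"], str) and partner["biotype"] != a.biotype:
                logger.warning(
                    "%s partners lncRNAs of different biotypes (%s kept)",
                    a.partner_id,
                    partner["biotype"],
                )
            else:
                partner["biotype"] = a.biotype
                partner["partner_id"] = a.lnc_id
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df


def associated_gene_sets(annotations: pd.DataFrame) -> dict[str, list[str]]:
    """Biotype -> ordered list of associated gene ids."""
    with_biotype = annotations.dropna(subset=["biotype"])
    return {
        b: list(with_biotype.index[with_biotype["biotype"] == b])
        for b in BIOTYPES
        if (with_biotype["biotype"] == b).any()
    }


def load_matrix(
    path: str | Path, annotations: pd.DataFrame | None = None
) -> ExpressionMatrix:
    """Load a gene x timepoint RPKM TSV (gene ids in the first column).

    Genes absent from the annotation table are carried with class
    ``unannotated``; row order is preserved.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    non_numeric = df.columns[
        [not pd.api.types.is_numeric_dtype(df[c]) for c in df.columns]
    ]
    for col in non_numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value at gene {bad[0]!r}, timepoint {col!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"missing value in row {gene!r}")
    if annotations is None:
        annotations = pd.DataFrame(
            index=df.index,
            columns=["gene_class", "biotype", "partner_id"],
        )
    return ExpressionMatrix(data=df, annotations=annotations.copy())


def filter_expressed(
    m: ExpressionMatrix,
    threshold: float = 1.0,
    min_timepoints: int = 1,
) -> ExpressionMatrix:
    """Keep genes reaching ``threshold`` RPKM in >= ``min_timepoints``
    columns; idempotent and order-preserving."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    keep = (m.data >= threshold).sum(axis=1) >= min_timepoints
    if not keep.any():
        logger.warning("no gene passes the expression filter")
    return ExpressionMatrix(
        data=m.data.loc[keep].copy(), annotations=m.annotations.loc[keep].copy()
    )


def fraction_expressed_by_biotype(
    m: ExpressionMatrix,
    threshold: float = 1.0,
    min_timepoints: int = 1,
) -> pd.Series:
    """Per biotype, the fraction of partner coding genes passing the
    expression filter (the Fig-1a-style summary).

    Only *partner coding genes* enter the denominator, so biotypes without
    partners (IG, or any biotype absent from the data) report NaN.
    """
    expressed = set(
        filter_expressed(m, threshold, min_timepoints).data.index
    )
    ann = m.annotations
    out: dict[str, float] = {}
    for b in BIOTYPES:
        partners = ann.index[
            (ann["biotype"] == b) & (ann["gene_class"] == "protein_coding")
        ]
        out[b] = (
            np.nan
            if len(partners) == 0
            else sum(g in expressed for g in partners) / len(partners)
        )
    return pd.Series(out, name="fraction_expressed")


def standardize_time(
    m: ExpressionMatrix | pd.DataFrame, log_transform: bool = True
) -> pd.DataFrame:
    """Time-based standardization: each gene row to mean 0, SD 1.

    RPKM rows are log2(x+1)-transformed first (``log_transform``), then
    z-scored with the population (n) denominator.  Constant rows map to
    all-zeros with a logged warning.  Returns a plain DataFrame because the
    result is no longer an RPKM matrix.
    """
    data = m.data if isinstance(m, ExpressionMatrix) else m
    if data.shape[1] < 2:
        raise ValueError("standardization needs at least 2 timepoints")
    x = data.to_numpy(dtype=float)
    if log_transform:
        x = np.log2(x + 1.0)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning(
            "%d constant row(s) mapped to all-zeros", int(constant.sum())
        )
    sd[constant] = 1.0
    z = (x - mean) / sd
    z[constant] = 0.0
    return pd.DataFrame(z, index=data.index, columns=data.columns)
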
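"""Gene-annotation parsing and positional lncRNA biotype classification.

Long noncoding RNA genes are labelled by their genomic geometry relative to
the nearest protein-coding gene.  The seven-label scheme distinguishes
"genic" lncRNAs (within 5 kb of a coding gene) from intergenic ones:

====== ==========================================================
label  geometry (lncRNA vs. its partner coding gene)
====== ==========================================================
XH     divergent / antisense head-to-head (5' ends face or overlap)
XT     convergent / antisense tail-to-tail (3' ends face or overlap)
XO     antisense, lncRNA fully contains the coding gene body
XI     antisense, lncRNA fully inside the coding gene body
SD     same strand, downstream of the coding gene's 3' end
SU     same strand, upstream of the coding gene's 5' end
IG     intergenic: no coding gene within the genic window
====== ==========================================================

Same-strand *overlap* falls outside the scheme and is reported explicitly
as ``unclassified_sense_overlap`` rather than being silently binned.

All geometry is evaluated on gene bodies (exon structure is ignored) in
0-based half-open coordinates; conversion from GTF happens at the I/O
boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: ordered tuple of the seven positional biotype labels
BIOTYPES = ("XH", "XT", "XO", "XI", "SD", "SU", "IG")

#: outcome for same-strand overlapping pairs (outside the seven-label scheme)
UNCLASSIFIED_SENSE_OVERLAP = "unclassified_sense_overlap"

#: default genic window in bp; distance <= window counts as genic
GENIC_WINDOW = 5000

PROTEIN_CODING = "protein_coding"
LNCRNA = "lncRNA"


class AnnotationError(ValueError):
    """Raised for malformed annotation records or invalid geometry queries."""


@dataclass(frozen=True)
class GeneModel:
    """One gene: strand, body coordinates, exon structure and class.

    Coordinates are 0-based half-open; ``start < end`` always holds and
    exons are non-overlapping, sorted and contained in the gene body.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...] = ()
    gene_class: str = PROTEIN_CODING

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.start < self.end:
            raise AnnotationError(f"{self.gene_id}: start must be < end")
        prev_end = self.start
        for s, e in self.exons:
            if s < prev_end or e > self.end or s >= e:
                raise AnnotationError(
                    f"{self.gene_id}: exons must be sorted, non-overlapping "
                    f"and within the gene body"
                )
            prev_end = e

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Base coordinate of the 5' end (first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        """Base coordinate of the 3' end (last transcribed base)."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class BiotypeAssignment:
    """Biotype label for one lncRNA plus the supporting geometry evidence."""

    lnc_id: str
    biotype: str
    partner_id: str | None
    distance_bp: int
    overlap_bp: int
    five_prime_overlap: bool = False
    ambiguous_ends: bool = False


def overlap_and_distance(a: GeneModel, b: GeneModel) -> tuple[int, int]:
    """Gene-body overlap and gap between two genes on the same chromosome.

    Returns ``(overlap_bp, distance_bp)``; exactly symmetric in its
    arguments.  Touching half-open intervals ([0,100) vs [100,200)) have
    overlap 0 and distance 0.
    """
    if a.chrom != b.chrom:
        raise AnnotationError(
            f"{a.gene_id} and {b.gene_id} are on different chromosomes"
        )
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    overlap = max(0, hi - lo)
    distance = max(0, lo - hi)
    return overlap, distance


def pair_partner(
    lnc: GeneModel,
    candidates: Sequence[GeneModel],
    genic_window: int = GENIC_WINDOW,
) -> GeneModel | None:
    """Select the partner coding gene for an lncRNA.

    Priority: (1) maximal gene-body overlap; (2) among non-overlapping
    candidates, minimal gene-body distance within ``genic_window``;
    ties broken by lexicographically smallest ``gene_id``.  Returns
    ``None`` when nothing overlaps or lies within the window.
    """
    same_chrom = [c for c in candidates if c.chrom == lnc.chrom]
    scored = [(c, *overlap_and_distance(lnc, c)) for c in same_chrom]
    overlapping = [(c, ov) for c, ov, _ in scored if ov > 0]
    if overlapping:
        return min(overlapping, key=lambda t: (-t[1], t[0].gene_id))[0]
    nearby = [(c, d) for c, ov, d in scored if d <= genic_window]
    if nearby:
        return min(nearby, key=lambda t: (t[1], t[0].gene_id))[0]
    return None


def _ends_in_overlap(g: GeneModel, lo: int, hi: int) -> tuple[bool, bool]:
    """Whether g's 5' / 3' base coordinates fall inside [lo, hi)."""
    return (lo <= g.five_prime < hi), (lo <= g.three_prime < hi)


def classify_biotype(
    lnc: GeneModel,
    coding_genes: Sequence[GeneModel],
    genic_window: int = GENIC_WINDOW,
) -> BiotypeAssignment:
    """Classify one lncRNA against an indexed collection of coding genes.

    The function is total: every lncRNA receives exactly one of the seven
    biotype labels or the explicit ``unclassified_sense_overlap`` outcome.
    The label depends only on gene-body geometry and strands, never on
    exon structure.
    """
    candidates = [
        c
        for c in coding_genes
        if c.chrom == lnc.chrom and c.gene_class == PROTEIN_CODING
    ]
    partner = pair_partner(lnc, candidates, genic_window)
    if partner is None:
        if candidates:
            nearest = min(
                overlap_and_distance(lnc, c)[1] for c in candidates
            )
        else:
            # no coding gene on the chromosome at all: report the minimal
            # distance consistent with the intergenic call
            nearest = genic_window + 1
        return BiotypeAssignment(
            lnc_id=lnc.gene_id,
            biotype="IG",
            partner_id=None,
            distance_bp=nearest,
            overlap_bp=0,
        )

    overlap, distance = overlap_and_distance(lnc, partner)
    opposite = lnc.strand != partner.strand

    if overlap > 0:
        lo = max(lnc.start, partner.start)
        hi = min(lnc.end, partner.end)
        if not opposite:
            return BiotypeAssignment(
                lnc_id=lnc.gene_id,
                biotype=UNCLASSIFIED_SENSE_OVERLAP,
                partner_id=partner.gene_id,
                distance_bp=0,
                overlap_bp=overlap,
            )
        if partner.start <= lnc.start and lnc.end <= partner.end:
            label, ambiguous, five = "XI", False, False
        elif lnc.start <= partner.start and partner.end <= lnc.end:
            label, ambiguous, five = "XO", False, False
        else:
            lnc5, lnc3 = _ends_in_overlap(lnc, lo, hi)
            par5, par3 = _ends_in_overlap(partner, lo, hi)
            if lnc5 and par5:
                label, ambiguous = "XH", False
            elif lnc3 and par3:
                label, ambiguous = "XT", False
            else:
                # mixed-end partial overlap: unreachable for interval gene
                # bodies on opposite strands, kept as a flagged fallback
                label = "XH" if lnc5 else "XT"
                ambiguous = True
                logger.warning(
                    "%s/%s: ambiguous_ends overlap resolved as %s",
                    lnc.gene_id,
                    partner.gene_id,
                    label,
                )
            five = lnc5 and par5
        return BiotypeAssignment(
            lnc_id=lnc.gene_id,
            biotype=label,
            partner_id=partner.gene_id,
            distance_bp=0,
            overlap_bp=overlap,
            five_prime_overlap=five,
            ambiguous_ends=ambiguous,
        )

    # non-overlapping partner within the genic window
    if opposite:
        left, right = (
            (lnc, partner) if lnc.start <= partner.start else (partner, lnc)
        )
        # facing ends of opposite-strand bodies are both 5' or both 3'
        left_end_is_5p = left.strand == "-"
        label = "XH" if left_end_is_5p else "XT"
    else:
        # lnc downstream of the coding gene's 3' end -> SD, upstream -> SU
        if partner.strand == "+":
            label = "SD" if lnc.start >= partner.end else "SU"
        else:
            label = "SD" if lnc.end <= partner.start else "SU"
    return BiotypeAssignment(
        lnc_id=lnc.gene_id,
        biotype=label,
        partner_id=partner.gene_id,
        distance_bp=distance,
        overlap_bp=0,
    )


def classify_all(
    genes: Iterable[GeneModel], genic_window: int = GENIC_WINDOW
) -> list[BiotypeAssignment]:
    """Classify every lncRNA gene against all protein-coding genes."""
    genes = list(genes)
    coding = [g for g in genes if g.gene_class == PROTEIN_CODING]
    return [
        classify_biotype(g, coding, genic_window)
        for g in genes
        if g.gene_class == LNCRNA
    ]


def assignments_to_frame(
    assignments: Sequence[BiotypeAssignment],
) -> pd.DataFrame:
    """Tabulate assignments as the TSV-ready report frame."""
    return pd.DataFrame(
        [
            {
                "lnc_id": a.lnc_id,
                "biotype": a.biotype,
                "partner_id": a.partner_id if a.partner_id is not None else "",
                "distance_bp": a.distance_bp,
                "overlap_bp": a.overlap_bp,
                "five_prime_overlap": a.five_prime_overlap,
                "ambiguous_ends": a.ambiguous_ends,
            }
            for a in assignments
        ]
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_BED12_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "thick_start",
    "thick_end",
    "item_rgb",
    "block_count",
    "block_sizes",
    "block_starts",
]


def read_annotation(
    path: str | Path,
    class_map: Mapping[str, str] | None = None,
) -> list[GeneModel]:
    """Read gene models from a GTF (1-based inclusive) or BED12 file.

    Gene class comes from the ``gene_biotype`` attribute (GTF) or from
    ``class_map`` (required for BED12, optional override for GTF).  Genes
    with unknown class or missing strand are skipped with a logged warning.
    """
    path = Path(path)
    if path.suffix.lower() in (".bed", ".bed12"):
        return _read_bed12(path, class_map)
    return _read_gtf(path, class_map)


def _resolve_class(raw: str | None) -> str | None:
    if raw is None:
        return None
    raw = raw.lower()
    if raw in ("protein_coding", "coding"):
        return PROTEIN_CODING
    if raw in ("lncrna", "lincrna", "noncoding", "lnc_rna"):
        return LNCRNA
    return None


def _read_gtf(
    path: Path, class_map: Mapping[str, str] | None
) -> list[GeneModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises a mix of error types
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc

    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by="start"):
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        if feat.strand not in ("+", "-"):
            logger.warning("%s: missing strand, record rejected", gene_id)
            continue
        raw_class = None
        if class_map and gene_id in class_map:
            raw_class = class_map[gene_id]
        else:
            vals = feat.attributes.get("gene_biotype") or feat.attributes.get(
                "gene_type"
            )
            raw_class = vals[0] if vals else None
        gene_class = _resolve_class(raw_class)
        if gene_class is None:
            logger.warning(
                "%s: unknown gene class %r, gene excluded", gene_id, raw_class
            )
            continue
        start, end = feat.start - 1, feat.end
        exons = sorted(
            (e.start - 1, e.end)
            for e in db.children(feat, featuretype="exon")
        )
        if not exons:
            logger.warning(
                "%s: no exon records, using gene body as single exon", gene_id
            )
            exons = [(start, end)]
        else:
            exons = _merge_blocks(exons)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=start,
                end=end,
                exons=tuple(exons),
                gene_class=gene_class,
            )
        )
    return genes


def _merge_blocks(blocks: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of sorted, possibly overlapping exon blocks (multi-transcript
    genes collapse to the gene-body union)."""
    merged: list[tuple[int, int]] = []
    for s, e in blocks:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _read_bed12(
    path: Path, class_map: Mapping[str, str] | None
) -> list[GeneModel]:
    if class_map is None:
        raise AnnotationError("BED12 input requires a gene class map")
    df = pd.read_csv(
        path, sep="\t", header=None, names=_BED12_COLUMNS, comment="#"
    )
    genes: list[GeneModel] = []
    for i, row in df.iterrows():
        name = str(row["name"])
        if row["strand"] not in ("+", "-"):
            logger.warning("%s: missing strand, record rejected", name)
            continue
        gene_class = _resolve_class(class_map.get(name))
        if gene_class is None:
            logger.warning("%s: unknown gene class, gene excluded", name)
            continue
        try:
            start, end = int(row["start"]), int(row["end"])
            sizes = [int(x) for x in str(row["block_sizes"]).strip(",").split(",")]
            offsets = [
                int(x) for x in str(row["block_starts"]).strip(",").split(",")
            ]
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"{path}, line {i + 1}: malformed record") from exc
        exons = tuple(
            (start + off, start + off + size)
            for off, size in zip(offsets, sizes)
        )
        genes.append(
            GeneModel(
                gene_id=name,
                chrom=str(row["chrom"]),
                strand=row["strand"],
                start=start,
                end=end,
                exons=exons,
                gene_class=gene_class,
            )
        )
    return genes


def write_biotype_table(
    assignments: Sequence[BiotypeAssignment], path: str | Path
) -> None:
    assignments_to_frame(assignments).to_csv(path, sep="\t", index=False)
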
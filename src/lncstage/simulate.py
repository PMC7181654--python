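"""Synthetic-data generators with known ground truth.

Every downstream stage of the analysis is testable without the original
corticogenesis RNA-seq series: this module fabricates (a) a single-
chromosome annotation realizing each positional biotype at controlled
geometries, (b) an 8-timepoint RPKM matrix with planted stage-specific and
module-forming co-expression groups anchored to marker genes, (c)
replicate-rich sample matrices with planted hub / chain / independent
network topologies (mutual-information estimation is unreliable on 8
timepoints, so network fixtures carry >= 30 samples), and (d) coding vs.
noncoding nucleotide sequences with planted open reading frames and codon
bias.

All generators are deterministic given their seed, and every emitted
gene / sequence appears exactly once in the corresponding truth table.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, LNCRNA, PROTEIN_CODING

CHROM = "chrS"
#: spacing between consecutive gene pairs; rules out cross-pair proximity
PAIR_SPACER = 10_500

GENIC_LABELS = ("XH", "XT", "XO", "XI", "SD", "SU")
ALL_LABELS = GENIC_LABELS + ("IG",)

DEFAULT_TIMEPOINTS = ("D0", "D7", "D12", "D19", "D26", "D49", "D63", "D77")

#: non-uniform codon usage for planted coding sequences; the compositional
#: asymmetry it induces is what position-based coding statistics detect
CODON_WEIGHTS: dict[str, float] = {
    "GCC": 4, "GAG": 4, "AAG": 4, "CTG": 4, "CAG": 4,
    "GAC": 3, "ATC": 3, "GTG": 3, "GGC": 3, "AAC": 2,
    "TTC": 2, "TAC": 2, "ACC": 2, "TCC": 2, "CCC": 2,
    "CGC": 2, "AGC": 2, "CAC": 2, "ATG": 1, "TGG": 1,
}
_STOPS = ("TAA", "TAG", "TGA")


class GeometryError(ValueError):
    """Raised when a requested geometry cannot realize its biotype."""


@dataclass(frozen=True)
class GeometrySpec:
    """One lncRNA / coding-gene pair at a controlled genomic geometry.

    Exactly one of ``gap_bp`` / ``overlap_bp`` is nonzero.  For XI the
    lncRNA length is the overlap (containment), for XO the coding length
    is; ``strand_lnc`` is derived from the label unless given.
    """

    biotype_label: str
    gap_bp: int = 0
    overlap_bp: int = 0
    coding_len_bp: int = 2000
    lnc_len_bp: int = 1000
    strand_coding: str = "+"
    strand_lnc: str | None = None

    def __post_init__(self) -> None:
        if self.biotype_label not in ALL_LABELS:
            raise GeometryError(f"unknown biotype label {self.biotype_label!r}")
        if self.gap_bp < 0 or self.overlap_bp < 0:
            raise GeometryError("gap_bp and overlap_bp must be >= 0")
        if (self.gap_bp > 0) == (self.overlap_bp > 0):
            raise GeometryError(
                "exactly one of gap_bp/overlap_bp must be nonzero"
            )
        if self.coding_len_bp <= 0 or self.lnc_len_bp <= 0:
            raise GeometryError("gene lengths must be positive")
        if self.strand_coding not in ("+", "-"):
            raise GeometryError("strand_coding must be '+' or '-'")


def _validate_realizable(spec: GeometrySpec, genic_window: int = 5000) -> None:
    lab, g, v = spec.biotype_label, spec.gap_bp, spec.overlap_bp
    cl, ll = spec.coding_len_bp, spec.lnc_len_bp
    if lab == "IG":
        if g <= genic_window:
            raise GeometryError("IG requires gap_bp > 5000")
    elif lab in ("SD", "SU"):
        if v > 0 or g > genic_window:
            raise GeometryError(f"{lab} requires 0 < gap_bp <= {genic_window}")
    elif lab in ("XH", "XT"):
        if g > genic_window:
            raise GeometryError(f"{lab} requires gap_bp <= {genic_window}")
        if v > 0 and v >= min(cl, ll):
            raise GeometryError(
                f"{lab} overlap must be partial (< both gene lengths)"
            )
    elif lab == "XI":
        if g > 0 or not 1 <= v <= cl - 2:
            raise GeometryError("XI requires 1 <= overlap_bp <= coding_len-2")
    elif lab == "XO":
        if g > 0 or not 1 <= v <= ll - 2:
            raise GeometryError("XO requires 1 <= overlap_bp <= lnc_len-2")


def _base_layout(
    spec: GeometrySpec,
) -> tuple[tuple[int, int, str], tuple[int, int, str]]:
    """Local (start, end, strand) for the coding gene and the lncRNA,
    assuming strand_coding '+'."""
    lab, g, v = spec.biotype_label, spec.gap_bp, spec.overlap_bp
    cl, ll = spec.coding_len_bp, spec.lnc_len_bp
    if lab == "XH":
        if v:
            return (ll - v, ll - v + cl, "+"), (0, ll, "-")
        return (ll + g, ll + g + cl, "+"), (0, ll, "-")
    if lab == "XT":
        if v:
            return (0, cl, "+"), (cl - v, cl - v + ll, "-")
        return (0, cl, "+"), (cl + g, cl + g + ll, "-")
    if lab == "XI":
        return (0, cl, "+"), (1, 1 + v, "-")
    if lab == "XO":
        return (1, 1 + v, "+"), (0, ll, "-")
    if lab == "SD":
        return (0, cl, "+"), (cl + g, cl + g + ll, "+")
    if lab == "SU":
        return (ll + g, ll + g + cl, "+"), (0, ll, "+")
    # IG
    strand_lnc = spec.strand_lnc or "+"
    return (0, cl, "+"), (cl + g, cl + g + ll, strand_lnc)


def realize_geometry(
    spec: GeometrySpec,
) -> tuple[tuple[int, int, str], tuple[int, int, str]]:
    """Local coordinates realizing the requested geometry; mirrored when
    ``strand_coding`` is '-', so both orientations are covered."""
    _validate_realizable(spec)
    coding, lnc = _base_layout(spec)
    if spec.strand_coding == "-":
        width = max(coding[1], lnc[1])

        def mirror(iv: tuple[int, int, str]) -> tuple[int, int, str]:
            s, e, st = iv
            return (width - e, width - s, "-" if st == "+" else "+")

        coding, lnc = mirror(coding), mirror(lnc)
    return coding, lnc


def _exon_split(
    start: int, end: int, rng: np.random.Generator
) -> tuple[tuple[int, int], ...]:
    """1-3 exons inside the gene body; geometry-irrelevant decoration."""
    length = end - start
    n = int(rng.integers(1, 4)) if length >= 400 else 1
    if n == 1:
        return ((start, end),)
    cuts = sorted(int(c) for c in rng.integers(50, length - 50, size=2 * (n - 1)))
    if any(b - a < 20 for a, b in zip(cuts, cuts[1:])):
        return ((start, end),)  # degenerate draw: keep a single exon
    bounds = [start] + [start + c for c in cuts] + [end]
    return tuple(
        (bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)
    )


def generate_annotation(
    specs: Sequence[GeometrySpec],
    chrom_len: int | None = None,
    seed: int = 0,
    ids: Sequence[tuple[str, str]] | None = None,
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Place lncRNA/coding pairs left-to-right on a synthetic chromosome.

    Returns the gene models and a truth table covering every generated
    lncRNA (``lnc_id``, ``biotype``, ``coding_id``, ``partner_id`` — empty
    for IG — and the realized overlap/gap).  Raises ``GeometryError`` if a
    provided ``chrom_len`` cannot hold all pairs.
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    rows = []
    cursor = 1000
    for i, spec in enumerate(specs):
        coding_iv, lnc_iv = realize_geometry(spec)
        cid, lid = (
            ids[i] if ids is not None else (f"CG{i:04d}", f"LNC{i:04d}")
        )
        cs, ce, cstrand = coding_iv
        ls, le, lstrand = lnc_iv
        genes.append(
            GeneModel(
                gene_id=cid,
                chrom=CHROM,
                strand=cstrand,
                start=cursor + cs,
                end=cursor + ce,
                exons=_exon_split(cursor + cs, cursor + ce, rng),
                gene_class=PROTEIN_CODING,
            )
        )
        genes.append(
            GeneModel(
                gene_id=lid,
                chrom=CHROM,
                strand=lstrand,
                start=cursor + ls,
                end=cursor + le,
                exons=_exon_split(cursor + ls, cursor + le, rng),
                gene_class=LNCRNA,
            )
        )
        rows.append(
            {
                "lnc_id": lid,
                "biotype": spec.biotype_label,
                "coding_id": cid,
                "partner_id": "" if spec.biotype_label == "IG" else cid,
                "overlap_bp": spec.overlap_bp,
                "gap_bp": spec.gap_bp,
                "strand_coding": spec.strand_coding,
            }
        )
        cursor += max(ce, le) + PAIR_SPACER
    if chrom_len is not None and cursor > chrom_len:
        raise GeometryError(
            f"chromosome of {chrom_len} bp too short: need {cursor} bp"
        )
    truth = pd.DataFrame(rows)
    assert truth["lnc_id"].is_unique
    return genes, truth


def write_gtf(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene/transcript/exon GTF records (1-based inclusive)."""
    lines = []
    for g in genes:
        attrs = (
            f'gene_id "{g.gene_id}"; gene_biotype "{g.gene_class}";'
        )
        tattrs = (
            f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
            f'gene_biotype "{g.gene_class}";'
        )
        for feature, (s, e), a in (
            ("gene", (g.start, g.end), attrs),
            ("transcript", (g.start, g.end), tattrs),
        ):
            lines.append(
                f"{g.chrom}\tlncstage\t{feature}\t{s + 1}\t{e}\t.\t"
                f"{g.strand}\t.\t{a}"
            )
        for s, e in g.exons:
            lines.append(
                f"{g.chrom}\tlncstage\texon\t{s + 1}\t{e}\t.\t"
                f"{g.strand}\t.\t{tattrs}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedClusterSpec:
    """A planted co-expression group: a mean log2-RPKM trajectory shared by
    its genes, with i.i.d. Gaussian noise on the log scale.

    ``stage`` is a developmental-stage label for marker-anchored groups
    (pluripotency / commitment / later) or ``None`` for plain module
    groups; ``marker_ids`` are extra genes forced into the group.
    """

    profile: tuple[float, ...]
    noise_sd: float
    stage: str | None = None
    n_genes: int = 0
    gene_ids: tuple[str, ...] = ()
    marker_ids: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_expression(
    gene_ids: Sequence[str],
    clusters: Sequence[PlantedClusterSpec],
    timepoints: Sequence[str] | None = None,
    seed: int = 0,
    background_log2: float = 1.0,
    background_noise_sd: float = 0.4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """RPKM matrix with planted clusters; RPKM = 2 ** (profile + noise).

    Each gene belongs to exactly one cluster (explicit ``gene_ids``, or the
    next unclaimed genes for specs using ``n_genes``) or to the flat
    low-mean background.  Returns (matrix, cluster truth table).
    """
    timepoints = list(timepoints or DEFAULT_TIMEPOINTS)
    gene_ids = list(gene_ids)
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError("duplicate gene ids in pool")
    rng = np.random.default_rng(seed)
    claimed: dict[str, tuple[int, PlantedClusterSpec]] = {}
    unclaimed = [g for g in gene_ids]
    for ci, spec in enumerate(clusters):
        if len(spec.profile) != len(timepoints):
            raise ValueError(
                f"cluster {ci}: profile length {len(spec.profile)} != "
                f"{len(timepoints)} timepoints"
            )
        members = list(spec.gene_ids)
        if not members and spec.n_genes:
            members = unclaimed[: spec.n_genes]
        members += [m for m in spec.marker_ids]
        for m in members:
            if m in claimed:
                raise ValueError(f"gene {m!r} claimed by two clusters")
            claimed[m] = (ci, spec)
        unclaimed = [g for g in unclaimed if g not in claimed]
    all_ids = gene_ids + [
        m
        for spec in clusters
        for m in spec.marker_ids
        if m not in gene_ids
    ]
    rows = np.empty((len(all_ids), len(timepoints)))
    truth_rows = []
    for i, g in enumerate(all_ids):
        if g in claimed:
            ci, spec = claimed[g]
            profile = np.asarray(spec.profile, dtype=float)
            sd = spec.noise_sd
            stage = spec.stage
        else:
            ci, stage = -1, None
            profile = np.full(len(timepoints), background_log2)
            sd = background_noise_sd
        log2 = profile + (rng.normal(0.0, sd, len(timepoints)) if sd else 0.0)
        rows[i] = 2.0**log2
        truth_rows.append({"gene_id": g, "cluster": ci, "stage": stage})
    matrix = pd.DataFrame(rows, index=all_ids, columns=timepoints)
    matrix.index.name = "gene_id"
    return matrix, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# network samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedNetworkSpec:
    """Replicate-rich sample matrix with a known dependency topology."""

    topology: str  # hub | chain | independent
    n_nodes: int
    n_samples: int = 200
    edge_strength: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.topology not in ("hub", "chain", "independent"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0 < self.edge_strength < 1:
            raise ValueError("edge_strength must be in (0, 1)")
        if self.n_samples < 30:
            raise ValueError("network fixtures need n_samples >= 30")


def generate_network_samples(
    spec: PlantedNetworkSpec,
    node_names: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Sample x gene matrix plus the planted truth edge list.

    hub: node 0 correlates (edge_strength) with every spoke and the spokes
    are conditionally independent given the hub; chain: first-order Markov
    chain; independent: i.i.d. standard normal columns.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, r = spec.n_samples, spec.n_nodes, spec.edge_strength
    names = (
        list(node_names)
        if node_names is not None
        else [f"N{i:02d}" for i in range(p)]
    )
    if len(names) != p:
        raise ValueError("node_names length must equal n_nodes")
    x = np.empty((n, p))
    edges: list[tuple[str, str]] = []
    if spec.topology == "independent":
        x = rng.standard_normal((n, p))
    elif spec.topology == "hub":
        hub = rng.standard_normal(n)
        x[:, 0] = hub
        for j in range(1, p):
            x[:, j] = r * hub + math.sqrt(1 - r**2) * rng.standard_normal(n)
            edges.append((names[0], names[j]))
    else:  # chain
        x[:, 0] = rng.standard_normal(n)
        for j in range(1, p):
            x[:, j] = r * x[:, j - 1] + math.sqrt(1 - r**2) * rng.standard_normal(n)
            edges.append((names[j - 1], names[j]))
    return pd.DataFrame(x, columns=names), edges


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------


def _random_codons(rng: np.random.Generator, n: int) -> str:
    codons = list(CODON_WEIGHTS)
    w = np.array([CODON_WEIGHTS[c] for c in codons], dtype=float)
    w /= w.sum()
    return "".join(rng.choice(codons, size=n, p=w))


def generate_sequences(
    n_coding: int,
    n_noncoding: int,
    length_bp: int = 1200,
    seed: int = 0,
    orf_frac: float = 0.8,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Planted-ORF coding sequences vs. uniform-random noncoding ones.

    Coding sequences carry an ATG..stop ORF spanning ``orf_frac`` of the
    length, with codons drawn from the biased usage table; noncoding
    sequences are uniform random.  Returns (records, label table).
    """
    if length_bp < 200:
        raise ValueError("length_bp must be >= 200")
    if not 0.6 <= orf_frac <= 0.95:
        raise ValueError("orf_frac should plant an ORF covering >= 60%")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    records: list[tuple[str, str]] = []
    rows = []

    def random_seq(n: int) -> str:
        return "".join(rng.choice(bases, size=n))

    for i in range(n_coding):
        orf_codons = max(2, int(length_bp * orf_frac) // 3 - 2)
        orf = "ATG" + _random_codons(rng, orf_codons) + str(rng.choice(_STOPS))
        lead = int(rng.integers(0, length_bp - len(orf) + 1))
        seq = random_seq(lead) + orf + random_seq(length_bp - lead - len(orf))
        tid = f"TXC{i:03d}"
        records.append((tid, seq))
        rows.append({"transcript_id": tid, "label": "coding"})
    for i in range(n_noncoding):
        tid = f"TXN{i:03d}"
        records.append((tid, random_seq(length_bp)))
        rows.append({"transcript_id": tid, "label": "noncoding"})
    return records, pd.DataFrame(rows)


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(s), id=i, description="") for i, s in records],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# the default synthetic study bundle
# ---------------------------------------------------------------------------

#: mean log2-RPKM trajectories over D0..D77; stage profiles peak at their
#: stage's timepoint, module profiles are mutually weakly correlated
BUNDLE_PROFILES: dict[str, tuple[float, ...]] = {
    "pluripotency": (6, 4, 2.5, 1.5, 1, 0.5, 0.5, 0.5),
    "commitment": (1, 6, 4, 2.5, 1.5, 1, 0.5, 0.5),
    "later": (0.5, 0.5, 1, 1.5, 2.5, 4, 5, 6),
    "modA": (0.5, 0.5, 2, 6, 2, 0.5, 0.5, 0.5),
    "modB": (5, 2, 0.5, 0.5, 0.5, 0.5, 2, 5),
    "modC": (4, 1, 4, 1, 4, 1, 4, 1),
    "modD": (0.5, 0.5, 1, 3, 6, 3, 1, 0.5),
    "flat": (1,) * 8,
    "silent": (-2,) * 8,
}

_STAGE_OF_PROFILE = {
    "pluripotency": "pluripotency",
    "commitment": "commitment",
    "later": "later",
}

#: per-biotype planted composition: (profile, n_genes) in assignment order.
#: Module-forming groups (>= 10 genes, structured profile) yield the
#: planted stratified module counts XH=4, IG=3, XI=2, SD=2, SU=0, XO=0.
BUNDLE_DESIGN: dict[str, tuple[tuple[str, int], ...]] = {
    "XH": (("commitment", 30), ("modA", 12), ("modB", 12), ("modC", 12),
           ("flat", 1), ("silent", 5)),
    "IG": (("pluripotency", 30), ("modD", 12), ("modC", 12), ("flat", 6)),
    "XI": (("pluripotency", 15), ("modA", 12), ("flat", 1), ("silent", 4)),
    "SD": (("modA", 12), ("modD", 12), ("flat", 1), ("silent", 5)),
    "SU": (("flat", 9), ("silent", 3)),
    "XO": (("flat", 9), ("silent", 3)),
    "XT": (("later", 30), ("silent", 4)),
}

BUNDLE_MODULE_COUNTS = {"XH": 4, "IG": 3, "XI": 2, "SD": 2, "SU": 0, "XO": 0}
BUNDLE_STAGE_COUNTS = {
    "commitment": {"XH": 30},
    "pluripotency": {"IG": 30, "XI": 15},
    "later": {"XT": 30},
}

STAGE_MARKER_IDS = {
    "pluripotency": ("POU5F1", "NANOG", "NODAL", "TDGF1"),
    "commitment": ("PAX6", "SOX1"),
    "later": ("EMX2", "TBR1", "BCL11B", "CACNA1E", "PRSS12", "CARTPT"),
}

_GEOMETRY_CYCLES: dict[str, tuple[dict, ...]] = {
    # the first XH geometry is the divergent 599-bp 5' overlap
    "XH": ({"overlap_bp": 599}, {"overlap_bp": 120}, {"gap_bp": 400},
            {"overlap_bp": 350}, {"gap_bp": 1500}, {"gap_bp": 3000}),
    "XT": ({"overlap_bp": 250}, {"gap_bp": 800}, {"overlap_bp": 90},
            {"gap_bp": 2200}),
    "XO": ({"overlap_bp": 300}, {"overlap_bp": 500}, {"overlap_bp": 700}),
    "XI": ({"overlap_bp": 300}, {"overlap_bp": 600}, {"overlap_bp": 900}),
    "SD": ({"gap_bp": 200}, {"gap_bp": 1000}, {"gap_bp": 2500},
            {"gap_bp": 4800}),
    "SU": ({"gap_bp": 150}, {"gap_bp": 900}, {"gap_bp": 3500}),
    "IG": ({"gap_bp": 5200}, {"gap_bp": 6000}, {"gap_bp": 7500},
            {"gap_bp": 9000}),
}

_NET_SAMPLES = 300
_NET_STRENGTH = 0.95
BUNDLE_MULTIEDGE = {
    "XH": {"t0": 3, "t1": 7},
    "IG": {"t0": 7, "t1": 2},
    "XI": {"t0": 6, "t1": 2},
}


def _bundle_specs() -> tuple[list[GeometrySpec], list[tuple[str, str]]]:
    specs: list[GeometrySpec] = []
    ids: list[tuple[str, str]] = []
    for biotype, groups in BUNDLE_DESIGN.items():
        total = sum(n for _, n in groups)
        cycle = _GEOMETRY_CYCLES[biotype]
        for i in range(total):
            geo = cycle[i % len(cycle)]
            specs.append(
                GeometrySpec(
                    biotype_label=biotype,
                    strand_coding="+" if i % 2 == 0 else "-",
                    **geo,
                )
            )
            ids.append((f"CG_{biotype}{i:03d}", f"LNC_{biotype}{i:03d}"))
    return specs, ids


def _associated_ids(truth: pd.DataFrame) -> dict[str, list[str]]:
    """biotype -> associated gene ids (coding partner, or the lncRNA for IG)."""
    out: dict[str, list[str]] = {}
    for _, row in truth.iterrows():
        gene = row["partner_id"] or row["lnc_id"]
        out.setdefault(row["biotype"], []).append(gene)
    return out


def _triad_frame(
    pool: Sequence[str],
    n_triads: int,
    n_samples: int,
    strength: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[str]]:
    """Disjoint 3-gene Markov chains over a gene pool; remaining genes are
    independent.  Returns the sample matrix and the triad middle genes."""
    x = rng.standard_normal((n_samples, len(pool)))
    middles = []
    for t in range(n_triads):
        a, b, c = 3 * t, 3 * t + 1, 3 * t + 2
        x[:, b] = strength * x[:, a] + math.sqrt(1 - strength**2) * x[:, b]
        x[:, c] = strength * x[:, b] + math.sqrt(1 - strength**2) * x[:, c]
        middles.append(pool[b])
    return pd.DataFrame(x, columns=list(pool)), middles


def simulate_bundle(outdir: str | Path, seed: int = 0) -> dict:
    """Write the default synthetic study bundle and return its manifest.

    The bundle emulates the study conditions end to end: annotation with
    realized biotype geometries, the 8-timepoint RPKM matrix with planted
    stage clusters (marker-anchored) and per-biotype module groups, the
    target gene set concentrated in XH-associated genes, per-biotype
    network sample matrices for two stages (D0/D7 analogues) with planted
    chain connectivity changes, a hub fixture whose hub is an
    XH-commitment gene (the divergent-pair analogue), and a 25+25
    coding/noncoding transcript set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    specs, ids = _bundle_specs()
    genes, truth = generate_annotation(specs, seed=seed, ids=ids)
    write_gtf(genes, outdir / "annotation.gtf")
    truth.to_csv(outdir / "biotype_truth.tsv", sep="\t", index=False)

    assoc = _associated_ids(truth)
    lnc_of = {  # associated coding gene -> its lncRNA (genic pairs only)
        row["partner_id"]: row["lnc_id"]
        for _, row in truth.iterrows()
        if row["partner_id"]
    }

    # planted expression groups: pool genes per (biotype, profile) in order
    group_members: dict[str, list[str]] = {}
    for biotype, groups in BUNDLE_DESIGN.items():
        pos = 0
        for profile, n in groups:
            members = assoc[biotype][pos : pos + n]
            group_members.setdefault(profile, []).extend(members)
            pos += n

    clusters: list[PlantedClusterSpec] = []
    for profile, members in group_members.items():
        stage = _STAGE_OF_PROFILE.get(profile)
        markers = STAGE_MARKER_IDS.get(stage, ()) if stage else ()
        if profile == "flat":
            continue  # flat genes fall through to the background model
        clusters.append(
            PlantedClusterSpec(
                profile=BUNDLE_PROFILES[profile],
                noise_sd=0.15,
                stage=stage,
                gene_ids=tuple(members),
                marker_ids=tuple(markers),
                name=profile,
            )
        )
        # genic lncRNAs mirror their partner's trajectory with extra noise
        mirrors = tuple(lnc_of[g] for g in members if g in lnc_of)
        if mirrors:
            clusters.append(
                PlantedClusterSpec(
                    profile=BUNDLE_PROFILES[profile],
                    noise_sd=0.35,
                    stage=None,
                    gene_ids=mirrors,
                    name=f"{profile}_lnc",
                )
            )
    all_gene_ids = [g.gene_id for g in genes]
    matrix, cluster_truth = generate_expression(
        all_gene_ids, clusters, seed=seed + 1
    )
    matrix.to_csv(outdir / "expression.tsv", sep="\t")
    cluster_truth["group"] = cluster_truth["cluster"].map(
        lambda ci: clusters[ci].name if ci >= 0 else "background"
    )
    cluster_truth.to_csv(outdir / "cluster_truth.tsv", sep="\t", index=False)

    from .fuzzy import write_markers

    write_markers(STAGE_MARKER_IDS, outdir / "markers.tsv")

    # target gene set: concentrated in XH commitment genes (enrichment
    # analogue of the neuronal-differentiation GO set)
    target = (
        group_members["commitment"][:6]
        + [g for g in group_members["pluripotency"] if g in assoc["XI"]][:2]
        + [g for g in group_members["modA"] if g in assoc["SD"]][:1]
    )
    (outdir / "target_genes.txt").write_text("\n".join(target) + "\n")

    # per-biotype network sample matrices for the two compared stages
    pools = {
        "XH": assoc["XH"][30:51],
        "IG": assoc["IG"][30:51],
        "XI": assoc["XI"][14:32],
    }
    net_paths: dict[str, dict[str, str]] = {}
    rng = np.random.default_rng(seed + 2)
    for biotype, pool in pools.items():
        net_paths[biotype] = {}
        for stage_key in ("t0", "t1"):
            frame, middles = _triad_frame(
                pool,
                BUNDLE_MULTIEDGE[biotype][stage_key],
                _NET_SAMPLES,
                _NET_STRENGTH,
                rng,
            )
            path = outdir / f"network_{biotype}_{stage_key}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            net_paths[biotype][stage_key] = str(path)

    # hub fixture: an XH commitment gene with 12 commitment spokes
    hub_pool = group_members["commitment"][:13]
    hub_frame, hub_edges = generate_network_samples(
        PlantedNetworkSpec(
            topology="hub",
            n_nodes=13,
            n_samples=_NET_SAMPLES,
            edge_strength=_NET_STRENGTH,
            seed=seed + 3,
        ),
        node_names=hub_pool,
    )
    hub_frame.to_csv(outdir / "network_hub.tsv", sep="\t", index=False)

    network_truth = {
        "hub": hub_pool[0],
        "hub_edges": hub_edges,
        "multiedge": BUNDLE_MULTIEDGE,
        "pools": pools,
    }
    (outdir / "network_truth.json").write_text(
        json.dumps(network_truth, indent=1, sort_keys=True)
    )

    records, labels = generate_sequences(25, 25, 1200, seed=seed + 4)
    write_fasta(records, outdir / "transcripts.fasta")
    labels.to_csv(outdir / "sequence_labels.tsv", sep="\t", index=False)

    manifest = {
        "annotation": str(outdir / "annotation.gtf"),
        "biotype_truth": str(outdir / "biotype_truth.tsv"),
        "expression": str(outdir / "expression.tsv"),
        "cluster_truth": str(outdir / "cluster_truth.tsv"),
        "markers": str(outdir / "markers.tsv"),
        "gene_set": str(outdir / "target_genes.txt"),
        "fasta": str(outdir / "transcripts.fasta"),
        "sequence_labels": str(outdir / "sequence_labels.tsv"),
        "networks": net_paths,
        "network_hub": str(outdir / "network_hub.tsv"),
        "network_truth": str(outdir / "network_truth.json"),
        "expected_module_counts": BUNDLE_MODULE_COUNTS,
        "expected_stage_counts": BUNDLE_STAGE_COUNTS,
        "expected_multiedge": BUNDLE_MULTIEDGE,
        "hub_gene": hub_pool[0],
        "seed": seed,
    }
    (outdir / "bundle.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
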
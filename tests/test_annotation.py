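"""Biotype classifier, partner pairing and annotation I/O."""

import pytest
from hypothesis import given, strategies as st

from lncstage.annotation import (
    GeneModel,
    UNCLASSIFIED_SENSE_OVERLAP,
    classify_biotype,
    overlap_and_distance,
    pair_partner,
    read_annotation,
)
from lncstage.simulate import GeometryError, GeometrySpec, generate_annotation


from geometry_oracle import geometry_grid, oracle_label


def test_classifier_matches_oracle_on_geometry_grid():
    """Exhaustive geometry grid: generator truth, classifier output and the
    independent per-base oracle agree on every placeable case."""
    placeable = 0
    for kw in geometry_grid():
        try:
            spec = GeometrySpec(**kw)
            genes, truth = generate_annotation([spec], seed=1)
        except GeometryError:
            continue
        placeable += 1
        cod = next(g for g in genes if g.gene_class == "protein_coding")
        lnc = next(g for g in genes if g.gene_class == "lncRNA")
        got = classify_biotype(lnc, [cod]).biotype
        assert got == truth["biotype"].iloc[0], kw
        assert got == oracle_label(lnc, cod), kw
    assert placeable >= 500


def test_divergent_599bp_head_to_head_overlap():
    """The divergent-pair geometry: opposite strands overlapping 599 bp at
    both 5' ends classifies as XH with the overlap recorded."""
    genes, _ = generate_annotation(
        [GeometrySpec("XH", overlap_bp=599, coding_len_bp=2000,
                      lnc_len_bp=3316)], seed=0
    )
    cod = next(g for g in genes if g.gene_class == "protein_coding")
    lnc = next(g for g in genes if g.gene_class == "lncRNA")
    a = classify_biotype(lnc, [cod])
    assert a.biotype == "XH"
    assert a.overlap_bp == 599
    assert a.distance_bp == 0
    assert a.five_prime_overlap
    assert lnc.strand != cod.strand


def test_genic_window_boundary():
    """Distance 5000 is genic (inclusive boundary); 5001 is intergenic."""
    cod = GeneModel("cod", "chr1", "+", 0, 1000)
    for gap, expected in ((5000, "SD"), (5001, "IG")):
        lnc = GeneModel("lnc", "chr1", "+", 1000 + gap, 2000 + gap,
                        gene_class="lncRNA")
        assert classify_biotype(lnc, [cod]).biotype == expected


def test_same_strand_overlap_is_explicit_outcome():
    cod = GeneModel("cod", "chr1", "+", 0, 1000)
    lnc = GeneModel("lnc", "chr1", "+", 500, 1500, gene_class="lncRNA")
    a = classify_biotype(lnc, [cod])
    assert a.biotype == UNCLASSIFIED_SENSE_OVERLAP
    assert a.partner_id == "cod"


def test_strand_flip_mirror_symmetry():
    """Flipping both strands and mirroring coordinates preserves labels."""
    span = 1_000_000
    for kw in geometry_grid()[::7]:
        try:
            genes, truth = generate_annotation([GeometrySpec(**kw)], seed=2)
        except GeometryError:
            continue
        mirrored = [
            GeneModel(
                gene_id=g.gene_id, chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                start=span - g.end, end=span - g.start,
                gene_class=g.gene_class,
            )
            for g in genes
        ]
        orig = {g.gene_class: g for g in genes}
        mirr = {g.gene_class: g for g in mirrored}
        assert (
            classify_biotype(mirr["lncRNA"], [mirr["protein_coding"]]).biotype
            == classify_biotype(orig["lncRNA"], [orig["protein_coding"]]).biotype
        )


def test_label_ignores_exon_structure():
    cod = GeneModel("cod", "chr1", "+", 0, 1000, exons=((0, 200), (800, 1000)))
    lnc_a = GeneModel("lnc", "chr1", "-", 500, 1500, gene_class="lncRNA")
    lnc_b = GeneModel("lnc", "chr1", "-", 500, 1500,
                      exons=((500, 600), (1400, 1500)), gene_class="lncRNA")
    assert (classify_biotype(lnc_a, [cod]).biotype
            == classify_biotype(lnc_b, [cod]).biotype == "XT")


@pytest.mark.parametrize(
    "candidates, expected",
    [
        # minimal distance wins among non-overlapping
        ([("a", 1100, 2100), ("b", 3000, 4000)], "a"),
        # overlap beats proximity
        ([("a", 950, 1950), ("b", 1010, 2010)], "a"),
        # equidistant ties break lexicographically
        ([("geneB", 1100, 2100), ("geneA", 0, 900 + 1)], "geneA"),
    ],
)
def test_pair_partner_priorities(candidates, expected):
    lnc = GeneModel("lnc", "chr1", "+", 901, 1001, gene_class="lncRNA")
    cands = [GeneModel(n, "chr1", "+", s, e) for n, s, e in candidates]
    assert pair_partner(lnc, cands).gene_id == expected


def test_overlap_and_distance_examples():
    a = GeneModel("a", "chr1", "+", 0, 100)
    assert overlap_and_distance(a, GeneModel("b", "chr1", "+", 50, 150)) == (50, 0)
    assert overlap_and_distance(a, GeneModel("c", "chr1", "+", 100, 200)) == (0, 0)
    with pytest.raises(Exception):
        overlap_and_distance(a, GeneModel("d", "chr2", "+", 0, 100))


@given(
    st.integers(0, 300), st.integers(1, 100),
    st.integers(0, 300), st.integers(1, 100),
)
def test_overlap_distance_against_per_base_oracle(s1, l1, s2, l2):
    a = GeneModel("a", "chr1", "+", s1, s1 + l1)
    b = GeneModel("b", "chr1", "-", s2, s2 + l2)
    ov, d = overlap_and_distance(a, b)
    assert ov == overlap_and_distance(b, a)[0]
    base_a = set(range(s1, s1 + l1))
    base_b = set(range(s2, s2 + l2))
    assert ov == len(base_a & base_b)
    if ov == 0:
        assert d == min(abs(x - y) for x in (s1, s1 + l1 - 1)
                        for y in (s2, s2 + l2 - 1)) - 1 or d == 0
    else:
        assert d == 0


def test_gtf_coordinate_conversion(tmp_path):
    """A GTF gene at 1-based [101, 200] becomes the half-open (100, 200)."""
    gtf = tmp_path / "one.gtf"
    gtf.write_text(
        'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1"; '
        'gene_biotype "protein_coding";\n'
        'chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1"; '
        'transcript_id "g1.t"; gene_biotype "protein_coding";\n'
    )
    (g,) = read_annotation(gtf)
    assert (g.start, g.end, g.length) == (100, 200, 100)
    assert g.exons == ((100, 150),)


def test_exonless_gene_gets_body_exon(tmp_path, caplog):
    gtf = tmp_path / "noexon.gtf"
    gtf.write_text(
        'chr1\tsrc\tgene\t1\t300\t.\t-\t.\tgene_id "g2"; '
        'gene_biotype "lncRNA";\n'
    )
    with caplog.at_level("WARNING", logger="lncstage.annotation"):
        (g,) = read_annotation(gtf)
    assert g.exons == ((0, 300),)
    assert any("no exon" in r.message for r in caplog.records)


def test_bundle_gtf_round_trip(bundle):
    """Re-parsing the generated GTF recovers every gene's coordinates."""
    from lncstage.simulate import _bundle_specs, generate_annotation

    specs, ids = _bundle_specs()
    genes, truth = generate_annotation(specs, seed=0, ids=ids)
    parsed = {g.gene_id: g for g in read_annotation(bundle["annotation"])}
    assert len(parsed) == len(genes)
    for g in genes:
        p = parsed[g.gene_id]
        assert (p.chrom, p.strand, p.start, p.end, p.gene_class) == (
            g.chrom, g.strand, g.start, g.end, g.gene_class
        )
        assert p.exons == g.exons
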
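"""Independent rule-table oracle for positional biotype labels.

Uses per-base coordinate sets and 5'/3' base distances, structurally
unlike the interval logic in the implementation, plus the exhaustive
geometry grid both the unit and acceptance suites classify against.
"""

import itertools

from lncstage.annotation import GeneModel, UNCLASSIFIED_SENSE_OVERLAP


def oracle_label(lnc: GeneModel, cod: GeneModel, window: int = 5000) -> str:
    L = set(range(lnc.start, lnc.end))
    C = set(range(cod.start, cod.end))
    lnc5 = lnc.start if lnc.strand == "+" else lnc.end - 1
    lnc3 = lnc.end - 1 if lnc.strand == "+" else lnc.start
    cod5 = cod.start if cod.strand == "+" else cod.end - 1
    cod3 = cod.end - 1 if cod.strand == "+" else cod.start
    if L & C:
        if lnc.strand == cod.strand:
            return UNCLASSIFIED_SENSE_OVERLAP
        if L <= C:
            return "XI"
        if C <= L:
            return "XO"
        return "XH" if abs(lnc5 - cod5) < abs(lnc3 - cod3) else "XT"
    gap = min(abs(a - b) for a in (lnc.start, lnc.end - 1)
              for b in (cod.start, cod.end - 1)) - 1
    if gap > window:
        return "IG"
    if lnc.strand != cod.strand:
        return "XH" if abs(lnc5 - cod5) < abs(lnc3 - cod3) else "XT"
    # same strand: downstream of the coding 3' end -> SD, else SU
    after = lnc.start > cod.start
    return ("SD" if after else "SU") if cod.strand == "+" else (
        "SU" if after else "SD"
    )


def geometry_grid():
    overlaps = [1, 2, 5, 10, 50, 100, 250, 400, 599, 750, 900, 999]
    gaps = [1, 2, 10, 100, 1000, 2500, 4000, 4999, 5000, 5001, 5500, 6000,
            7500, 10000]
    sizes = [(2000, 1000), (1500, 800), (3000, 600)]
    cases = []
    for label in ("XH", "XT", "XO", "XI", "SD", "SU", "IG"):
        for (cl, ll), strand in itertools.product(sizes, "+-"):
            for v in overlaps:
                cases.append(dict(biotype_label=label, overlap_bp=v,
                                  coding_len_bp=cl, lnc_len_bp=ll,
                                  strand_coding=strand))
            for g in gaps:
                cases.append(dict(biotype_label=label, gap_bp=g,
                                  coding_len_bp=cl, lnc_len_bp=ll,
                                  strand_coding=strand))
    return cases


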
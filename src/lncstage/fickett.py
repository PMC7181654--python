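"""Coding-potential scoring: Fickett TESTCODE statistic and ORF coverage.

The TESTCODE statistic (Fickett, Nucleic Acids Res. 1982) combines eight
parameters of a nucleotide sequence: for each base, a *position* value
measuring codon-position asymmetry (max over the three frames of the
per-frame count, divided by the min + 1) and a *composition* value (the
base fraction).  Each parameter is mapped through the published lookup
tables to a probability-of-coding and the eight probabilities are combined
as a weighted sum.  Scores range roughly 0.2-1.2; the classic TESTCODE
bounds call < 0.74 noncoding and > 0.95 coding.

ORF coverage is the length of the longest ATG..stop open reading frame
(stop included) over the transcript length, scanned on the forward strand
in all three frames (transcripts are stranded; a reverse-strand scan is
available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

_STOPS = ("TAA", "TAG", "TGA")

# Lookup tables transcribed from Fickett (1982), Tables 1 and 2, as used by
# the classic TESTCODE program: for each base, probability-of-coding per
# parameter bin plus the weight of that parameter.
_POSITION_PROB = {
    "A": (0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22),
    "C": (0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23),
    "G": (0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08),
    "T": (0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09),
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_POSITION_BINS = (1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0)

_CONTENT_PROB = {
    "A": (0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21),
    "C": (0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31),
    "G": (0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29),
    "T": (0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58),
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_CONTENT_BINS = (0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0)

VERDICT_CODING = "coding"
VERDICT_NONCODING = "noncoding"
VERDICT_INDETERMINATE = "indeterminate"

#: classic TESTCODE "coding" bound; configurable in classify_transcript
DEFAULT_FICKETT_CUTOFF = 0.74
DEFAULT_COVERAGE_CUTOFF = 0.5


@dataclass(frozen=True)
class FickettReport:
    transcript_id: str
    fickett_score: float
    orf_coverage: float
    longest_orf_bp: int
    verdict: str


def _lookup(value: float, bins: Sequence[float], probs: Sequence[float]) -> float:
    for i, b in enumerate(bins):
        if value >= b:
            return probs[i]
    return probs[-1]


def _clean(seq: str) -> str:
    """Uppercase and drop Ns; the statistic is invariant to case and to
    where Ns occurred."""
    return seq.upper().replace("N", "")


def fickett_score(seq: str) -> float:
    """TESTCODE statistic of a nucleotide sequence (>= 200 nt, ACGTN)."""
    raw = seq.upper()
    if len(raw) < 200:
        raise ValueError("sequence shorter than 200 nt")
    bad = sum(1 for c in raw if c not in "ACGTN")
    if bad > 0.1 * len(raw):
        raise ValueError("more than 10% of bases outside the ACGTN alphabet")
    s = "".join(c for c in raw if c in "ACGT")
    n = len(s)
    score = 0.0
    for base in "ACGT":
        frame_counts = [
            sum(1 for i in range(f, n, 3) if s[i] == base) for f in range(3)
        ]
        position_value = max(frame_counts) / (min(frame_counts) + 1.0)
        content_value = sum(frame_counts) / n if n else 0.0
        score += _POSITION_WEIGHT[base] * _lookup(
            position_value, _POSITION_BINS, _POSITION_PROB[base]
        )
        score += _CONTENT_WEIGHT[base] * _lookup(
            content_value, _CONTENT_BINS, _CONTENT_PROB[base]
        )
    return score


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def orf_coverage(
    seq: str, open_ended: bool = False, scan_reverse: bool = False
) -> tuple[float, int]:
    """Longest ATG..stop ORF over all three forward frames.

    Returns ``(coverage, longest_orf_bp)`` where coverage is the ORF
    length (stop codon included) over the sequence length.  ``open_ended``
    also counts an unterminated ORF to the last full codon;
    ``scan_reverse`` additionally scans the reverse complement.
    """
    s = seq.upper()
    if len(s) == 0:
        raise ValueError("empty sequence")
    if len(s) < 3:
        return 0.0, 0
    strands = [s] + ([_revcomp(s)] if scan_reverse else [])
    longest = 0
    for strand in strands:
        for frame in range(3):
            start: int | None = None
            last_full = frame + 3 * ((len(strand) - frame) // 3)
            for p in range(frame, last_full, 3):
                codon = strand[p : p + 3]
                if start is None:
                    if codon == "ATG":
                        start = p
                elif codon in _STOPS:
                    longest = max(longest, p + 3 - start)
                    start = None
            if open_ended and start is not None:
                longest = max(longest, last_full - start)
    return longest / len(s), longest


def classify_transcript(
    fickett: float,
    coverage: float,
    fickett_cutoff: float = DEFAULT_FICKETT_CUTOFF,
    coverage_cutoff: float = DEFAULT_COVERAGE_CUTOFF,
) -> str:
    """coding iff both scores reach their cutoffs, noncoding iff both are
    below, indeterminate otherwise (monotone in both scores)."""
    f_ok = fickett >= fickett_cutoff
    c_ok = coverage >= coverage_cutoff
    if f_ok and c_ok:
        return VERDICT_CODING
    if not f_ok and not c_ok:
        return VERDICT_NONCODING
    return VERDICT_INDETERMINATE


def score_transcripts(
    records: Iterable[tuple[str, str]] | str | Path,
    fickett_cutoff: float = DEFAULT_FICKETT_CUTOFF,
    coverage_cutoff: float = DEFAULT_COVERAGE_CUTOFF,
) -> pd.DataFrame:
    """Score transcripts from (id, sequence) pairs or a FASTA path."""
    if isinstance(records, (str, Path)):
        from Bio import SeqIO

        records = [
            (r.id, str(r.seq)) for r in SeqIO.parse(str(records), "fasta")
        ]
    rows = []
    for tid, seq in records:
        score = fickett_score(seq)
        cov, orf = orf_coverage(seq)
        rows.append(
            {
                "transcript_id": tid,
                "fickett_score": score,
                "orf_coverage": cov,
                "longest_orf_bp": orf,
                "verdict": classify_transcript(
                    score, cov, fickett_cutoff, coverage_cutoff
                ),
            }
        )
    return pd.DataFrame(rows)
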
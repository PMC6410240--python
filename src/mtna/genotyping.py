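"""Dual-reference, junction-overlap genotyping of a presence/absence indel.

Each line's short reads are aligned against two small references — the
deletion allele (upstream + downstream flank joined at a junction) and the
non-deletion allele (same flanks with the indel sequence between them).
Because the references are tiny (~90/139 bp), mapping is an exhaustive
ungapped overlap alignment over every offset and both strands, which is
exact and deterministic. A read is *informative* only if it spans the
junction (or the whole indel interval) with a minimum number of aligned
bases on each side, matches well enough, and strictly prefers one allele.
A line is called for an allele when at least a majority-threshold fraction
(default 95%) of its informative reads support it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

DELETION = "deletion"
NON_DELETION = "non_deletion"
UNINFORMATIVE = "uninformative"

DEFAULT_MIN_OVERLAP = 15  # bp on each side of the junction, for >=100 bp reads
SHORT_READ_MIN_OVERLAP = 8  # relaxed setting for 45-126 bp read cohorts
DEFAULT_MAJORITY_THRESHOLD = 0.95
DEFAULT_MAX_MISMATCH_RATE = 0.1
DEFAULT_MISMATCH_PENALTY = 1.0

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lower case


def encode_seq(seq: str) -> np.ndarray:
    """Encode DNA as uint8 codes (A,C,G,T -> 0..3; anything else -> 4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    out = codes[::-1].copy()
    acgt = out < 4
    out[acgt] = 3 - out[acgt]
    return out


def revcomp(seq: str) -> str:
    table = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return seq.translate(table)[::-1]


@dataclass(frozen=True)
class AlleleReference:
    """One allele of the indel with its junction coordinates (0-based).

    For the deletion allele ``junction`` is the inter-base position between
    the upstream and downstream flanks; for the non-deletion allele
    ``interval`` is the half-open [start, end) span of the inserted bases.
    """

    allele_id: str
    sequence: str
    junction: int | None = None
    interval: tuple[int, int] | None = None

    def __post_init__(self):
        if self.allele_id not in (DELETION, NON_DELETION):
            raise ValueError(f"unknown allele_id {self.allele_id!r}")
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"non-DNA characters in reference: {sorted(bad)}")
        if self.allele_id == DELETION:
            if self.junction is None or not 0 <= self.junction <= len(self.sequence):
                raise ValueError("deletion allele needs a junction inside the sequence")
        else:
            if self.interval is None:
                raise ValueError("non-deletion allele needs an indel interval")
            s, e = self.interval
            if not 0 <= s < e <= len(self.sequence):
                raise ValueError("indel interval outside the sequence")

    @property
    def codes(self) -> np.ndarray:
        return encode_seq(self.sequence)


@dataclass(frozen=True)
class Placement:
    """Best ungapped placement of a read on a reference."""

    offset: int  # read start in reference coordinates (may be negative)
    strand: int  # +1 forward, -1 reverse complement
    matches: int
    mismatches: int
    score: float


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    best_allele: str  # deletion / non_deletion / uninformative
    score_del: float
    score_non: float
    overlap_left: int
    overlap_right: int


@dataclass(frozen=True)
class LineGenotypeCall:
    line_id: str
    n_del_reads: int
    n_non_reads: int
    call: str  # deletion / non_deletion / ambiguous / no_data
    major_fraction: float
    min_overlap: int
    majority_threshold: float


def _scan_one_strand(
    read_codes: np.ndarray, ref_codes: np.ndarray, penalty: float
) -> tuple[int, int, int, float]:
    """Best placement of one read orientation; ties -> smallest offset."""
    lr = len(read_codes)
    lref = len(ref_codes)
    padded = np.full(lref + 2 * (lr - 1), 255, dtype=np.uint8)
    padded[lr - 1 : lr - 1 + lref] = ref_codes
    windows = sliding_window_view(padded, lr)  # one window per offset
    matches = (windows == read_codes).sum(axis=1)
    offsets = np.arange(-(lr - 1), lref)
    overlap = np.minimum(lref, offsets + lr) - np.maximum(0, offsets)
    mismatches = overlap - matches
    scores = matches - penalty * mismatches
    best = int(np.argmax(scores))  # first max = smallest offset
    return (
        int(offsets[best]),
        int(matches[best]),
        int(mismatches[best]),
        float(scores[best]),
    )


def align_read(
    read: str,
    ref: AlleleReference | str,
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
) -> Placement:
    """Exhaustive ungapped alignment of a read against a short reference.

    Scans every offset (overhangs allowed) of the read and of its reverse
    complement; the score over the overlapping span is
    ``matches - mismatch_penalty * mismatches``. Deterministic tie-break:
    smallest offset, forward strand preferred on equal scores.
    """
    if len(read) == 0:
        raise ValueError("empty read")
    ref_codes = ref.codes if isinstance(ref, AlleleReference) else encode_seq(ref)
    fwd = encode_seq(read)
    o_f, m_f, x_f, s_f = _scan_one_strand(fwd, ref_codes, mismatch_penalty)
    o_r, m_r, x_r, s_r = _scan_one_strand(
        _revcomp_codes(fwd), ref_codes, mismatch_penalty
    )
    if s_r > s_f:
        return Placement(o_r, -1, m_r, x_r, s_r)
    return Placement(o_f, +1, m_f, x_f, s_f)


def _junction_overlaps(
    placement: Placement, read_len: int, ref: AlleleReference
) -> tuple[int, int, int, int]:
    """Aligned span and junction edges on the reference (all 0-based)."""
    span_start = max(0, placement.offset)
    span_end = min(len(ref.sequence), placement.offset + read_len)
    if ref.allele_id == DELETION:
        left_edge = right_edge = ref.junction
    else:
        left_edge, right_edge = ref.interval
    return span_start, span_end, left_edge, right_edge


def classify_read(
    read: str,
    refs: tuple[AlleleReference, AlleleReference],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    read_id: str = "",
    mismatch_penalty: float = DEFAULT_MISMATCH_PENALTY,
) -> ReadAssignment:
    """Assign a read to an allele, or declare it uninformative.

    The candidate allele is the higher-scoring reference; the read counts
    as evidence only if its aligned span extends at least ``min_overlap``
    bases on each side of the junction (deletion allele) or of the indel
    interval (non-deletion allele), its mismatch rate is at most
    ``max_mismatch_rate``, and the two allele scores differ (equal-score
    reads carry no information about the indel).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    by_id = {r.allele_id: r for r in refs}
    if set(by_id) != {DELETION, NON_DELETION}:
        raise ValueError("refs must be one deletion and one non_deletion allele")
    placements = {aid: align_read(read, r, mismatch_penalty) for aid, r in by_id.items()}
    score_del = placements[DELETION].score
    score_non = placements[NON_DELETION].score
    if score_del == score_non:
        return ReadAssignment(read_id, UNINFORMATIVE, score_del, score_non, 0, 0)
    winner = DELETION if score_del > score_non else NON_DELETION
    pl = placements[winner]
    ref = by_id[winner]
    span_start, span_end, left_edge, right_edge = _junction_overlaps(
        pl, len(read), ref
    )
    left = left_edge - span_start
    right = span_end - right_edge
    aligned = pl.matches + pl.mismatches
    rate = pl.mismatches / aligned if aligned else 1.0
    if left >= min_overlap and right >= min_overlap and rate <= max_mismatch_rate:
        return ReadAssignment(read_id, winner, score_del, score_non, left, right)
    return ReadAssignment(
        read_id, UNINFORMATIVE, score_del, score_non, max(left, 0), max(right, 0)
    )


def call_line(
    assignments: Iterable[ReadAssignment] | tuple[int, int],
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
    line_id: str = "",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> LineGenotypeCall:
    """Call a line's allele from its informative read counts.

    Accepts either a collection of :class:`ReadAssignment` or a raw
    ``(n_deletion_reads, n_non_deletion_reads)`` pair. The majority allele
    is called when its fraction of informative reads reaches the threshold;
    otherwise the line is ``ambiguous`` (or ``no_data`` with no informative
    reads at all).
    """
    if not 0.5 < majority_threshold <= 1:
        raise ValueError("majority_threshold must be in (0.5, 1]")
    if isinstance(assignments, tuple) and len(assignments) == 2:
        n_del, n_non = assignments
    else:
        n_del = n_non = 0
        for a in assignments:  # type: ignore[union-attr]
            if a.best_allele == DELETION:
                n_del += 1
            elif a.best_allele == NON_DELETION:
                n_non += 1
    total = n_del + n_non
    if total == 0:
        return LineGenotypeCall(
            line_id, 0, 0, "no_data", float("nan"), min_overlap, majority_threshold
        )
    frac = max(n_del, n_non) / total
    if frac >= majority_threshold:
        call = DELETION if n_del >= n_non else NON_DELETION
    else:
        call = "ambiguous"
    return LineGenotypeCall(
        line_id, n_del, n_non, call, frac, min_overlap, majority_threshold
    )


def _iter_read_seqs(reads) -> Iterable[tuple[str, str]]:
    for i, r in enumerate(reads):
        if isinstance(r, str):
            yield f"read{i}", r
        elif isinstance(r, tuple):
            yield r[0], r[1]
        else:  # SimulatedRead / SeqRecord-like
            yield getattr(r, "read_id", getattr(r, "id", f"read{i}")), getattr(
                r, "sequence", None
            ) or str(getattr(r, "seq"))


def genotype_cohort(
    reads_by_line: Mapping[str, Sequence],
    refs: tuple[AlleleReference, AlleleReference],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    majority_threshold: float = DEFAULT_MAJORITY_THRESHOLD,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> tuple[pd.DataFrame, dict]:
    """Classify every read of every line and call each line's allele.

    ``reads_by_line`` maps line id to reads (strings, ``(id, seq)`` tuples,
    or objects with ``sequence``); a line whose reads cannot be obtained
    (e.g. a malformed FASTQ loader raising) is recorded as an error and the
    cohort continues. Returns a per-line table and a summary dict with
    counts of classified / ambiguous / no_data / error lines and the
    deletion-line count.
    """
    rows = []
    errors: dict[str, str] = {}
    for line_id, reads in reads_by_line.items():
        try:
            assignments = [
                classify_read(
                    seq, refs, min_overlap, max_mismatch_rate, read_id=rid
                )
                for rid, seq in _iter_read_seqs(reads)
            ]
        except Exception as exc:  # unreadable input for this line only
            errors[line_id] = str(exc)
            rows.append(
                dict(
                    line_id=line_id,
                    n_del=0,
                    n_non=0,
                    major_fraction=float("nan"),
                    call="error",
                )
            )
            continue
        call = call_line(
            assignments, majority_threshold, line_id=line_id, min_overlap=min_overlap
        )
        rows.append(
            dict(
                line_id=line_id,
                n_del=call.n_del_reads,
                n_non=call.n_non_reads,
                major_fraction=call.major_fraction,
                call=call.call,
            )
        )
    table = pd.DataFrame(rows)
    calls = table["call"]
    summary = dict(
        n_lines=len(table),
        n_classified=int(calls.isin([DELETION, NON_DELETION]).sum()),
        n_ambiguous=int((calls == "ambiguous").sum()),
        n_no_data=int((calls == "no_data").sum()),
        n_error=int((calls == "error").sum()),
        n_deletion=int((calls == DELETION).sum()),
        n_non_deletion=int((calls == NON_DELETION).sum()),
        min_overlap=min_overlap,
        majority_threshold=majority_threshold,
    )
    return table, summary


__all__ = [
    "AlleleReference",
    "Placement",
    "ReadAssignment",
    "LineGenotypeCall",
    "align_read",
    "classify_read",
    "call_line",
    "genotype_cohort",
    "encode_seq",
    "revcomp",
    "DELETION",
    "NON_DELETION",
    "UNINFORMATIVE",
    "DEFAULT_MIN_OVERLAP",
    "SHORT_READ_MIN_OVERLAP",
    "DEFAULT_MAJORITY_THRESHOLD",
]
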
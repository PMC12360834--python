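"""Read mapping: candidate retrieval plus bisulfite-asymmetric local alignment.

Each read is tried twice, matching how a directional bisulfite library
presents on the forward reference:

* as-is against the CT index, scoring a genomic C under a read T as a
  match (top-strand reads carry unmethylated-C -> T conversions);
* reverse-complemented against the GA index, scoring a genomic G under
  a read A as a match (bottom-strand reads appear as G -> A relative to
  the forward reference).

Candidate segments come from sketch-value voting
(:func:`bishash.index.query_index`); each candidate is then aligned
with an affine-gap local dynamic program whose substitution function is
asymmetric — the converted direction scores as a full match, the
reverse direction (genomic T under read C, or genomic A under read G)
remains a mismatch.  The best alignment across both attempts is
reported in SAM coordinates.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from numba import njit

from .index import CandidateRule, GenomeIndex, SegmentIndex
from .sketch import MetricMode, sketch_sequence

__all__ = [
    "ScoringScheme",
    "LocalAlignment",
    "AlignmentResult",
    "AlignSummary",
    "bisulfite_sw",
    "map_read",
    "align_file",
    "reverse_complement",
]

logger = logging.getLogger("bishash")

_CODE = np.full(256, 4, dtype=np.uint8)  # 4 = unknown base, mismatches everything
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scores with an optional bisulfite asymmetry.

    ``gap_open`` is the score of the first base of a gap and
    ``gap_extend`` of each further base.  ``mode=COLLAPSE_CT`` makes
    (genomic C, read T) score as a match while (genomic T, read C)
    stays a mismatch; ``mode=COLLAPSE_GA`` does the same for
    (genomic G, read A) versus (genomic A, read G); ``mode=None`` is
    the symmetric textbook scheme.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    mode: Optional[MetricMode] = None

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative scores")

    def substitution_matrix(self) -> np.ndarray:
        """5x5 int32 matrix over codes A,C,G,T,unknown; rows = genomic base,
        columns = read base."""
        sub = np.full((5, 5), self.mismatch, dtype=np.int32)
        for i in range(4):
            sub[i, i] = self.match
        if self.mode is MetricMode.COLLAPSE_CT:
            sub[1, 3] = self.match  # genomic C, read T
        elif self.mode is MetricMode.COLLAPSE_GA:
            sub[2, 0] = self.match  # genomic G, read A
        elif self.mode is not None:
            raise ValueError("mode must be COLLAPSE_CT, COLLAPSE_GA or None")
        sub[4, :] = self.mismatch
        sub[:, 4] = self.mismatch
        return sub

    @classmethod
    def ct(cls, **kw) -> "ScoringScheme":
        return cls(mode=MetricMode.COLLAPSE_CT, **kw)

    @classmethod
    def ga(cls, **kw) -> "ScoringScheme":
        return cls(mode=MetricMode.COLLAPSE_GA, **kw)

    @classmethod
    def symmetric(cls, **kw) -> "ScoringScheme":
        return cls(mode=None, **kw)


@njit(cache=False, nogil=True)
def _sw_fill(read, ref, sub, gap_open, gap_extend):  # pragma: no cover - numba
    m = read.shape[0]
    n = ref.shape[0]
    NEG = -(10**8)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in read (deletion)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)  # gap in reference (insertion)
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            p = np.uint8(0)
            e_open = H[i, j - 1] + gap_open
            e_ext = E[i, j - 1] + gap_extend
            if e_ext > e_open:  # ties close the gap (prefer open)
                E[i, j] = e_ext
                p |= np.uint8(4)
            else:
                E[i, j] = e_open
            f_open = H[i - 1, j] + gap_open
            f_ext = F[i - 1, j] + gap_extend
            if f_ext > f_open:
                F[i, j] = f_ext
                p |= np.uint8(8)
            else:
                F[i, j] = f_open
            diag = H[i - 1, j - 1] + sub[ref[j - 1], read[i - 1]]
            # source preference on ties: diagonal, then deletion, then insertion
            h = diag
            src = np.uint8(1)
            if E[i, j] > h:
                h = E[i, j]
                src = np.uint8(2)
            if F[i, j] > h:
                h = F[i, j]
                src = np.uint8(3)
            if h <= 0:
                h = np.int32(0)
                src = np.uint8(0)
            H[i, j] = h
            ptr[i, j] = p | src
            if h > best:  # first maximum in row-major order wins
                best = h
                bi = i
                bj = j
    return best, bi, bj, ptr


@dataclass
class LocalAlignment:
    """Local alignment of a read against one segment sequence.

    Coordinates are 0-based half-open within the segment (``ref_*``)
    and within the read (``read_*``); ``cigar`` covers the aligned
    region only (M/I/D; asymmetric matches are reported as M).
    """

    score: int
    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    cigar: str


def bisulfite_sw(read: str, segment_seq: str, scheme: ScoringScheme) -> LocalAlignment:
    """Best local alignment of ``read`` against ``segment_seq``.

    Traceback tie order: diagonal, then deletion (gap in the read),
    then insertion; within a gap, ties end the gap.  The reported cell
    is the first maximum in row-major (read-major) order.
    """
    if not read or not segment_seq:
        raise ValueError("empty read or segment sequence")
    rd = _CODE[np.frombuffer(read.encode("ascii"), dtype=np.uint8)]
    rf = _CODE[np.frombuffer(segment_seq.encode("ascii"), dtype=np.uint8)]
    sub = scheme.substitution_matrix()
    best, bi, bj, ptr = _sw_fill(
        rd, rf, sub, np.int32(scheme.gap_open), np.int32(scheme.gap_extend)
    )
    # traceback
    ops: list[str] = []
    i, j = int(bi), int(bj)
    state = "H"
    while True:
        if state == "H":
            src = ptr[i, j] & 3
            if src == 0:
                break
            if src == 1:
                ops.append("M")
                i -= 1
                j -= 1
            elif src == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            ext = ptr[i, j] & 4
            ops.append("D")
            j -= 1
            if not ext:
                state = "H"
        else:  # F
            ext = ptr[i, j] & 8
            ops.append("I")
            i -= 1
            if not ext:
                state = "H"
    ops.reverse()
    cigar = _run_length(ops)
    return LocalAlignment(
        score=int(best),
        ref_start=j,
        ref_end=int(bj),
        read_start=i,
        read_end=int(bi),
        cigar=cigar,
    )


def _run_length(ops: Sequence[str]) -> str:
    if not ops:
        return ""
    parts = []
    prev = ops[0]
    count = 1
    for op in ops[1:]:
        if op == prev:
            count += 1
        else:
            parts.append(f"{count}{prev}")
            prev = op
            count = 1
    parts.append(f"{count}{prev}")
    return "".join(parts)


# ---------------------------------------------------------------------------
# read mapping
# ---------------------------------------------------------------------------


@dataclass
class AlignmentResult:
    read_id: str
    contig: str
    pos: int  # 0-based leftmost reference offset
    strand_mode: str  # "CT_forward" | "GA_revcomp"
    score: int
    cigar: str  # full-read CIGAR including soft clips
    mapq: int
    n_candidates: int
    secondary_best_score: Optional[int]


def map_read(
    read_id: str,
    sequence: str,
    genome_index: GenomeIndex,
    rule: CandidateRule | None = None,
    scheme_params: dict | None = None,
    min_score_fraction: float = 0.66,
) -> Optional[AlignmentResult]:
    """Map one read against both conversion-mode indexes.

    Attempt 1 sketches the read as-is and extends CT candidates with
    the CT scheme; attempt 2 reverse-complements the read and uses the
    GA index and scheme.  The single best-scoring alignment (after
    merging hits that resolve to the same genomic position through
    overlapping segments) is returned, or ``None`` when no candidate
    passes the vote rule or the best score falls below
    ``min_score_fraction * match * read_length``.
    """
    rule = rule or CandidateRule()
    kw = dict(scheme_params or {})
    tau = genome_index.params.tau
    if len(sequence) > tau:
        raise ValueError(
            f"read {read_id!r} has length {len(sequence)} > tau={tau}; "
            "rebuild the index with a larger overlap"
        )
    attempts = (
        ("CT_forward", sequence, genome_index.ct, ScoringScheme.ct(**kw)),
        ("GA_revcomp", reverse_complement(sequence), genome_index.ga, ScoringScheme.ga(**kw)),
    )
    contig_order = genome_index.contig_order
    contig_seq = dict(genome_index.contigs)
    pad = len(sequence)  # lets a read straddling a segment boundary align fully
    hits: dict[tuple[str, int], tuple] = {}
    n_candidates = 0
    for label, seq_variant, side, scheme in attempts:
        rs = sketch_sequence(seq_variant, side.config, side.mode)
        candidates = query_index_side(rs, side, rule)
        n_candidates += len(candidates)
        for seg_id, votes in candidates:
            seg = side.segments[seg_id]
            cseq = contig_seq[seg.contig]
            win_start = max(0, seg.start - pad)
            win_end = min(len(cseq), seg.start + seg.length + pad)
            la = bisulfite_sw(seq_variant, cseq[win_start:win_end], scheme)
            if la.score <= 0:
                continue
            pos = win_start + la.ref_start
            key = (seg.contig, pos)
            prev = hits.get(key)
            if prev is None or la.score > prev[0]:
                hits[key] = (la.score, label, la, seq_variant)
    if not hits:
        return None
    ranked = sorted(
        (
            (-score, contig_order[contig], pos, label, la, seq_variant)
            for (contig, pos), (score, label, la, seq_variant) in hits.items()
        )
    )
    best = ranked[0]
    best_score = -best[0]
    best_contig = genome_index.contigs[best[1]][0]
    pos, label, la, seq_variant = best[2], best[3], best[4], best[5]

    match_score = ScoringScheme.ct(**kw).match
    if best_score < min_score_fraction * match_score * len(sequence):
        return None

    second = -ranked[1][0] if len(ranked) > 1 else None
    if second is not None and second == best_score:
        mapq = 0
    else:
        mapq = min(60, 4 * (best_score - (second or 0)))

    read_len = len(seq_variant)
    clips_left = la.read_start
    clips_right = read_len - la.read_end
    cigar = (
        (f"{clips_left}S" if clips_left else "")
        + la.cigar
        + (f"{clips_right}S" if clips_right else "")
    )
    return AlignmentResult(
        read_id=read_id,
        contig=best_contig,
        pos=pos,
        strand_mode=label,
        score=best_score,
        cigar=cigar,
        mapq=mapq,
        n_candidates=n_candidates,
        secondary_best_score=second,
    )


def query_index_side(read_sketch, side: SegmentIndex, rule: CandidateRule):
    from .index import query_index

    return query_index(read_sketch, side, rule)


# ---------------------------------------------------------------------------
# file-level driver
# ---------------------------------------------------------------------------


@dataclass
class AlignSummary:
    n_reads: int
    mapped: int
    unmapped: int


def _read_fastq(path) -> Iterable[tuple[str, str, str]]:
    """Minimal 4-line FASTQ reader that reports the offending line number."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            lineno += 1
            if not header.startswith("@"):
                raise ValueError(
                    f"malformed FASTQ at line {lineno}: expected '@', got {header[:20]!r}"
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ValueError(f"malformed FASTQ: truncated record at line {lineno}")
            lineno += 3
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ at line {lineno - 1}: expected '+'")
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ at line {lineno}: sequence/quality length mismatch"
                )
            yield header[1:].split()[0], seq, qual


def align_file(
    fastq_path,
    index,
    out_sam_path,
    *,
    rule: CandidateRule | None = None,
    scheme_params: dict | None = None,
    min_score_fraction: float = 0.66,
    threads: int = 1,
    program_args: str = "",
    extra_comments: Sequence[str] = (),
) -> AlignSummary:
    """Map a FASTQ file and write one SAM record per read.

    Output order matches input order for any ``threads`` value, so SAM
    bodies are byte-identical across worker counts.
    """
    import pysam

    from . import __version__

    if not isinstance(index, GenomeIndex):
        index = GenomeIndex.load(index)
    rule = rule or CandidateRule()

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in index.contigs],
        "PG": [
            {
                "ID": "bishash",
                "PN": "bishash",
                "VN": __version__,
                "CL": program_args or "bishash align",
            }
        ],
        "CO": list(extra_comments),
    }

    reads = list(_read_fastq(fastq_path))

    def _map(item):
        rid, seq, qual = item
        return map_read(
            rid,
            seq,
            index,
            rule=rule,
            scheme_params=scheme_params,
            min_score_fraction=min_score_fraction,
        )

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(_map, reads, chunksize=16))
    else:
        results = [_map(item) for item in reads]

    tid = {name: i for i, (name, _) in enumerate(index.contigs)}
    mapped = 0
    with pysam.AlignmentFile(str(out_sam_path), "w", header=header) as sam:
        for (rid, seq, qual), res in zip(reads, results):
            rec = pysam.AlignedSegment(sam.header)
            rec.query_name = rid
            if res is None:
                rec.flag = 4
                rec.query_sequence = seq
                rec.query_qualities = pysam.qualitystring_to_array(qual)
                rec.mapping_quality = 0
            else:
                mapped += 1
                reverse = res.strand_mode == "GA_revcomp"
                rec.flag = 16 if reverse else 0
                rec.reference_id = tid[res.contig]
                rec.reference_start = res.pos
                rec.mapping_quality = res.mapq
                rec.cigarstring = res.cigar
                rec.query_sequence = reverse_complement(seq) if reverse else seq
                rec.query_qualities = pysam.qualitystring_to_array(
                    qual[::-1] if reverse else qual
                )
                rec.set_tag("AS", res.score)
                rec.set_tag("XC", res.n_candidates)
                rec.set_tag("XM", "GA" if reverse else "CT")
            sam.write(rec)
    summary = AlignSummary(
        n_reads=len(reads), mapped=mapped, unmapped=len(reads) - mapped
    )
    logger.info(
        "aligned %s: %d reads, %d mapped, %d unmapped",
        fastq_path,
        summary.n_reads,
        summary.mapped,
        summary.unmapped,
    )
    return summary
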
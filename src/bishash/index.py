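"""Reference segmentation and the sketch-value vote index.

The reference genome is cut into overlapping windows ("segments") of
length ``T`` with overlap ``tau >= maximum read length``, so every read
lies entirely inside at least one segment.  Each segment is sketched
with M3Hash under a conversion mode (CT or GA), and every defined
sketch entry is inserted into an ordered associative structure keyed by
``(cell, metric, repetition, value)``.  A read is located by looking up
its own sketch entries and counting, per segment, how many coordinates
agree — the vote count — and keeping the top-voted segments.
"""

from __future__ import annotations

import gzip
import io
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sketch import (
    UNDEFINED,
    MetricMode,
    Sketch,
    SketchConfig,
    sketch_sequence,
)

__all__ = [
    "Segment",
    "IndexParams",
    "CandidateRule",
    "SegmentIndex",
    "GenomeIndex",
    "segment_genome",
    "build_index",
    "query_index",
    "build_genome_index",
    "read_fasta",
]

_INDEX_MAGIC = b"BHX1"


@dataclass(frozen=True)
class IndexParams:
    """Segmentation and sketching parameters.

    ``T`` is the segment length in bp and ``tau`` the overlap between
    consecutive segments; ``tau`` must be at least the maximum read
    length so every read is contained in a single segment.
    """

    T: int = 500
    tau: int = 300
    sketch: SketchConfig = field(default_factory=SketchConfig)

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.T <= self.tau:
            raise ValueError(f"segment length T={self.T} must exceed overlap tau={self.tau}")

    @property
    def step(self) -> int:
        return self.T - self.tau

    def config_for(self, mode: MetricMode) -> SketchConfig:
        """Sketch config with the metric pair matching a conversion mode."""
        return SketchConfig.for_mode(
            MetricMode(mode),
            k=self.sketch.k,
            kappa=self.sketch.kappa,
            R=self.sketch.R,
            master_seed=self.sketch.master_seed,
        )


@dataclass
class Segment:
    segment_id: int
    contig: str
    start: int  # 0-based inclusive
    length: int
    sequence: str


@dataclass(frozen=True)
class CandidateRule:
    """Vote thresholds for candidate-segment selection.

    A segment is kept when its vote count reaches both ``min_votes``
    and ``fraction`` of the best count; at most ``max_candidates`` are
    returned, best first, ties broken by ascending segment id.
    """

    fraction: float = 0.8
    min_votes: int = 2
    max_candidates: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if self.min_votes < 1:
            raise ValueError("min_votes must be >= 1")
        if self.max_candidates < 1:
            raise ValueError("max_candidates must be >= 1")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a (possibly gzipped) FASTA file into (name, sequence) pairs."""
    from Bio import SeqIO

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _norm_records(reference) -> list[tuple[str, str]]:
    out = []
    for rec in reference:
        if isinstance(rec, tuple):
            out.append((rec[0], str(rec[1])))
        else:  # Bio.SeqRecord
            out.append((rec.id, str(rec.seq)))
    if not out:
        raise ValueError("empty reference: no contigs")
    return out


def segment_genome(reference, params: IndexParams) -> list[Segment]:
    """Cut every contig into overlapping segments of length ``T``.

    Starts advance by ``T - tau``; the final segment is anchored to end
    at the contig end, so every window of length <= ``tau`` lies fully
    inside at least one segment.  Contigs shorter than ``T`` yield one
    whole-contig segment.
    """
    records = _norm_records(reference)
    segments: list[Segment] = []
    sid = 0
    for name, seq in records:
        L = len(seq)
        if L <= params.T:
            starts = [0]
        else:
            starts = list(range(0, L - params.T + 1, params.step))
            if starts[-1] != L - params.T:
                starts.append(L - params.T)
        for s in starts:
            length = min(params.T, L - s)
            segments.append(
                Segment(
                    segment_id=sid,
                    contig=name,
                    start=s,
                    length=length,
                    sequence=seq[s : s + length],
                )
            )
            sid += 1
    return segments


@dataclass
class SegmentIndex:
    """Ordered lookup from (cell, metric, repetition, hash value) to
    the sorted segment ids holding that value at that coordinate."""

    mode: MetricMode
    config: SketchConfig
    lookup: dict[tuple[int, int, int, int], np.ndarray]
    segments: list[Segment]

    @property
    def fingerprint(self) -> str:
        return self.config.fingerprint(self.mode)


def build_index(
    segments: list[Segment], params: IndexParams, mode: MetricMode
) -> SegmentIndex:
    """Sketch every segment and assemble the vote index for one mode."""
    mode = MetricMode(mode)
    config = params.config_for(mode)
    acc: dict[tuple[int, int, int, int], list[int]] = {}
    for seg in segments:
        sk = sketch_sequence(seg.sequence, config, mode)
        vals = sk.values
        z, d, r = vals.shape
        defined = vals != UNDEFINED
        for i, j, rep in zip(*np.nonzero(defined)):
            key = (int(i), int(j), int(rep), int(vals[i, j, rep]))
            acc.setdefault(key, []).append(seg.segment_id)
    lookup = {
        key: np.unique(np.array(ids, dtype=np.uint32))
        for key, ids in sorted(acc.items())
    }
    return SegmentIndex(mode=mode, config=config, lookup=lookup, segments=segments)


def query_index(
    read_sketch: Sketch, index: SegmentIndex, select: CandidateRule
) -> list[tuple[int, int]]:
    """Vote-count candidate segments for a read sketch.

    Returns ``(segment_id, vote_count)`` pairs with vote counts at least
    ``max(select.min_votes, ceil(select.fraction * best))``, sorted by
    descending votes then ascending id, capped at
    ``select.max_candidates``.
    """
    if read_sketch.config_fingerprint != index.fingerprint:
        raise ValueError(
            "sketch/index config mismatch: "
            f"{read_sketch.config_fingerprint} vs {index.fingerprint}"
        )
    vals = read_sketch.values
    defined = vals != UNDEFINED
    n_segments = len(index.segments)
    counts = np.zeros(n_segments, dtype=np.int64)
    for i, j, rep in zip(*np.nonzero(defined)):
        hit = index.lookup.get((int(i), int(j), int(rep), int(vals[i, j, rep])))
        if hit is not None:
            counts[hit] += 1
    best = int(counts.max()) if n_segments else 0
    if best == 0:
        return []
    threshold = max(select.min_votes, math.ceil(select.fraction * best))
    ids = np.nonzero(counts >= threshold)[0]
    ranked = sorted(((int(counts[s]), -int(s)) for s in ids), reverse=True)
    return [(-neg_id, votes) for votes, neg_id in ranked[: select.max_candidates]]


# ---------------------------------------------------------------------------
# the two-mode genome index and its on-disk form
# ---------------------------------------------------------------------------


@dataclass
class GenomeIndex:
    """CT and GA segment indexes over one reference, plus metadata."""

    params: IndexParams
    contigs: list[tuple[str, str]]  # (name, sequence)
    segments: list[Segment]
    ct: SegmentIndex
    ga: SegmentIndex
    meta: dict = field(default_factory=dict)

    @property
    def contig_order(self) -> dict[str, int]:
        return {name: i for i, (name, _) in enumerate(self.contigs)}

    # -- serialization -----------------------------------------------------
    # Layout (all little-endian):
    #   magic "BHX1"
    #   u32 header_len, JSON header {version, params, meta, contigs, segments}
    #   per contig: u64 length + ASCII sequence bytes
    #   per mode (CT then GA):
    #     u64 n_keys
    #     u32[n_keys]  packed coordinate (cell<<16 | metric<<8 | repetition)
    #     u64[n_keys]  hash value (UNDEFINED never appears)
    #     u64[n_keys+1] payload offsets
    #     u32[total]   segment ids
    def save(self, path) -> None:
        header = {
            "version": 1,
            "params": {
                "T": self.params.T,
                "tau": self.params.tau,
                "k": self.params.sketch.k,
                "kappa": self.params.sketch.kappa,
                "R": self.params.sketch.R,
                "master_seed": self.params.sketch.master_seed,
            },
            "meta": self.meta,
            "contigs": [{"name": n, "length": len(s)} for n, s in self.contigs],
            "segments": [
                {"contig": s.contig, "start": s.start, "length": s.length}
                for s in self.segments
            ],
        }
        hj = json.dumps(header).encode()
        with open(path, "wb") as fh:
            fh.write(_INDEX_MAGIC)
            fh.write(np.uint32(len(hj)).astype("<u4").tobytes())
            fh.write(hj)
            for _, seq in self.contigs:
                data = seq.encode("ascii")
                fh.write(np.uint64(len(data)).astype("<u8").tobytes())
                fh.write(data)
            for side in (self.ct, self.ga):
                keys = sorted(side.lookup.keys())
                coords = np.array(
                    [(i << 16) | (j << 8) | r for i, j, r, _ in keys], dtype="<u4"
                )
                values = np.array([v for _, _, _, v in keys], dtype="<u8")
                offsets = np.zeros(len(keys) + 1, dtype="<u8")
                payload_parts = []
                for n, key in enumerate(keys):
                    ids = side.lookup[key]
                    offsets[n + 1] = offsets[n] + len(ids)
                    payload_parts.append(ids.astype("<u4"))
                payload = (
                    np.concatenate(payload_parts)
                    if payload_parts
                    else np.empty(0, dtype="<u4")
                )
                fh.write(np.uint64(len(keys)).astype("<u8").tobytes())
                fh.write(coords.tobytes())
                fh.write(values.tobytes())
                fh.write(offsets.tobytes())
                fh.write(payload.tobytes())

    @classmethod
    def load(cls, path) -> "GenomeIndex":
        with open(path, "rb") as fh:
            if fh.read(4) != _INDEX_MAGIC:
                raise ValueError(f"{path} is not a bishash index (bad magic)")
            (hlen,) = np.frombuffer(fh.read(4), dtype="<u4")
            header = json.loads(fh.read(int(hlen)).decode())
            p = header["params"]
            params = IndexParams(
                T=p["T"],
                tau=p["tau"],
                sketch=SketchConfig(
                    k=p["k"], kappa=p["kappa"], R=p["R"], master_seed=p["master_seed"]
                ),
            )
            contigs = []
            for c in header["contigs"]:
                (n,) = np.frombuffer(fh.read(8), dtype="<u8")
                contigs.append((c["name"], fh.read(int(n)).decode("ascii")))
            seq_by_name = dict(contigs)
            segments = [
                Segment(
                    segment_id=i,
                    contig=s["contig"],
                    start=s["start"],
                    length=s["length"],
                    sequence=seq_by_name[s["contig"]][s["start"] : s["start"] + s["length"]],
                )
                for i, s in enumerate(header["segments"])
            ]
            sides = []
            for mode in (MetricMode.COLLAPSE_CT, MetricMode.COLLAPSE_GA):
                (nk,) = np.frombuffer(fh.read(8), dtype="<u8")
                nk = int(nk)
                coords = np.frombuffer(fh.read(4 * nk), dtype="<u4")
                values = np.frombuffer(fh.read(8 * nk), dtype="<u8")
                offsets = np.frombuffer(fh.read(8 * (nk + 1)), dtype="<u8")
                total = int(offsets[-1]) if nk else 0
                payload = np.frombuffer(fh.read(4 * total), dtype="<u4")
                lookup = {}
                for n in range(nk):
                    c = int(coords[n])
                    key = (c >> 16, (c >> 8) & 0xFF, c & 0xFF, int(values[n]))
                    lookup[key] = payload[int(offsets[n]) : int(offsets[n + 1])].astype(
                        np.uint32
                    )
                sides.append(
                    SegmentIndex(
                        mode=mode,
                        config=params.config_for(mode),
                        lookup=lookup,
                        segments=segments,
                    )
                )
        return cls(
            params=params,
            contigs=contigs,
            segments=segments,
            ct=sides[0],
            ga=sides[1],
            meta=header.get("meta", {}),
        )


def build_genome_index(
    reference, params: IndexParams, meta: dict | None = None
) -> GenomeIndex:
    """Segment a reference and build both conversion-mode indexes."""
    contigs = _norm_records(reference)
    segments = segment_genome(contigs, params)
    ct = build_index(segments, params, MetricMode.COLLAPSE_CT)
    ga = build_index(segments, params, MetricMode.COLLAPSE_GA)
    return GenomeIndex(
        params=params,
        contigs=contigs,
        segments=segments,
        ct=ct,
        ga=ga,
        meta=meta or {},
    )
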
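"""Synthetic references, methylation landscapes and directional bisulfite reads.

The simulator emulates a directional whole-genome bisulfite library:
top-strand reads carry C -> T conversions at unmethylated cytosines,
bottom-strand reads are reverse-complemented fragments whose converted
cytosines appear as G -> A relative to the forward reference.  Two
methylation landscapes are provided: ``normal`` (CpG-structured — CpG
sites hypermethylated outside CpG islands, hypomethylated inside them,
non-CpG cytosines nearly unmethylated) and ``random`` (every cytosine
context gets an independent uniform methylation probability, the
unpredictable landscape seen e.g. in cancer genomes).  Sequencing
error is a uniform substitution process.  Every read is paired with a
ground-truth record for downstream evaluation.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MethylationProfile",
    "TruthRecord",
    "generate_reference",
    "assign_methylation",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
    "write_truth",
    "read_truth",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# "normal" landscape defaults: CpG sites outside islands are mostly
# methylated, island CpGs mostly not, non-CpG cytosines almost never
NORMAL_DEFAULTS = {
    "cpg_meth": 0.8,
    "island_cpg_meth": 0.2,
    "non_cpg_meth": 0.02,
}

# CpG-island call: CG-dinucleotide starts per bp inside a centred window
_ISLAND_WINDOW = 201
_ISLAND_CG_PER_BP = 0.15

# island sequence composition during reference generation
_ISLAND_CG_EMIT = 0.35
_ISLAND_GC = 0.6

TRUTH_COLUMNS = ["read_id", "contig", "start_0based", "strand", "n_conversions", "n_errors"]


def _norm_records(reference) -> list[tuple[str, str]]:
    out = []
    for rec in reference:
        if isinstance(rec, tuple):
            out.append((rec[0], str(rec[1])))
        else:
            out.append((rec.id, str(rec.seq)))
    return out


# ---------------------------------------------------------------------------
# reference generation
# ---------------------------------------------------------------------------


def generate_reference(
    n_contigs: int = 1,
    contig_len: int = 200_000,
    gc_content: float = 0.5,
    cpg_island_density: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Random reference contigs with optional CpG-enriched islands.

    The background is i.i.d. at the requested GC content.  Islands
    cover approximately ``cpg_island_density`` of each contig; inside
    an island a CG dinucleotide is emitted with high probability so
    islands are detectable by local CpG density, mimicking the elevated
    CpG rate of real islands.  Deterministic given ``seed``.
    """
    if contig_len < 1:
        raise ValueError("contig_len must be >= 1")
    if not 0.0 < gc_content < 1.0:
        raise ValueError("gc_content must be in (0, 1)")
    if not 0.0 <= cpg_island_density < 1.0:
        raise ValueError("cpg_island_density must be in [0, 1)")
    rng = np.random.default_rng(seed)
    probs = np.array(
        [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
    )
    records = []
    for c in range(n_contigs):
        codes = rng.choice(4, size=contig_len, p=probs).astype(np.uint8)
        if cpg_island_density > 0:
            for lo, hi in _plan_islands(rng, contig_len, cpg_island_density):
                codes[lo:hi] = _island_sequence(rng, hi - lo)
        seq = codes_to_str(codes)
        records.append((f"contig_{c + 1}", seq))
    return records


def codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _plan_islands(rng, contig_len, density) -> list[tuple[int, int]]:
    target = density * contig_len
    intervals: list[tuple[int, int]] = []
    covered = 0
    attempts = 0
    while covered < target and attempts < 10_000:
        attempts += 1
        length = int(rng.integers(300, 1001))
        if length >= contig_len:
            length = contig_len
        start = int(rng.integers(0, contig_len - length + 1))
        if any(start < hi and lo < start + length for lo, hi in intervals):
            continue
        intervals.append((start, start + length))
        covered += length
    return sorted(intervals)


def _island_sequence(rng, length: int) -> np.ndarray:
    """CpG-enriched stretch: emit 'CG' with high probability, else a
    GC-rich single base."""
    base_probs = np.array(
        [(1 - _ISLAND_GC) / 2, _ISLAND_GC / 2, _ISLAND_GC / 2, (1 - _ISLAND_GC) / 2]
    )
    out = np.empty(length, dtype=np.uint8)
    pos = 0
    while pos < length:
        if rng.random() < _ISLAND_CG_EMIT and pos + 1 < length:
            out[pos] = 1  # C
            out[pos + 1] = 2  # G
            pos += 2
        else:
            out[pos] = rng.choice(4, p=base_probs)
            pos += 1
    return out


# ---------------------------------------------------------------------------
# methylation landscape
# ---------------------------------------------------------------------------


@dataclass
class MethylationProfile:
    """Per-contig methylation probability tracks.

    ``c_probs[name][i]`` is the methylation probability of the forward-
    strand cytosine at position ``i`` (NaN where the base is not C);
    ``g_probs`` is the analogous track at guanine positions, standing
    in for the bottom-strand cytosine of the same site.
    """

    mode: str
    c_probs: dict[str, np.ndarray]
    g_probs: dict[str, np.ndarray]


def detect_cpg_islands(seq_codes: np.ndarray) -> np.ndarray:
    """Boolean island mask from local CpG density.

    A position is inside an island when the centred ``_ISLAND_WINDOW``
    window holds at least ``_ISLAND_CG_PER_BP`` CG-dinucleotide starts
    per bp — a density far above what an i.i.d. background produces.
    """
    n = seq_codes.size
    cg_start = np.zeros(n)
    if n >= 2:
        cg_start[:-1] = (seq_codes[:-1] == 1) & (seq_codes[1:] == 2)
    kernel = np.ones(_ISLAND_WINDOW)
    counts = np.convolve(cg_start, kernel, mode="same")
    window = np.convolve(np.ones(n), kernel, mode="same")  # edge-corrected width
    return counts / window >= _ISLAND_CG_PER_BP


def assign_methylation(
    reference,
    mode: str,
    params: dict | None = None,
    seed: int = 0,
) -> MethylationProfile:
    """Build a methylation probability track for every contig.

    ``mode='normal'``: CpG cytosines get ``cpg_meth`` (default 0.8),
    CpG cytosines inside detected islands get ``island_cpg_meth``
    (default 0.2), all other cytosines ``non_cpg_meth`` (default 0.02).
    ``mode='random'``: every cytosine-context probability is drawn
    Uniform(0, 1) independently.  Guanine positions receive the same
    treatment on the bottom strand (a GpC... i.e. CpG read on the minus
    strand corresponds to a forward-strand G preceded by C).
    """
    if mode not in ("normal", "random"):
        raise ValueError(f"unknown methylation mode {mode!r}")
    p = dict(NORMAL_DEFAULTS)
    p.update(params or {})
    rng = np.random.default_rng(seed)
    c_probs: dict[str, np.ndarray] = {}
    g_probs: dict[str, np.ndarray] = {}
    for name, seq in _norm_records(reference):
        codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        is_c = codes == ord("C")
        is_g = codes == ord("G")
        n = codes.size
        c_track = np.full(n, np.nan)
        g_track = np.full(n, np.nan)
        if mode == "random":
            c_track[is_c] = rng.random(int(is_c.sum()))
            g_track[is_g] = rng.random(int(is_g.sum()))
        else:
            code4 = np.full(n, 4, dtype=np.uint8)
            for i, b in enumerate(b"ACGT"):
                code4[codes == b] = i
            island = detect_cpg_islands(code4)
            cpg_c = np.zeros(n, dtype=bool)  # C followed by G
            if n >= 2:
                cpg_c[:-1] = is_c[:-1] & is_g[1:]
            cpg_g = np.zeros(n, dtype=bool)  # G preceded by C
            if n >= 2:
                cpg_g[1:] = is_g[1:] & is_c[:-1]
            c_track[is_c] = p["non_cpg_meth"]
            c_track[cpg_c] = np.where(island[cpg_c], p["island_cpg_meth"], p["cpg_meth"])
            g_track[is_g] = p["non_cpg_meth"]
            g_track[cpg_g] = np.where(island[cpg_g], p["island_cpg_meth"], p["cpg_meth"])
        c_probs[name] = c_track
        g_probs[name] = g_track
    return MethylationProfile(mode=mode, c_probs=c_probs, g_probs=g_probs)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class TruthRecord:
    read_id: str
    contig: str
    true_start: int  # 0-based
    strand: str  # '+' | '-'
    n_conversions: int
    n_errors: int


_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b


def simulate_reads(
    reference,
    profile: MethylationProfile,
    n_reads: int,
    read_len: int = 150,
    error_rate: float = 0.01,
    seed: int = 0,
    both_strands: bool = True,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate directional bisulfite reads with ground truth.

    Each read draws a uniform (contig, offset) over all valid start
    positions and, when ``both_strands``, a uniform strand.  Forward
    reads convert each C to T with probability ``1 - m`` (``m`` the
    cytosine's methylation probability); bottom-strand reads convert
    the fragment's bottom-strand cytosines (forward-strand Gs) the same
    way and are emitted reverse-complemented, so they show G -> A
    relative to the forward reference.  Substitution errors are applied
    uniformly at ``error_rate`` afterwards.  Returns FASTQ tuples
    ``(read_id, sequence, quality)`` (constant quality 'I') and the
    truth table.
    """
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    records = _norm_records(reference)
    for name, seq in records:
        if read_len > len(seq):
            raise ValueError(
                f"read_len={read_len} exceeds contig {name!r} length {len(seq)}"
            )
    rng = np.random.default_rng(seed)
    n_starts = np.array([len(seq) - read_len + 1 for _, seq in records], dtype=float)
    contig_p = n_starts / n_starts.sum()
    qual = "I" * read_len

    contig_codes = {
        name: np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
        for name, seq in records
    }

    fastq: list[tuple[str, str, str]] = []
    rows = []
    for idx in range(n_reads):
        ci = int(rng.choice(len(records), p=contig_p))
        name, _ = records[ci]
        codes = contig_codes[name]
        start = int(rng.integers(0, int(n_starts[ci])))
        strand = "+" if (not both_strands or rng.random() < 0.5) else "-"
        frag = codes[start : start + read_len].copy()
        if strand == "+":
            c_pos = np.nonzero(frag == ord("C"))[0]
            m = profile.c_probs[name][start + c_pos]
            convert = rng.random(c_pos.size) >= m
            frag[c_pos[convert]] = ord("T")
        else:
            g_pos = np.nonzero(frag == ord("G"))[0]
            m = profile.g_probs[name][start + g_pos]
            convert = rng.random(g_pos.size) >= m
            frag[g_pos[convert]] = ord("A")
            frag = _COMP[frag][::-1]
        n_conversions = int(convert.sum()) if frag.size else 0
        err_mask = rng.random(read_len) < error_rate
        err_pos = np.nonzero(err_mask)[0]
        for pcur in err_pos:
            cur = frag[pcur]
            choices = [b for b in b"ACGT" if b != cur]
            frag[pcur] = choices[int(rng.integers(0, 3))]
        read_id = f"read_{idx:06d}"
        fastq.append((read_id, frag.tobytes().decode("ascii"), qual))
        rows.append(
            (read_id, name, start, strand, n_conversions, int(err_pos.size))
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return fastq, truth


# ---------------------------------------------------------------------------
# plain-text writers
# ---------------------------------------------------------------------------


def _opener(path):
    return gzip.open if str(path).endswith(".gz") else open


def write_fasta(records, path, width: int = 70) -> None:
    with _opener(path)(path, "wt") as fh:
        for name, seq in _norm_records(records):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    with _opener(path)(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
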
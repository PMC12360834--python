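"""Alignment evaluation against a simulated ground truth.

A mapped read counts as correct when it lands on the true contig
within a small positional tolerance (default 1 bp) of the simulated
origin.  The false discovery rate is the fraction of mapped reads that
are mapped incorrectly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

__all__ = ["EvalReport", "evaluate"]


@dataclass
class EvalReport:
    """Accuracy summary of one SAM file against its truth table.

    ``pct_correct`` is the percentage of *all* reads mapped within
    tolerance; ``pct_correct_of_mapped`` restricts the denominator to
    mapped reads.  ``fdr = n_incorrect / n_mapped`` (0 when nothing is
    mapped, by convention).
    """

    n_reads: int
    n_mapped: int
    n_correct: int
    n_incorrect: int
    pct_correct: float
    pct_correct_of_mapped: float
    fdr: float
    tolerance_bp: int

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def evaluate(
    sam_path,
    truth_path,
    tolerance_bp: int = 1,
    require_strand: bool = False,
) -> EvalReport:
    """Score a SAM file against a truth table.

    A mapped read is correct iff its contig matches the truth and the
    absolute difference between the reported leftmost position and the
    simulated start is at most ``tolerance_bp`` (both 0-based; pysam
    already converts SAM's 1-based POS).  With ``require_strand`` the
    reported orientation must also match.  Every read id present in
    the SAM must appear in the truth table.
    """
    import pysam

    from .sim import read_truth

    truth = read_truth(truth_path)
    by_id = {
        row.read_id: (row.contig, int(row.start_0based), row.strand)
        for row in truth.itertuples()
    }

    n_reads = n_mapped = n_correct = 0
    missing = []
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.query_name not in by_id:
                missing.append(rec.query_name)
                continue
            n_reads += 1
            if rec.is_unmapped:
                continue
            n_mapped += 1
            contig, start, strand = by_id[rec.query_name]
            ok = (
                rec.reference_name == contig
                and abs(rec.reference_start - start) <= tolerance_bp
            )
            if ok and require_strand:
                ok = ("-" if rec.is_reverse else "+") == strand
            if ok:
                n_correct += 1
    if missing:
        shown = ", ".join(missing[:10])
        raise ValueError(
            f"{len(missing)} SAM read id(s) missing from truth table: {shown}"
        )
    n_incorrect = n_mapped - n_correct
    return EvalReport(
        n_reads=n_reads,
        n_mapped=n_mapped,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        pct_correct=100.0 * n_correct / n_reads if n_reads else 0.0,
        pct_correct_of_mapped=100.0 * n_correct / n_mapped if n_mapped else 0.0,
        fdr=n_incorrect / n_mapped if n_mapped else 0.0,
        tolerance_bp=tolerance_bp,
    )
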
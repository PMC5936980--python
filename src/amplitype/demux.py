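"""Barcode demultiplexing of multiplexed amplicon reads.

Each barcode (and its reverse complement) is aligned semi-globally —
free end gaps on the read window — against the first and last ``window``
bases of the read. The best edit distance over all barcodes, ends and
orientations decides the assignment; a read is left unclassified when
the best distance exceeds ``max_edits``, when the margin to the
runner-up barcode is below ``min_margin``, or when the two read ends
confidently match different barcodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import edlib
import pandas as pd

from .alleles import reverse_complement
from .qc import ReadRecord, read_fastq, write_fastq

__all__ = ["DemuxParams", "DemuxResult", "scan_barcode", "demux_reads",
           "demux_run"]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class DemuxParams:
    """Thresholds for barcode assignment.

    ``max_edits`` defaults to 25% of barcode length (computed per set);
    ``min_margin`` is the required edit-distance gap to the runner-up
    barcode.
    """

    window: int = 150
    max_edits: Optional[int] = None
    min_margin: int = 2

    def resolved_max_edits(self, barcode_len: int) -> int:
        return (self.max_edits if self.max_edits is not None
                else barcode_len // 4)


@dataclass(frozen=True)
class DemuxResult:
    read_id: str
    sample: str              # barcode/sample id or "unclassified"
    distance: Optional[int]  # best edit distance over all combinations
    margin: Optional[int]    # runner-up best minus best (>= 0)
    matched_end: str         # "left" / "right" / "both" / "none"
    orientation: str         # orientation of the best-matching barcode

    @property
    def classified(self) -> bool:
        return self.sample != UNCLASSIFIED


def _end_windows(seq: str, window: int):
    w = min(window, len(seq))
    return {"left": seq[:w], "right": seq[-w:]}


def scan_barcode(read: ReadRecord, barcodes: Mapping[str, str],
                 params: DemuxParams = DemuxParams()) -> DemuxResult:
    """Assign one read to a barcode, or mark it unclassified."""
    if not barcodes:
        raise ValueError("empty barcode set")
    bc_len = len(next(iter(barcodes.values())))
    max_edits = params.resolved_max_edits(bc_len)
    windows = _end_windows(read.sequence, params.window)

    # Best distance per (barcode, end) over both orientations; fixed
    # iteration order keeps ties deterministic.
    per_end: dict = {}   # (bc_id, end) -> (dist, orient)
    best_by_bc: dict = {}  # bc_id -> (dist, end, orient)
    end_best: dict = {"left": None, "right": None}  # end -> (dist, bc_id)
    for bc_id in sorted(barcodes):
        variants = (("fwd", barcodes[bc_id]),
                    ("rc", reverse_complement(barcodes[bc_id])))
        overall = None
        for end in ("left", "right"):
            hit = None
            for orient, bseq in variants:
                d = edlib.align(bseq, windows[end], mode="HW")["editDistance"]
                if hit is None or d < hit[0]:
                    hit = (d, orient)
            per_end[bc_id, end] = hit
            if overall is None or hit[0] < overall[0]:
                overall = (hit[0], end, hit[1])
            if end_best[end] is None or hit[0] < end_best[end][0]:
                end_best[end] = (hit[0], bc_id)
        best_by_bc[bc_id] = overall

    ranked = sorted(best_by_bc.items(), key=lambda kv: (kv[1][0], kv[0]))
    (bc_id, (dist, end, orient)) = ranked[0]
    margin = (ranked[1][1][0] - dist) if len(ranked) > 1 else dist + 1

    # conflicting confident ends -> unclassified
    conflict = (end_best["left"][0] <= max_edits
                and end_best["right"][0] <= max_edits
                and end_best["left"][1] != end_best["right"][1])

    left_ok = per_end[bc_id, "left"][0] <= max_edits
    right_ok = per_end[bc_id, "right"][0] <= max_edits
    matched_end = ("both" if left_ok and right_ok
                   else "left" if left_ok else "right" if right_ok else "none")
    assigned = dist <= max_edits and margin >= params.min_margin and not conflict
    return DemuxResult(
        read_id=read.id,
        sample=bc_id if assigned else UNCLASSIFIED,
        distance=dist,
        margin=margin,
        matched_end=matched_end,
        orientation="+" if orient == "fwd" else "-",
    )


def demux_reads(reads: Iterable[ReadRecord], barcodes: Mapping[str, str],
                params: DemuxParams = DemuxParams()):
    """Partition reads by barcode.

    Returns ``(per_sample, results)`` where ``per_sample`` maps each
    barcode id (plus "unclassified") to its list of reads.
    """
    per_sample = {bc: [] for bc in barcodes}
    per_sample[UNCLASSIFIED] = []
    results = []
    for read in reads:
        res = scan_barcode(read, barcodes, params)
        per_sample[res.sample].append(read)
        results.append(res)
    return per_sample, results


def demux_run(fastq_path, barcodes: Mapping[str, str], out_dir,
              params: DemuxParams = DemuxParams()) -> pd.DataFrame:
    """Demultiplex a FASTQ file into per-sample files plus a summary.

    The summary has one row per sample (and one for unclassified) with
    read count and median best edit distance. Input read count always
    equals the sum of output counts.
    """
    reads = read_fastq(fastq_path)
    per_sample, results = demux_reads(reads, barcodes, params)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    by_sample: dict = {}
    for res in results:
        by_sample.setdefault(res.sample, []).append(res)
    for sample in list(barcodes) + [UNCLASSIFIED]:
        rs = per_sample[sample]
        write_fastq(out_dir / f"{sample}.fastq", rs)
        dists = [r.distance for r in by_sample.get(sample, [])
                 if r.distance is not None]
        rows.append({
            "sample": sample,
            "n_reads": len(rs),
            "median_distance": (float(pd.Series(dists).median())
                                if dists else float("nan")),
        })
    summary = pd.DataFrame(rows)
    assert summary["n_reads"].sum() == len(reads)
    summary.to_csv(out_dir / "demux_summary.tsv", sep="\t", index=False)
    return summary
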
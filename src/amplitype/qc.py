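"""Read quality control and run statistics.

Mean read quality follows the ONT pass/fail convention: Phred symbols
are converted to error probabilities, averaged, and converted back —
not an arithmetic mean of Phred scores. A read passes when its mean Q
reaches the threshold (default 15) and its length falls inside a window
around the expected amplicon size.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = ["ReadRecord", "RunStats", "read_fastq", "write_fastq",
           "mean_read_quality", "filter_reads", "compute_n50", "run_stats",
           "default_length_window"]


@dataclass(frozen=True)
class ReadRecord:
    """A FASTQ read: id, sequence, Phred+33 quality string."""

    id: str
    sequence: str
    quality: str

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"{self.id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.quality)})")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_q(self) -> float:
        return mean_read_quality(self.quality)


def read_fastq(path) -> list:
    """Load a Sanger FASTQ file into :class:`ReadRecord` objects."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in
                       rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq), qual))
    return out


def write_fastq(path, reads: Iterable[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def mean_read_quality(quality: str) -> float:
    """Probability-space mean quality of a Phred+33 string.

    >>> round(mean_read_quality(chr(33+10)*5 + chr(33+20)*5), 2)
    12.6
    """
    if not quality:
        raise ValueError("empty quality string")
    phred = np.frombuffer(quality.encode(), dtype=np.uint8).astype(float) - 33
    if (phred < 0).any():
        raise ValueError("quality symbol below '!'")
    return float(-10.0 * math.log10(np.mean(10.0 ** (-phred / 10.0))))


def default_length_window(amplicon_len: int = 943,
                          frac: tuple = (0.8, 1.25)) -> tuple:
    """Length window ``[0.8, 1.25] x amplicon`` (943 -> [754, 1179])."""
    return (int(amplicon_len * frac[0]), math.ceil(amplicon_len * frac[1]))


def filter_reads(reads: Sequence[ReadRecord], min_q: float = 15.0,
                 length_window: Optional[tuple] = None):
    """Split reads into (passing, rejection log).

    The log holds ``(read, reason)`` pairs, reason being the first rule
    that fired: "quality" then "length". Passing and rejected reads
    partition the input.
    """
    if length_window is None:
        length_window = default_length_window()
    lo, hi = length_window
    passing, rejects = [], []
    for r in reads:
        if r.mean_q < min_q:
            rejects.append((r, "quality"))
        elif not lo <= len(r) <= hi:
            rejects.append((r, "length"))
        else:
            passing.append(r)
    return passing, rejects


def compute_n50(lengths: Sequence[int]) -> int:
    """Smallest L such that reads of length >= L hold >= half of all bases."""
    if len(lengths) == 0:
        raise ValueError("no lengths")
    arr = np.sort(np.asarray(lengths))[::-1]
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, csum[-1] / 2.0)])


@dataclass
class RunStats:
    """Summary statistics of one sequencing run."""

    n_reads: int
    mean_length: float
    n50: int
    fraction_q_pass: float
    min_q: float
    per_sample_counts: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def run_stats(reads: Sequence[ReadRecord], min_q: float = 15.0,
              sample_of: Optional[dict] = None) -> RunStats:
    """Counts, mean length, N50, Q-pass fraction, optional per-sample depth."""
    if not reads:
        raise ValueError("no reads")
    lengths = [len(r) for r in reads]
    n_pass = sum(1 for r in reads if r.mean_q >= min_q)
    counts: dict = {}
    if sample_of:
        for r in reads:
            s = sample_of.get(r.id, "unassigned")
            counts[s] = counts.get(s, 0) + 1
    return RunStats(
        n_reads=len(reads),
        mean_length=float(np.mean(lengths)),
        n50=compute_n50(lengths),
        fraction_q_pass=n_pass / len(reads),
        min_q=min_q,
        per_sample_counts=counts,
    )
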
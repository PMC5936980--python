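"""Synthetic multiplexed nanopore amplicon runs.

Emulates the study design this package targets: diploid samples, a 943 bp
HLA-B exon2+3 amplicon, two-sided barcode tails bringing the barcoded
product to 1,063 bp, heavily skewed per-sample depth, and a legacy-2D
nanopore error profile of ~7.3% total per-base error dominated by
deletions (~3.5%), with deletions further elevated inside short tandem
repeats such as the (GA)3 tract near exon 2 nt 130-136.

Everything is driven by one :class:`numpy.random.Generator` seeded once
per run, so identical seeds give byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .alleles import (
    AlleleRecord,
    MINION_PRIMERS,
    IUPAC_SETS,
    parse_allele_name,
    reverse_complement,
)

__all__ = [
    "ErrorModel",
    "DEFAULT_ERROR_MODEL",
    "SimTruth",
    "SampleTruth",
    "ReadTruth",
    "SimRead",
    "BarcodedTemplate",
    "SimRun",
    "DepthModel",
    "DEFAULT_LEFT_TAIL",
    "DEFAULT_RIGHT_TAIL",
    "synthetic_allele_set",
    "intron_variant",
    "find_str_intervals",
    "repeat_mask_for",
    "make_barcode_set",
    "make_cohort",
    "make_barcoded_template",
    "simulate_read",
    "simulate_run",
    "load_error_model",
]


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ErrorModel:
    """Per-base error rates of the simulated basecaller.

    Defaults follow the R9-chemistry 2D profile: 3.5% deletion with
    substitution and insertion chosen so the components sum to 7.3%
    total. ``repeat_del_multiplier`` scales the deletion rate inside
    annotated short-tandem-repeat intervals, reproducing the
    repeat-associated deletion artifact that breaks phasing around the
    (GA)3 tract.
    """

    p_sub: float = 0.028
    p_ins: float = 0.010
    p_del: float = 0.035
    repeat_del_multiplier: float = 3.0
    read_q_mean: float = 12.0
    read_q_sd: float = 3.0

    def __post_init__(self):
        for name in ("p_sub", "p_ins", "p_del"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.p_sub + self.p_ins + self.p_del > 1.0:
            raise ValueError("p_sub + p_ins + p_del must not exceed 1")
        if self.repeat_del_multiplier < 1.0:
            raise ValueError("repeat_del_multiplier must be >= 1")
        if self.p_del * self.repeat_del_multiplier > 1.0:
            raise ValueError("boosted deletion rate exceeds 1")

    @property
    def p_total(self) -> float:
        return self.p_sub + self.p_ins + self.p_del

    def error_free(self) -> "ErrorModel":
        return replace(self, p_sub=0.0, p_ins=0.0, p_del=0.0)


DEFAULT_ERROR_MODEL = ErrorModel()


def load_error_model(path) -> ErrorModel:
    """Load an :class:`ErrorModel` from a YAML/JSON mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return ErrorModel(**cfg)


# ---------------------------------------------------------------------------
# Synthetic allele references
# ---------------------------------------------------------------------------

# Concrete realizations of the degenerate amplification primers, embedded
# at the amplicon termini so in-silico PCR and primer trimming work on the
# synthetic references exactly as on real amplicons.
_FWD_SITE = "".join(sorted(IUPAC_SETS[c])[0] if c not in "ACGT" else c
                    for c in MINION_PRIMERS.forward)
_REV_SITE = reverse_complement(
    "".join(sorted(IUPAC_SETS[c])[0] if c not in "ACGT" else c
            for c in MINION_PRIMERS.reverse))

AMPLICON_LEN = 943
_EXON2 = (64, 334)    # 270 bp, as for class I exon 2
_EXON3 = (580, 856)   # 276 bp, as for class I exon 3
# (GA)3 context planted at exon2-local 1-based 127..136: GAGAGA + R + GAG,
# the R (A/G at nt 133) being the heterozygous site the repeat artifact hits.
_GA_TRACT_LOCAL = 127
_DEFAULT_NAMES = [
    "B*07:02:01", "B*08:01:01", "B*15:01:01", "B*27:05:02", "B*35:01:01",
    "B*40:01:01", "B*44:02:01", "B*51:01:01", "B*56:02:01", "B*57:01:01",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _random_dna_low_repeat(rng: np.random.Generator, n: int) -> str:
    """Random DNA with bounded local repetitiveness: no homopolymer of
    4+ and no 5-base dinucleotide alternation. Keeps the planted (GA)3
    tract the only deletion-concentrating repeat in a synthetic allele,
    mirroring the single troublesome tract of the modeled locus."""
    out = []
    while len(out) < n:
        b = "ACGT"[rng.integers(0, 4)]
        if len(out) >= 3 and b == out[-1] == out[-2] == out[-3]:
            continue
        if (len(out) >= 4 and b == out[-2] == out[-4]
                and out[-1] == out[-3]):
            continue
        out.append(b)
    return "".join(out)


def synthetic_allele_set(n_alleles: int = 10, seed: int = 20180401,
                         min_exon_distance: int = 3) -> list:
    """Generate a deterministic set of synthetic HLA-B-like amplicons.

    All alleles share one 943 bp backbone carrying the amplification
    primer sites at its termini and a (GA)3 tract inside exon 2; each
    allele gets four private exonic substitutions (pairwise exon distance
    >= 8 > ``min_exon_distance``) plus an A/G state at the nt-133 repeat
    site. Sequence content is synthetic; names reuse common HLA-B allele
    groups purely as labels.
    """
    if n_alleles < 2:
        raise ValueError("need at least 2 alleles")
    rng = np.random.default_rng(seed)
    backbone = list(
        _FWD_SITE
        + _random_dna_low_repeat(rng, _EXON2[0] - len(_FWD_SITE))
        + _random_dna_low_repeat(rng, _EXON2[1] - _EXON2[0])
        + _random_dna_low_repeat(rng, _EXON3[0] - _EXON2[1])
        + _random_dna_low_repeat(rng, _EXON3[1] - _EXON3[0])
        + _random_dna_low_repeat(rng, AMPLICON_LEN - len(_REV_SITE) - _EXON3[1])
        + _REV_SITE
    )
    assert len(backbone) == AMPLICON_LEN
    tract0 = _EXON2[0] + _GA_TRACT_LOCAL - 1
    backbone[tract0:tract0 + 10] = "GAGAGA" + "A" + "GAG"
    site133 = tract0 + 6

    exon_positions = [p for se in (_EXON2, _EXON3) for p in range(*se)
                      if not tract0 - 2 <= p < tract0 + 12]
    picks = rng.choice(len(exon_positions), size=4 * n_alleles, replace=False)

    names = list(_DEFAULT_NAMES[:n_alleles])
    names += [f"B*{60 + i}:01:01" for i in range(n_alleles - len(names))]
    records = []
    for i in range(n_alleles):
        seq = backbone.copy()
        seq[site133] = "G" if i % 2 else "A"
        for j in picks[4 * i:4 * i + 4]:
            p = exon_positions[j]
            alts = [b for b in "ACGT" if b != seq[p]]
            seq[p] = alts[rng.integers(0, 3)]
        records.append(AlleleRecord(
            name=parse_allele_name(names[i]),
            amplicon_seq="".join(seq),
            exon2=_EXON2, exon3=_EXON3,
        ))
    return records


def intron_variant(record: AlleleRecord, new_name: str,
                   offset: int = 40) -> AlleleRecord:
    """An allele identical to ``record`` over exons 2+3 but differing at
    one intron-2 position — i.e. a G-group mate."""
    pos = record.exon2[1] + offset
    if not record.exon2[1] <= pos < record.exon3[0]:
        raise ValueError("offset outside intron 2")
    seq = list(record.amplicon_seq)
    seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
    return replace(record, name=parse_allele_name(new_name),
                   amplicon_seq="".join(seq))


def find_str_intervals(seq: str, max_unit: int = 2, min_copies: int = 3,
                       min_len: int = 6) -> list:
    """Maximal short-tandem-repeat intervals (0-based half-open).

    A position range [s, e) qualifies when it consists of >= min_copies
    tandem copies of a unit of length <= max_unit and spans >= min_len
    bases. Overlapping intervals from different unit sizes are merged.
    """
    n = len(seq)
    raw = []
    for u in range(1, max_unit + 1):
        i = 0
        while i + u < n:
            if seq[i + u] != seq[i]:
                i += 1
                continue
            s = i
            while i + u < n and seq[i + u] == seq[i]:
                i += 1
            e = i + u  # maximal run where seq[j] == seq[j-u]
            if e - s >= min_len and (e - s) // u >= min_copies:
                raw.append((s, e))
            i = max(i, s + 1)
    if not raw:
        return []
    raw.sort()
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def repeat_mask_for(alleles: Iterable[AlleleRecord], pad: int = 3,
                    **kwargs) -> dict:
    """Per-allele STR intervals in amplicon coordinates.

    Intervals are padded by ``pad`` bases each side: aligners place a
    repeat deletion at a canonical (typically rightmost) position, which
    can fall just outside the literal repeat run.
    """
    out = {}
    for r in alleles:
        ivs = find_str_intervals(r.amplicon_seq, **kwargs)
        n = len(r.amplicon_seq)
        out[str(r.name)] = [(max(0, s - pad), min(n, e + pad))
                            for s, e in ivs]
    return out


# ---------------------------------------------------------------------------
# Barcodes, tails and templates
# ---------------------------------------------------------------------------

# Fixed synthetic ligation tails flanking the barcode on each side; with a
# 24 bp barcode at both ends these add 120 bp to the amplicon (943 -> 1,063).
DEFAULT_LEFT_TAIL = "TTGTACTTCGTTCAGTTACGTATTGCTAAGGTTAAG"
DEFAULT_RIGHT_TAIL = "GCAATACGTAACTGAACGAAGTACAAGGTTAACCTA"
BARCODE_LEN = 24


def make_barcode_set(n: int, length: int = BARCODE_LEN, seed: int = 7,
                     min_distance: int = 9) -> dict:
    """``n`` random barcodes, pairwise edit distance >= ``min_distance``."""
    import edlib

    rng = np.random.default_rng(seed)
    barcodes: dict = {}
    attempts = 0
    while len(barcodes) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError("cannot satisfy barcode distance constraint")
        cand = _random_dna(rng, length)
        if all(edlib.align(cand, bc, mode="NW")["editDistance"]
               >= min_distance for bc in barcodes.values()):
            barcodes[f"BC{len(barcodes) + 1:02d}"] = cand
    return barcodes


@dataclass(frozen=True)
class BarcodedTemplate:
    """One haplotype's sequencing template: tails + barcode + amplicon."""

    sample_id: str
    allele_name: str
    sequence: str
    amplicon_span: tuple  # (start, end) of the amplicon within sequence

    def __len__(self) -> int:
        return len(self.sequence)


def make_barcoded_template(record: AlleleRecord, barcode: str,
                           tails: tuple = (DEFAULT_LEFT_TAIL, DEFAULT_RIGHT_TAIL),
                           sample_id: str = "") -> BarcodedTemplate:
    """Assemble ``left_tail + barcode + amplicon + rc(barcode) + right_tail``."""
    left, right = tails
    seq = left + barcode + record.amplicon_seq + reverse_complement(barcode) + right
    start = len(left) + len(barcode)
    return BarcodedTemplate(
        sample_id=sample_id,
        allele_name=str(record.name),
        sequence=seq,
        amplicon_span=(start, start + len(record.amplicon_seq)),
    )


# ---------------------------------------------------------------------------
# Cohort truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleTruth:
    allele_a: str
    allele_b: str
    barcode_id: str


@dataclass(frozen=True)
class ReadTruth:
    sample: str
    allele: str
    strand: str
    n_sub: int
    n_ins: int
    n_del: int


@dataclass
class SimTruth:
    """Ground truth of a simulated run: genotypes, barcodes, per-read errors."""

    samples: dict = field(default_factory=dict)   # sample -> SampleTruth
    barcodes: dict = field(default_factory=dict)  # barcode id -> sequence
    reads: dict = field(default_factory=dict)     # read id -> ReadTruth


def make_cohort(alleles: Sequence[AlleleRecord], n_samples: int,
                barcodes: Optional[Mapping[str, str]] = None,
                allele_freqs: Optional[Sequence[float]] = None,
                homozygote_rate: float = 0.08,
                seed: int = 0) -> SimTruth:
    """Draw diploid genotypes for ``n_samples`` barcoded samples.

    Genotypes are drawn from ``allele_freqs`` (uniform by default); with
    probability ``homozygote_rate`` the second allele is forced equal to
    the first. The default homozygote rate reflects the 4-in-49 fraction
    of the cohort this design emulates.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if barcodes is None:
        barcodes = make_barcode_set(max(n_samples, 49))
    if n_samples > len(barcodes):
        raise ValueError(
            f"{n_samples} samples exceed barcode set size {len(barcodes)}")
    freqs = (np.full(len(alleles), 1.0 / len(alleles))
             if allele_freqs is None else np.asarray(allele_freqs, float))
    if len(freqs) != len(alleles):
        raise ValueError("allele_freqs length mismatch")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError("allele_freqs must sum to 1")
    rng = np.random.default_rng(seed)
    names = [str(r.name) for r in alleles]
    bc_ids = sorted(barcodes)[:n_samples]
    truth = SimTruth(barcodes={b: barcodes[b] for b in bc_ids})
    for i in range(n_samples):
        a = names[rng.choice(len(names), p=freqs)]
        if rng.random() < homozygote_rate:
            b = a
        else:
            b = names[rng.choice(len(names), p=freqs)]
        truth.samples[f"S{i + 1:03d}"] = SampleTruth(a, b, bc_ids[i])
    return truth


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimRead:
    seq: str
    qual: str
    n_sub: int
    n_ins: int
    n_del: int


def _periodic_unit(segment: str, max_unit: int = 2):
    """Unit length of a perfect tandem repeat, or None."""
    for u in range(1, max_unit + 1):
        if len(segment) >= 2 * u and all(segment[i] == segment[i - u]
                                         for i in range(u, len(segment))):
            return u
    return None


def _pure_runs(segment: str, max_unit: int = 2, min_len: int = 6):
    """Maximal perfectly periodic runs within ``segment``.

    Returns ``(start, end, unit)`` triples, local coordinates, smaller
    units taking precedence over overlapping larger-unit runs.
    """
    n = len(segment)
    covered = np.zeros(n, dtype=bool)
    runs = []
    for u in range(1, max_unit + 1):
        i = 0
        while i + u < n:
            if segment[i + u] != segment[i]:
                i += 1
                continue
            s = i
            while i + u < n and segment[i + u] == segment[i]:
                i += 1
            e = i + u
            if e - s >= min_len and not covered[s:e].any():
                runs.append((s, e, u))
                covered[s:e] = True
    return sorted(runs)


def simulate_read(template: str, model: ErrorModel,
                  rng: np.random.Generator, strand: str = "+",
                  str_mask: Sequence[tuple] = ()) -> SimRead:
    """Simulate one noisy read of ``template``.

    Walks the template base by base: each base is deleted with ``p_del``,
    otherwise emitted with substitution probability ``p_sub`` (uniform
    over the three alternatives); after each template position a uniform
    random base is inserted with ``p_ins``.

    Inside ``str_mask`` intervals (template coordinates) deletions are
    elevated to ``repeat_del_multiplier × p_del`` per base. For a
    perfect tandem repeat the extra deletions take the form of
    whole-unit slippage — each repeat unit drops with probability
    ``(multiplier − 1) × p_del × unit`` — reproducing the 2–4 nt
    repeat deletions that break phasing around (GA)n tracts; a
    non-periodic masked interval falls back to an independent per-base
    boost. Either way the expected per-base deletion rate inside the
    mask is ~``multiplier × p_del``.

    Minus-strand reads are reverse-complemented after the walk. The
    quality string is flat at the read's mean Q, drawn from a truncated
    normal.
    """
    n = len(template)
    tarr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
    p_del = np.full(n, model.p_del)
    slip_dels = np.zeros(n, dtype=bool)
    # per-unit slip probability q yields q extra deleted bases per base;
    # dividing by (1 - p_del) compensates overlap with baseline deletions
    # so the total in-run rate is exactly multiplier x p_del
    q = min(1.0, (model.repeat_del_multiplier - 1) * model.p_del
            / max(1e-12, 1.0 - model.p_del))
    for s, e in sorted(str_mask):
        s, e = max(0, s), min(n, e)
        in_run = np.zeros(e - s, dtype=bool)
        for rs, re_, unit in _pure_runs(template[s:e]):
            n_units = (re_ - rs) // unit
            in_run[rs:rs + n_units * unit] = True  # unit remainder boosts per-base
            for k in np.nonzero(rng.random(n_units) < q)[0]:
                slip_dels[s + rs + k * unit:s + rs + (k + 1) * unit] = True
        # non-periodic leftovers of the interval: per-base boost
        boost = np.nonzero(~in_run)[0] + s
        p_del[boost] = min(1.0, model.p_del * model.repeat_del_multiplier)
    dels = (rng.random(n) < p_del) | slip_dels
    subs = (rng.random(n) < model.p_sub) & ~dels
    ins = rng.random(n) < model.p_ins

    # substitution: shift within ACGT by 1..3, uniform over alternatives
    lut = np.zeros(256, dtype=np.uint8)
    lut[_BASES] = np.arange(4)
    idx = lut[tarr]
    n_sub = int(subs.sum())
    if n_sub:
        idx[subs] = (idx[subs] + rng.integers(1, 4, size=n_sub)) % 4
    emitted = _BASES[idx]

    n_ins = int(ins.sum())
    ins_bases = _BASES[rng.integers(0, 4, size=n_ins)] if n_ins else None

    keep = ~dels
    counts = keep.astype(np.int64) + ins
    starts = np.zeros(n, dtype=np.int64)
    np.cumsum(counts[:-1], out=starts[1:])
    out = np.empty(int(counts.sum()), dtype=np.uint8)
    out[starts[keep]] = emitted[keep]
    if n_ins:
        out[(starts + keep)[ins]] = ins_bases
    seq = out.tobytes().decode()
    if strand == "-":
        seq = reverse_complement(seq)
    q = int(round(float(np.clip(rng.normal(model.read_q_mean, model.read_q_sd),
                                2.0, 30.0))))
    return SimRead(seq=seq, qual=chr(33 + q) * len(seq), n_sub=n_sub,
                   n_ins=n_ins, n_del=int(dels.sum()))


# ---------------------------------------------------------------------------
# Depth models and whole runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthModel:
    """Per-sample read-count distribution.

    ``constant`` gives every sample the same depth. ``lognormal``
    emulates the heavy per-sample skew seen in multiplexed runs (aligned
    depths spanning 80 to ~17,000 reads); defaults are scaled for desk
    use, clipped at the 80-read floor that still yields confident calls.
    """

    kind: str = "constant"
    depth: int = 100
    median: float = 2000.0
    sigma: float = 1.3
    min_depth: int = 80
    max_depth: int = 17500

    @classmethod
    def constant(cls, depth: int) -> "DepthModel":
        return cls(kind="constant", depth=depth)

    @classmethod
    def lognormal(cls, median: float = 2000.0, sigma: float = 1.3,
                  min_depth: int = 80, max_depth: int = 17500) -> "DepthModel":
        return cls(kind="lognormal", median=median, sigma=sigma,
                   min_depth=min_depth, max_depth=max_depth)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "constant":
            return np.full(n, self.depth, dtype=np.int64)
        if self.kind == "lognormal":
            d = rng.lognormal(np.log(self.median), self.sigma, size=n)
            return np.clip(d, self.min_depth, self.max_depth).astype(np.int64)
        raise ValueError(f"unknown depth model kind {self.kind!r}")


@dataclass
class SimRun:
    """All reads of one simulated run plus their ground truth."""

    reads: list                 # list of (read_id, seq, qual) in file order
    truth: SimTruth

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for rid, seq, qual in self.reads:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tsample\tallele\tstrand\tn_sub\tn_ins\tn_del\n")
            for rid, _, _ in self.reads:
                t = self.truth.reads[rid]
                fh.write(f"{rid}\t{t.sample}\t{t.allele}\t{t.strand}\t"
                         f"{t.n_sub}\t{t.n_ins}\t{t.n_del}\n")


def simulate_run(truth: SimTruth, alleles: Sequence[AlleleRecord],
                 error_model: ErrorModel = DEFAULT_ERROR_MODEL,
                 depth_model: DepthModel = DepthModel.constant(100),
                 seed: int = 0,
                 tails: tuple = (DEFAULT_LEFT_TAIL, DEFAULT_RIGHT_TAIL),
                 mask_repeats: bool = True) -> SimRun:
    """Simulate a multiplexed run for a cohort drawn by :func:`make_cohort`.

    Each read picks a haplotype and a strand uniformly; reads from all
    samples are emitted in one shuffled stream, as on a real flow cell.
    With ``mask_repeats`` the deletion boost applies inside every STR
    interval of each template.
    """
    by_name = {str(r.name): r for r in alleles}
    for st in truth.samples.values():
        for a in (st.allele_a, st.allele_b):
            if a not in by_name:
                raise ValueError(f"truth references unknown allele {a}")
    rng = np.random.default_rng(seed)
    sample_ids = sorted(truth.samples)
    depths = depth_model.draw(rng, len(sample_ids))

    reads = []
    read_truth = {}
    i = 0
    for sample, depth in zip(sample_ids, depths):
        st = truth.samples[sample]
        bc = truth.barcodes[st.barcode_id]
        templates = []
        for allele in (st.allele_a, st.allele_b):
            tpl = make_barcoded_template(by_name[allele], bc, tails, sample)
            off = tpl.amplicon_span[0]
            mask = ([(s + off, e + off) for s, e in
                     find_str_intervals(by_name[allele].amplicon_seq)]
                    if mask_repeats else [])
            templates.append((allele, tpl.sequence, mask))
        haps = rng.integers(0, 2, size=depth)
        strands = rng.integers(0, 2, size=depth)
        for h, s in zip(haps, strands):
            allele, tseq, mask = templates[h]
            strand = "+-"[s]
            sim = simulate_read(tseq, error_model, rng, strand, mask)
            rid = f"r{i:07d}"
            i += 1
            reads.append((rid, sim.seq, sim.qual))
            read_truth[rid] = ReadTruth(sample, allele, strand,
                                        sim.n_sub, sim.n_ins, sim.n_del)
    order = rng.permutation(len(reads))
    run_truth = SimTruth(samples=dict(truth.samples),
                         barcodes=dict(truth.barcodes), reads=read_truth)
    return SimRun(reads=[reads[j] for j in order], truth=run_truth)
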
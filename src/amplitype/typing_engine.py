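"""Allele-pair genotyping from amplicon reads.

The caller mirrors how ranked-mismatch HLA typing is done in practice:

1. orient and primer-trim each read;
2. shortlist candidate alleles by per-read minimum-edit-distance votes;
3. for every unordered candidate pair (self-pairs included), partition
   the reads between the two alleles by alignment distance, build one
   consensus per allele, and count consensus-versus-reference edits
   restricted to exon 2+3 columns;
4. rank pairs by total mismatches (ties broken toward balanced read
   support) and call the best pair, mapping names through G-groups;
5. report recurring mismatch positions as hotspots, flagging those
   inside short-tandem-repeat masks, and optionally rescore pairs with
   masked columns excluded to adjudicate repeat-driven artifacts.

A genotype whose best pair still shows mismatches is annotated
``manual-review`` and ships its full ranked list, the behavior a human
analyst relies on to hand-pick the least-mismatch pair.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np

from .alleles import (
    AlleleRecord,
    GGroupMap,
    IUPAC_SETS,
    MINION_PRIMERS,
    PrimerPair,
    reverse_complement,
)

__all__ = [
    "TypingParams", "DepthError", "AlignmentResult", "ConsensusResult",
    "PairScore", "GenotypeCall", "Hotspot",
    "align_read", "orient_and_trim", "shortlist_alleles", "build_consensus",
    "score_pair", "call_genotype", "find_hotspots", "rescore_masked",
    "adjudicate_with_mask",
]

_IUPAC_EQUALITIES = [(code, base)
                     for code, bases in IUPAC_SETS.items()
                     if code not in "ACGT"
                     for base in bases]


class DepthError(RuntimeError):
    """Too few reads to call a genotype."""


@dataclass(frozen=True)
class TypingParams:
    """Tunables of the genotyping engine.

    ``min_depth`` is a refusal floor (confident calls have been shown
    down to 80 reads; 20 is a floor, not a claim). ``minor_fraction`` is
    the minimum share of assignable reads the rarer member of a pair
    must attract before the pair is demoted to the majority homozygote,
    guarding against allele-dropout mimicry. ``k`` is the shortlist
    size. ``het_fraction`` is the minor-base fraction above which a
    consensus column is treated as mixed — evidence that one reference
    cannot explain the reads, the pileup analogue of an IUPAC ambiguity
    code in a Sanger trace; mixed columns count as mismatches.
    """

    k: int = 6
    min_depth: int = 20
    minor_fraction: float = 0.2
    max_primer_edit_frac: float = 0.25
    het_fraction: float = 0.22
    min_het_coverage: int = 6


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _parse_cigar(cigar: str):
    num = 0
    for ch in cigar:
        if ch.isdigit():
            num = num * 10 + ord(ch) - 48
        else:
            yield num, ch
            num = 0


@dataclass
class AlignmentResult:
    """Semi-global alignment of a read against one allele amplicon.

    Coordinates are 0-based on the allele; ``t_start``/``t_end`` bound
    the aligned allele interval (half-open). ``diffs`` lists the
    non-match events: ``("sub", col, base)``, ``("del", col, None)`` per
    deleted allele column, and ``("ins", col, seq)`` for read bases
    inserted before allele column ``col``.
    """

    allele: str
    distance: int
    cigar: str
    t_start: int
    t_end: int
    read: str

    @cached_property
    def diffs(self) -> list:
        events = []
        tpos, qpos = self.t_start, 0
        for n, op in _parse_cigar(self.cigar):
            if op == "=":
                tpos += n
                qpos += n
            elif op == "X":
                for i in range(n):
                    events.append(("sub", tpos + i, self.read[qpos + i]))
                tpos += n
                qpos += n
            elif op == "D":
                for i in range(n):
                    events.append(("del", tpos + i, None))
                tpos += n
            elif op == "I":
                events.append(("ins", tpos, self.read[qpos:qpos + n]))
                qpos += n
            else:  # pragma: no cover - edlib emits only =XDI
                raise ValueError(f"unexpected cigar op {op!r}")
        return events

    @property
    def n_ops(self) -> dict:
        c = Counter()
        for kind, _, detail in self.diffs:
            c[kind] += len(detail) if kind == "ins" else 1
        return dict(c)

    @property
    def mismatch_positions(self) -> list:
        return sorted({col for _, col, _ in self.diffs})

    def exon_mismatch_count(self, record: AlleleRecord) -> int:
        spans = (record.exon2, record.exon3)
        total = 0
        for kind, col, detail in self.diffs:
            if any(s <= col < e for s, e in spans):
                total += len(detail) if kind == "ins" else 1
        return total


def align_read(read: str, record: AlleleRecord) -> AlignmentResult:
    """Align a (trimmed, plus-strand) read to one allele amplicon.

    Semi-global with free end gaps on the allele, so partial reads pay
    nothing for the allele sequence they do not cover; residual tail
    bases on the read surface as terminal insertions.
    """
    if not read:
        raise ValueError("empty read")
    res = edlib.align(read, record.amplicon_seq, mode="HW", task="path")
    start, end = res["locations"][0]
    return AlignmentResult(
        allele=str(record.name),
        distance=res["editDistance"],
        cigar=res["cigar"],
        t_start=start,
        t_end=end + 1,
        read=read,
    )


def orient_and_trim(seq: str, primers: PrimerPair = MINION_PRIMERS,
                    max_edit_frac: float = 0.25):
    """Orient a raw read to the plus strand and trim to the primer span.

    Locates the forward primer and the reverse-primer binding site
    (IUPAC-aware) on both strands; the orientation with the lower total
    edit distance wins. Returns ``(trimmed_seq, strand)``; when either
    primer cannot be placed within ``max_edit_frac`` of its length the
    read is returned untrimmed with strand ``"?"``.
    """
    rev_site = reverse_complement(primers.reverse)
    best = None
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        f = edlib.align(primers.forward, s, mode="HW", task="locations",
                        additionalEqualities=_IUPAC_EQUALITIES)
        r = edlib.align(rev_site, s, mode="HW", task="locations",
                        additionalEqualities=_IUPAC_EQUALITIES)
        f_loc = f["locations"][0]
        r_loc = max(r["locations"], key=lambda lo: lo[1])
        score = f["editDistance"] + r["editDistance"]
        if best is None or score < best[0]:
            best = (score, strand, s, f["editDistance"], r["editDistance"],
                    f_loc, r_loc)
    _, strand, s, fd, rd, f_loc, r_loc = best
    limit_f = int(len(primers.forward) * max_edit_frac)
    limit_r = int(len(rev_site) * max_edit_frac)
    if fd > limit_f or rd > limit_r or r_loc[1] <= f_loc[0]:
        return seq, "?"
    return s[f_loc[0]:r_loc[1] + 1], strand


def shortlist_alleles(reads: Sequence[str], alleles: Sequence[AlleleRecord],
                      k: int = 6) -> list:
    """Candidate alleles by per-read minimum-distance voting.

    Each read votes for its minimum-edit-distance allele(s); alleles are
    ranked by votes and the top ``k`` returned, plus any allele whose
    vote count is within 10% of the k-th.
    """
    if not reads:
        raise ValueError("no reads to vote")
    if k < 2:
        raise ValueError("k must be >= 2")
    names = [str(r.name) for r in alleles]
    votes = Counter()
    for read in reads:
        dists = [edlib.align(read, rec.amplicon_seq, mode="HW")["editDistance"]
                 for rec in alleles]
        m = min(dists)
        for name, d in zip(names, dists):
            if d == m:
                votes[name] += 1
    ranked = sorted(names, key=lambda n: (-votes[n], n))
    if k >= len(ranked):
        chosen = ranked
    else:
        cutoff = votes[ranked[k - 1]]
        chosen = [n for i, n in enumerate(ranked)
                  if i < k or votes[n] >= 0.9 * cutoff]
    by_name = {str(r.name): r for r in alleles}
    return [by_name[n] for n in chosen]


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

@dataclass
class ConsensusResult:
    """Majority-vote consensus of reads over one allele's columns.

    ``events`` are the consensus-versus-reference edits; ``mixed``
    lists columns whose minor base/gap fraction exceeded the mixture
    threshold even though the majority stayed on the reference — the
    signature of a heterozygous mixture (or of a concentrated repeat
    deletion artifact) that a single reference cannot explain.
    """

    allele: str
    sequence: str
    events: list          # (kind, col, detail) consensus-vs-reference edits
    mixed: list           # (col, minor_fraction) mixed-pileup columns
    n_reads: int

    def mismatches(self, record: AlleleRecord,
                   exclude: Sequence[tuple] = ()) -> tuple:
        """(edit count, positions) restricted to exon 2+3 columns.

        Mixed columns count one mismatch each. ``exclude`` intervals
        (allele coordinates) are left out of the count — used for
        repeat-masked rescoring.
        """
        spans = (record.exon2, record.exon3)

        def in_exons(col):
            return any(s <= col < e for s, e in spans)

        def excluded(col):
            return any(s <= col < e for s, e in exclude)

        total, positions = 0, []
        event_cols = set()
        for kind, col, detail in self.events:
            event_cols.add(col)
            if not in_exons(col) or excluded(col):
                continue
            total += len(detail) if kind == "ins" else 1
            positions.append(col)
        for col, _frac in self.mixed:
            if col in event_cols or not in_exons(col) or excluded(col):
                continue
            total += 1
            positions.append(col)
        return total, sorted(set(positions))


def _consensus_from_alignments(alns: Sequence[AlignmentResult],
                               record: AlleleRecord,
                               het_fraction: float = 0.22,
                               min_het_coverage: int = 6) -> ConsensusResult:
    L = len(record.amplicon_seq)
    cov_d = np.zeros(L + 1, dtype=np.int64)
    jcov_d = np.zeros(L + 2, dtype=np.int64)
    subs: dict = {}
    dels = Counter()
    ins_seqs: dict = {}
    ins_reads = Counter()
    for a in alns:
        cov_d[a.t_start] += 1
        cov_d[a.t_end] -= 1
        jcov_d[a.t_start + 1] += 1
        jcov_d[a.t_end] -= 1
        seen_ins = set()
        for kind, col, detail in a.diffs:
            if kind == "sub":
                subs.setdefault(col, Counter())[detail] += 1
            elif kind == "del":
                dels[col] += 1
            else:
                ins_seqs.setdefault(col, Counter())[detail] += 1
                if col not in seen_ins:
                    ins_reads[col] += 1
                    seen_ins.add(col)
    coverage = np.cumsum(cov_d[:-1])
    jcov = np.cumsum(jcov_d[:-1])

    events = []
    mixed = []
    for col in sorted(set(subs) | set(dels)):
        cov = int(coverage[col])
        ref = record.amplicon_seq[col]
        alt_counts = subs.get(col, Counter())
        ref_count = cov - sum(alt_counts.values()) - dels[col]
        # majority among {A,C,G,T,gap}; ties resolved toward the reference
        candidates = [(ref_count, 1, ref)]
        candidates += [(n, 0, b) for b, n in sorted(alt_counts.items())]
        if dels[col]:
            candidates.append((dels[col], 0, None))
        candidates.sort(key=lambda c: (c[0], c[1]), reverse=True)
        winner = candidates[0]
        if winner[2] is None:
            events.append(("del", col, None))
        elif winner[2] != ref:
            events.append(("sub", col, winner[2]))
        elif cov >= min_het_coverage and len(candidates) > 1:
            second = candidates[1][0]
            # absolute floor of 3 reads keeps low-coverage columns honest
            if second >= max(3, het_fraction * cov):
                mixed.append((col, second / cov))
    for col in sorted(ins_reads):
        overlap = int(jcov[col]) if col < L else 0
        if overlap and ins_reads[col] > 0.5 * overlap:
            seq = min(ins_seqs[col].items(), key=lambda kv: (-kv[1], kv[0]))[0]
            events.append(("ins", col, seq))

    by_col: dict = {}
    for kind, col, detail in events:
        by_col.setdefault(col, []).append((kind, detail))
    parts = []
    for col, ref in enumerate(record.amplicon_seq):
        here = by_col.get(col, [])
        for kind, detail in here:
            if kind == "ins":
                parts.append(detail)
        base = ref
        for kind, detail in here:
            if kind == "del":
                base = ""
            elif kind == "sub":
                base = detail
        parts.append(base)
    return ConsensusResult(
        allele=str(record.name),
        sequence="".join(parts),
        events=sorted(events, key=lambda e: (e[1], e[0])),
        mixed=mixed,
        n_reads=len(alns),
    )


def build_consensus(reads: Sequence[str], record: AlleleRecord,
                    het_fraction: float = 0.22,
                    min_het_coverage: int = 6) -> ConsensusResult:
    """Majority-vote consensus of ``reads`` over ``record``'s columns.

    Per column the majority among {A, C, G, T, gap} wins, ties breaking
    toward the reference base; a gap majority deletes the column.
    Insertions are retained only when supported by more than half of the
    reads overlapping the junction. Columns where the runner-up
    base/gap exceeds ``het_fraction`` of the coverage are flagged as
    mixed.
    """
    if not reads:
        raise ValueError("need at least one read")
    alns = [align_read(r, record) for r in reads]
    return _consensus_from_alignments(alns, record, het_fraction,
                                      min_het_coverage)


# ---------------------------------------------------------------------------
# Pair scoring
# ---------------------------------------------------------------------------

@dataclass
class PairScore:
    """Consensus-vs-reference mismatch score of one unordered allele pair."""

    a: str
    b: str
    n_a: int
    n_b: int
    n_unassigned: int
    consensus_a: ConsensusResult
    consensus_b: ConsensusResult
    mismatches_a: int
    mismatches_b: int
    positions_a: list
    positions_b: list
    demoted_from: Optional[tuple] = None

    @property
    def total(self) -> int:
        return self.mismatches_a + self.mismatches_b

    @property
    def support(self) -> int:
        return self.n_a + self.n_b

    @property
    def pair(self) -> tuple:
        return (self.a, self.b)

    @property
    def is_homozygous(self) -> bool:
        return self.a == self.b


class _AlignCache:
    def __init__(self):
        self._store: dict = {}

    def get(self, idx: int, read: str, record: AlleleRecord) -> AlignmentResult:
        key = (idx, str(record.name))
        if key not in self._store:
            self._store[key] = align_read(read, record)
        return self._store[key]


def score_pair(reads: Sequence[str], a: AlleleRecord, b: AlleleRecord,
               params: TypingParams = TypingParams(),
               mask: Optional[Mapping[str, Sequence[tuple]]] = None,
               _cache: Optional[_AlignCache] = None) -> PairScore:
    """Score one allele pair against a sample's reads.

    Reads go to the member with the smaller edit distance; equidistant
    reads are unassignable (counted for depth, excluded from consensus).
    When the rarer member draws less than ``minor_fraction`` of the
    assignable reads the pair is demoted to the homozygous pair of the
    majority member. Mismatches are consensus-vs-reference edits over
    exon 2+3 columns only, optionally excluding ``mask`` intervals.
    """
    if not reads:
        raise ValueError("no reads")
    cache = _cache or _AlignCache()
    if str(a.name) > str(b.name):
        a, b = b, a
    if str(a.name) == str(b.name):
        alns = [cache.get(i, r, a) for i, r in enumerate(reads)]
        cons = _consensus_from_alignments(alns, a, params.het_fraction,
                                          params.min_het_coverage)
        excl = tuple(mask.get(str(a.name), ())) if mask else ()
        m, pos = cons.mismatches(a, excl)
        return PairScore(
            a=str(a.name), b=str(b.name),
            n_a=len(reads), n_b=len(reads), n_unassigned=0,
            consensus_a=cons, consensus_b=cons,
            mismatches_a=m, mismatches_b=m,
            positions_a=pos, positions_b=pos,
        )

    to_a, to_b = [], []
    n_un = 0
    for i, r in enumerate(reads):
        aln_a = cache.get(i, r, a)
        aln_b = cache.get(i, r, b)
        if aln_a.distance < aln_b.distance:
            to_a.append(aln_a)
        elif aln_b.distance < aln_a.distance:
            to_b.append(aln_b)
        else:
            n_un += 1
    assignable = len(to_a) + len(to_b)
    if assignable and min(len(to_a), len(to_b)) < params.minor_fraction * assignable:
        major = a if len(to_a) >= len(to_b) else b
        demoted = score_pair(reads, major, major, params, mask, cache)
        demoted.demoted_from = (str(a.name), str(b.name))
        return demoted

    cons_a = _consensus_from_alignments(to_a, a, params.het_fraction,
                                        params.min_het_coverage)
    cons_b = _consensus_from_alignments(to_b, b, params.het_fraction,
                                        params.min_het_coverage)
    excl_a = tuple(mask.get(str(a.name), ())) if mask else ()
    excl_b = tuple(mask.get(str(b.name), ())) if mask else ()
    m_a, pos_a = cons_a.mismatches(a, excl_a)
    m_b, pos_b = cons_b.mismatches(b, excl_b)
    return PairScore(
        a=str(a.name), b=str(b.name),
        n_a=len(to_a), n_b=len(to_b), n_unassigned=n_un,
        consensus_a=cons_a, consensus_b=cons_b,
        mismatches_a=m_a, mismatches_b=m_b,
        positions_a=pos_a, positions_b=pos_b,
    )


def rescore_masked(reads: Sequence[str], a: AlleleRecord, b: AlleleRecord,
                   repeat_mask: Mapping[str, Sequence[tuple]],
                   params: TypingParams = TypingParams()) -> PairScore:
    """:func:`score_pair` with repeat-masked exon columns excluded.

    Used to adjudicate manual-review calls whose mismatches are driven
    by repeat-associated deletion errors.
    """
    return score_pair(reads, a, b, params, mask=repeat_mask)


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCall:
    """Ranked allele-pair scores and the called diploid genotype."""

    sample_id: str
    ranked: list                     # PairScore, best first
    best: PairScore
    zygosity: str                    # "homozygous" / "heterozygous"
    ambiguous: bool                  # >= 2 distinct co-best pairs
    reported: tuple                  # names after G-group mapping
    manual_review: bool              # best pair still has mismatches
    n_reads: int
    hotspots: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sample": self.sample_id,
            "allele1": self.reported[0],
            "allele2": self.reported[1],
            "zygosity": self.zygosity,
            "ambiguous": self.ambiguous,
            "manual_review": self.manual_review,
            "total_mismatches": self.best.total,
            "depth": {"allele1": self.best.n_a, "allele2": self.best.n_b,
                      "unassigned": self.best.n_unassigned},
            "ranked": [
                {"pair": p.pair, "total": p.total,
                 "support": [p.n_a, p.n_b],
                 "positions": [p.positions_a, p.positions_b]}
                for p in self.ranked
            ],
            "hotspots": [h.__dict__ for h in self.hotspots],
        }


def _rank_key(p: PairScore):
    return (p.total, -min(p.n_a, p.n_b), -p.support, p.pair)


def call_genotype(reads: Sequence[str], alleles: Sequence[AlleleRecord],
                  ggroups: Optional[GGroupMap] = None,
                  params: TypingParams = TypingParams(),
                  sample_id: str = "",
                  pre_trimmed: bool = False,
                  allow_low_depth: bool = False,
                  repeat_mask: Optional[Mapping[str, Sequence[tuple]]] = None
                  ) -> GenotypeCall:
    """Call a diploid genotype from one sample's reads.

    Enumerates all unordered pairs (self-pairs included) over the
    shortlist, scores each, and ranks by ascending total mismatches with
    ties broken toward balanced read support. A best pair with any
    remaining mismatch is annotated for manual review and the full
    ranked list is retained. Raises :class:`DepthError` below
    ``params.min_depth`` unless ``allow_low_depth``.
    """
    if len(reads) < params.min_depth and not allow_low_depth:
        raise DepthError(
            f"{sample_id or 'sample'}: {len(reads)} reads < "
            f"min_depth {params.min_depth} (pass allow_low_depth to override)")
    if not reads:
        raise DepthError("no reads at all")

    if pre_trimmed:
        trimmed = list(reads)
    else:
        trimmed = [orient_and_trim(r, max_edit_frac=params.max_primer_edit_frac)[0]
                   for r in reads]

    candidates = shortlist_alleles(trimmed, alleles, k=params.k)
    cache = _AlignCache()
    scores: dict = {}
    for a, b in itertools.combinations_with_replacement(
            sorted(candidates, key=lambda r: str(r.name)), 2):
        ps = score_pair(trimmed, a, b, params, mask=None, _cache=cache)
        if ps.pair not in scores:
            scores[ps.pair] = ps
    ranked = sorted(scores.values(), key=_rank_key)
    best = ranked[0]
    # co-best = tied on mismatches AND read support (a zero-mismatch pair
    # with no assignable reads is unsupported, not a competing call)
    ambiguous = sum(1 for p in ranked
                    if _rank_key(p)[:3] == _rank_key(best)[:3]) > 1
    gmap = ggroups or GGroupMap()
    reported = tuple(gmap.report_name(n) for n in best.pair)
    call = GenotypeCall(
        sample_id=sample_id,
        ranked=ranked,
        best=best,
        zygosity="homozygous" if best.is_homozygous else "heterozygous",
        ambiguous=ambiguous,
        reported=reported,
        manual_review=best.total > 0,
        n_reads=len(reads),
    )
    if repeat_mask is not None:
        by_name = {str(r.name): r for r in alleles}
        call.hotspots = find_hotspots(ranked, repeat_mask, by_name)
    return call


# ---------------------------------------------------------------------------
# Hotspots and masked adjudication
# ---------------------------------------------------------------------------

@dataclass
class Hotspot:
    """A mismatch position recurring across top-ranked pairs."""

    exon: str
    position: int        # 1-based within the exon
    n_pairs: int         # how many of the inspected pairs show it
    repeat_associated: bool


def find_hotspots(ranked: Sequence[PairScore],
                  repeat_mask: Mapping[str, Sequence[tuple]],
                  alleles_by_name: Mapping[str, AlleleRecord],
                  top_n: int = 5, min_recurrence: float = 0.5) -> list:
    """Systematic mismatch positions across the top-ranked pairs.

    A position (in 1-based exon-local coordinates, comparable across
    alleles) is a hotspot when it recurs in at least ``min_recurrence``
    of the ``top_n`` best pairs; positions inside the repeat mask of the
    allele they were seen on are labeled repeat-associated.
    """
    if not ranked:
        raise ValueError("no pair scores")
    top = ranked[:top_n]
    seen_in: dict = {}
    repeat_flag: dict = {}
    for p in top:
        keys = set()
        for member, positions in ((p.a, p.positions_a), (p.b, p.positions_b)):
            rec = alleles_by_name[member]
            mask_iv = repeat_mask.get(member, ())
            for col in positions:
                exon, local = rec.exon_local(col)
                if exon is None:
                    continue
                key = (exon, local)
                keys.add(key)
                if any(s <= col < e for s, e in mask_iv):
                    repeat_flag[key] = True
        for key in keys:
            seen_in[key] = seen_in.get(key, 0) + 1
    threshold = min_recurrence * len(top)
    return [Hotspot(exon=k[0], position=k[1], n_pairs=n,
                    repeat_associated=repeat_flag.get(k, False))
            for k, n in sorted(seen_in.items()) if n >= threshold]


def adjudicate_with_mask(call: GenotypeCall, reads: Sequence[str],
                         alleles: Sequence[AlleleRecord],
                         repeat_mask: Mapping[str, Sequence[tuple]],
                         params: TypingParams = TypingParams(),
                         top_n: int = 10, pre_trimmed: bool = False) -> tuple:
    """Re-rank a call's top pairs with repeat-masked scoring.

    Returns ``(best_pair_names, masked PairScore)`` after rescoring the
    ``top_n`` ranked pairs with masked exon columns excluded; the
    automatic counterpart of manually adjudicating a repeat artifact.
    """
    by_name = {str(r.name): r for r in alleles}
    if pre_trimmed:
        trimmed = list(reads)
    else:
        trimmed = [orient_and_trim(r, max_edit_frac=params.max_primer_edit_frac)[0]
                   for r in reads]
    rescored = []
    for p in call.ranked[:top_n]:
        ps = rescore_masked(trimmed, by_name[p.a], by_name[p.b],
                            repeat_mask, params)
        rescored.append(ps)
    rescored.sort(key=_rank_key)
    return rescored[0].pair, rescored[0]
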
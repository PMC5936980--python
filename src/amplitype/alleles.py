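"""Allele reference handling for HLA amplicon typing.

HLA alleles are named ``LOCUS*f1:f2[:f3[:f4]][suffix][G]`` where the
colon-separated numeric fields encode allele group, protein, synonymous
coding change and non-coding change. Class I typing that reads only exons
2 and 3 (the peptide-binding domain) cannot distinguish alleles that are
identical across those exons; such alleles are reported together as a
*G-group*, named after the numerically smallest member truncated to three
fields with a trailing ``G``.

This module loads amplicon reference sequences with their exon
coordinates, parses and formats allele names, constructs G-groups, and
performs IUPAC-degenerate in-silico PCR to derive amplicon references
from longer templates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "AlleleName",
    "AlleleRecord",
    "GGroupMap",
    "PrimerPair",
    "MINION_PRIMERS",
    "IUPAC_SETS",
    "parse_allele_name",
    "load_allele_set",
    "build_ggroups",
    "iupac_match",
    "in_silico_pcr",
    "reverse_complement",
    "AlleleParseError",
    "AlleleSetError",
    "AmplificationError",
]


class AlleleParseError(ValueError):
    """An allele name string does not follow HLA nomenclature."""


class AlleleSetError(ValueError):
    """A reference FASTA / exon sidecar pair is inconsistent."""


class AmplificationError(ValueError):
    """In-silico PCR found no product."""


# IUPAC nucleotide codes -> the set of concrete bases each denotes.
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_SUFFIXES = frozenset("NLSCAQ")

_NAME_RE = re.compile(
    r"^(?P<locus>[A-Za-z][A-Za-z0-9]*)\*(?P<fields>\d+(?::\d+)*)"
    r"(?P<suffix>[NLSCAQ]?)(?P<g>G?)$"
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=False)
class AlleleName:
    """A parsed HLA allele name such as ``B*40:01:01G``."""

    locus: str
    fields: tuple
    suffix: str = ""
    g_flag: bool = False

    def __post_init__(self):
        if not self.fields:
            raise AlleleParseError("allele name needs at least one field")
        if any((not isinstance(f, int)) or f < 0 for f in self.fields):
            raise AlleleParseError(f"non-numeric field in {self.fields!r}")
        if self.suffix and self.suffix not in _SUFFIXES:
            raise AlleleParseError(f"invalid expression suffix {self.suffix!r}")
        if self.g_flag and len(self.fields) != 3:
            raise AlleleParseError(
                f"G-group names are three-field; got {len(self.fields)} fields"
            )

    def __str__(self) -> str:
        body = ":".join(f"{f:02d}" for f in self.fields)
        return f"{self.locus}*{body}{self.suffix}{'G' if self.g_flag else ''}"

    def __lt__(self, other: "AlleleName") -> bool:
        return (self.locus, self.fields, self.suffix, self.g_flag) < (
            other.locus, other.fields, other.suffix, other.g_flag)

    def truncate(self, n_fields: int) -> "AlleleName":
        """Drop fields beyond ``n_fields`` (also drops suffix and G flag)."""
        return AlleleName(self.locus, self.fields[:n_fields])


def parse_allele_name(text: str) -> AlleleName:
    """Parse an HLA allele name string.

    >>> parse_allele_name("B*40:01:01G").fields
    (40, 1, 1)
    """
    if not text:
        raise AlleleParseError("empty allele name")
    if "*" not in text:
        raise AlleleParseError(f"{text!r}: missing '*' after locus")
    m = _NAME_RE.match(text.strip())
    if m is None:
        raise AlleleParseError(f"{text!r}: not a valid allele name")
    fields = tuple(int(f) for f in m.group("fields").split(":"))
    if len(fields) > 4:
        raise AlleleParseError(f"{text!r}: more than 4 fields")
    try:
        return AlleleName(m.group("locus"), fields, m.group("suffix"),
                          m.group("g") == "G")
    except AlleleParseError as exc:
        raise AlleleParseError(f"{text!r}: {exc}") from None


@dataclass(frozen=True)
class AlleleRecord:
    """A named allele with its amplicon sequence and exon intervals.

    Intervals are 0-based half-open on the amplicon; exon 2 precedes
    exon 3 and they do not overlap.
    """

    name: AlleleName
    amplicon_seq: str
    exon2: tuple
    exon3: tuple

    def __post_init__(self):
        seq = self.amplicon_seq
        if set(seq) - set("ACGT"):
            bad = sorted(set(seq) - set("ACGT"))
            raise AlleleSetError(f"{self.name}: non-ACGT characters {bad}")
        for label, (s, e) in (("exon2", self.exon2), ("exon3", self.exon3)):
            if not (0 <= s < e <= len(seq)):
                raise AlleleSetError(
                    f"{self.name}: {label} interval {(s, e)} outside "
                    f"sequence of length {len(seq)}")
        if self.exon2[1] > self.exon3[0]:
            raise AlleleSetError(
                f"{self.name}: exon2 must precede exon3 without overlap")

    @property
    def exon_seq(self) -> str:
        """Concatenated exon2+exon3 sequence (the typed region)."""
        return (self.amplicon_seq[slice(*self.exon2)]
                + self.amplicon_seq[slice(*self.exon3)])

    def exon_local(self, pos: int):
        """Map an amplicon coordinate to (exon label, 1-based local pos).

        Returns ``(None, None)`` for positions outside both exons.
        """
        if self.exon2[0] <= pos < self.exon2[1]:
            return "exon2", pos - self.exon2[0] + 1
        if self.exon3[0] <= pos < self.exon3[1]:
            return "exon3", pos - self.exon3[0] + 1
        return None, None


@dataclass
class GGroupMap:
    """Partition of an allele set into groups with identical exon2+3."""

    allele_to_group: dict = field(default_factory=dict)
    groups: dict = field(default_factory=dict)

    def report_name(self, allele_name) -> str:
        """Group name under which ``allele_name`` is reported."""
        return self.allele_to_group.get(str(allele_name), str(allele_name))


def build_ggroups(alleles: Sequence[AlleleRecord]) -> GGroupMap:
    """Partition alleles by exact exon2+exon3 sequence identity.

    Multi-member groups are named after the numerically smallest member,
    truncated to three fields, with ``G`` appended; singleton groups keep
    the member's own name unchanged.
    """
    if not alleles:
        raise AlleleSetError("empty allele set")
    by_exon: dict = {}
    for rec in alleles:
        by_exon.setdefault(rec.exon_seq, []).append(rec.name)
    gmap = GGroupMap()
    for members in by_exon.values():
        members = sorted(members)
        if len(members) == 1:
            gname = str(members[0])
        else:
            f = members[0].fields[:3]
            f = f + (1,) * (3 - len(f))  # pad short names to 3-field form
            gname = str(AlleleName(members[0].locus, f, g_flag=True))
        gmap.groups[gname] = [str(m) for m in members]
        for m in members:
            gmap.allele_to_group[str(m)] = gname
    return gmap


def load_allele_set(fasta_path, exon_table_path) -> list:
    """Load allele amplicons from FASTA plus a TSV exon-coordinate sidecar.

    FASTA headers (up to the first whitespace) are allele names. The
    sidecar needs columns ``allele, exon2_start, exon2_end, exon3_start,
    exon3_end`` with 0-based half-open coordinates. Every allele must
    appear in both files exactly once.
    """
    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise AlleleSetError(f"duplicate FASTA header {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    table = pd.read_csv(exon_table_path, sep="\t")
    required = {"allele", "exon2_start", "exon2_end", "exon3_start", "exon3_end"}
    if missing := required - set(table.columns):
        raise AlleleSetError(f"sidecar missing columns {sorted(missing)}")
    if table["allele"].duplicated().any():
        dups = table.loc[table["allele"].duplicated(), "allele"].tolist()
        raise AlleleSetError(f"duplicate sidecar rows for {dups}")
    coords = table.set_index("allele")
    if extra := set(seqs) - set(coords.index):
        raise AlleleSetError(f"alleles missing from sidecar: {sorted(extra)}")
    if extra := set(coords.index) - set(seqs):
        raise AlleleSetError(f"alleles missing from FASTA: {sorted(extra)}")
    records = []
    for name, seq in seqs.items():
        row = coords.loc[name]
        records.append(AlleleRecord(
            name=parse_allele_name(name),
            amplicon_seq=seq,
            exon2=(int(row["exon2_start"]), int(row["exon2_end"])),
            exon3=(int(row["exon3_start"]), int(row["exon3_end"])),
        ))
    return records


# ---------------------------------------------------------------------------
# IUPAC-degenerate in-silico PCR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse amplification primers, each 5'->3' on its strand."""

    forward: str
    reverse: str

    def __post_init__(self):
        for seq in (self.forward, self.reverse):
            if set(seq) - set(IUPAC_SETS):
                raise ValueError(f"non-IUPAC characters in primer {seq!r}")


# MinION amplification pair: 943 bp product over HLA-B exons 2+3, with
# degeneracies at known polymorphic positions to avoid allelic dropout.
MINION_PRIMERS = PrimerPair(
    forward="TTTCTGTTGGTGCTGATATTGCGGGAGGAGMRAGGGGACCSCAG",
    reverse="ACTTGCCTGTCGCTCTATCTTCGGAGGCCATCCCCGGCGACCTAT",
)


def iupac_match(base: str, code: str) -> bool:
    """True iff concrete ``base`` is within the set denoted by IUPAC ``code``."""
    if base not in "ACGT":
        raise ValueError(f"invalid template base {base!r}")
    if code not in IUPAC_SETS:
        raise ValueError(f"invalid IUPAC code {code!r}")
    return base in IUPAC_SETS[code]


def _primer_sites(template: str, primer: str, max_mismatch: int):
    """Start positions where ``primer`` binds with <= max_mismatch mismatches."""
    k = len(primer)
    sites = []
    for i in range(len(template) - k + 1):
        mism = 0
        for b, c in zip(template[i:i + k], primer):
            if b not in IUPAC_SETS[c]:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            sites.append(i)
    return sites


def in_silico_pcr(template: str, primers: PrimerPair, max_mismatch: int = 0):
    """Predict the PCR product of a degenerate primer pair on a template.

    The forward primer is matched on the plus strand and the reverse
    primer on the minus strand, each with at most ``max_mismatch``
    IUPAC-aware mismatches. Degenerate positions are not mismatches when
    the template base lies in the denoted set. Returns ``(start, end,
    product)`` with the primer-to-primer product inclusive of both primer
    sites; when several products are possible the shortest is returned
    with a warning (degenerate primers can have spurious distal sites).
    """
    template = template.upper()
    if len(template) < len(primers.forward) + len(primers.reverse):
        raise AmplificationError("template shorter than combined primers")
    fwd_sites = _primer_sites(template, primers.forward, max_mismatch)
    if not fwd_sites:
        raise AmplificationError("no forward primer site")
    rev_site_plus = reverse_complement(primers.reverse)
    rev_sites = _primer_sites(template, rev_site_plus, max_mismatch)
    if not rev_sites:
        raise AmplificationError("no reverse primer site")
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_site_plus)
            if r >= f + len(primers.forward):
                products.append((f, end))
    if not products:
        raise AmplificationError(
            "primer sites found but in non-amplifiable arrangement")
    products.sort(key=lambda p: (p[1] - p[0], p[0]))
    if len(products) > 1:
        warnings.warn(
            f"{len(products)} possible products; returning shortest",
            stacklevel=2)
    start, end = products[0]
    return start, end, template[start:end]
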
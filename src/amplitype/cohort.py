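"""Cohort-level genotype tables and allele-frequency statistics.

Works on diploid genotype tables (one row per sample with two allele
calls plus a free-text ancestry annotation). Includes zygosity counts,
distinct-allele inventories, allele occurrence frequencies under two
declared denominators, and pharmacogenetic risk-allele carrier
screening at two-field resolution (e.g. B*57:01 for abacavir
hypersensitivity, B*58:01 for allopurinol-induced SCAR, B*15:02 for
carbamazepine-induced SJS/TEN).

A 49-sample reference cohort table (40 Māori/Pacific Island samples
with ``PI_`` ids, four Coriell ``NA`` references and five UDRUGS
samples) ships as a packaged fixture, see :func:`reference_cohort_path`.

Frequency denominators: ``chromosomes`` mode is the conventional
count/(2·n_samples); ``distinct_alleles`` mode divides occurrence
counts by the number of distinct alleles in the subset, the convention
under which the reference cohort's reported headline percentages
(28.95%, 18.42%) were computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .alleles import AlleleName, AlleleParseError, parse_allele_name

__all__ = ["GenotypeTable", "FrequencyReport", "reference_cohort_path",
           "read_genotype_table", "zygosity_counts", "distinct_alleles",
           "allele_frequencies", "screen_risk_alleles"]

MAORI_PACIFIC_PREFIX = "PI_"


def reference_cohort_path() -> Path:
    """Path of the packaged 49-sample reference genotype table."""
    return Path(resources.files("amplitype") / "data" / "reference_cohort.tsv")


@dataclass
class GenotypeTable:
    """Validated per-sample diploid genotype calls."""

    df: pd.DataFrame  # columns: sample, ancestry, allele1, allele2, ...

    def __len__(self) -> int:
        return len(self.df)

    @property
    def maori_pacific(self) -> "GenotypeTable":
        """Rows of Māori / Pacific Island samples (``PI_`` id prefix)."""
        return GenotypeTable(
            self.df[self.df["sample"].str.startswith(MAORI_PACIFIC_PREFIX)]
            .reset_index(drop=True))

    def subset(self, sample_ids: Iterable[str]) -> "GenotypeTable":
        ids = set(sample_ids)
        return GenotypeTable(
            self.df[self.df["sample"].isin(ids)].reset_index(drop=True))


def read_genotype_table(path) -> GenotypeTable:
    """Load and validate a genotype TSV (columns sample/ancestry/allele1/allele2).

    Allele strings are canonicalized through the nomenclature parser;
    an unparseable allele raises with the offending row number. Numeric
    ancestry fractions, where present, must sum to <= 1 per row.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "ancestry", "allele1", "allele2"}
    if missing := required - set(df.columns):
        raise ValueError(f"genotype table missing columns {sorted(missing)}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids {dups}")
    for col in ("allele1", "allele2"):
        canonical = []
        for i, text in enumerate(df[col]):
            try:
                canonical.append(str(parse_allele_name(text)))
            except AlleleParseError as exc:
                raise AlleleParseError(f"row {i + 2} ({df['sample'][i]}), "
                                       f"column {col}: {exc}") from None
        df[col] = canonical
    for i, ann in enumerate(df["ancestry"].fillna("")):
        fracs = [float(tok) for tok in ann.split()
                 if tok.replace(".", "", 1).isdigit()]
        if fracs and sum(fracs) > 1.0 + 1e-9:
            raise ValueError(f"row {i + 2}: ancestry fractions sum to "
                             f"{sum(fracs):.3f} > 1")
    return GenotypeTable(df)


def zygosity_counts(table: GenotypeTable) -> tuple:
    """(homozygotes, heterozygotes); homozygous iff allele1 == allele2."""
    hom = int((table.df["allele1"] == table.df["allele2"]).sum())
    return hom, len(table) - hom


def distinct_alleles(table: GenotypeTable) -> tuple:
    """(count, sorted list) of distinct allele names over both columns."""
    names = sorted(set(table.df["allele1"]) | set(table.df["allele2"]))
    return len(names), names


@dataclass
class FrequencyReport:
    """Per-allele occurrence counts and frequencies for one subset."""

    mode: str                 # "chromosomes" or "distinct_alleles"
    n_samples: int
    denominator: int
    table: pd.DataFrame       # columns: allele, count, frequency (descending)
    subset: str = ""

    def frequency(self, allele: str) -> float:
        row = self.table[self.table["allele"] == allele]
        return float(row["frequency"].iloc[0]) if len(row) else 0.0

    def top(self, n: int = 3) -> pd.DataFrame:
        return self.table.head(n)


def allele_frequencies(table: GenotypeTable, mode: str = "chromosomes",
                       subset: str = "") -> FrequencyReport:
    """Allele occurrence counts and frequencies.

    ``chromosomes`` mode divides occurrence counts by 2·n_samples (the
    conventional allele frequency, summing to 1); ``distinct_alleles``
    mode divides by the number of distinct alleles in the subset.
    """
    if mode not in ("chromosomes", "distinct_alleles"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(table) == 0:
        raise ValueError("empty genotype subset")
    counts = pd.concat([table.df["allele1"], table.df["allele2"]]).value_counts()
    assert int(counts.sum()) == 2 * len(table)
    denom = (2 * len(table) if mode == "chromosomes"
             else distinct_alleles(table)[0])
    out = (counts.rename("count").rename_axis("allele").reset_index())
    out["frequency"] = out["count"] / denom
    out = out.sort_values(["count", "allele"],
                          ascending=[False, True]).reset_index(drop=True)
    return FrequencyReport(mode=mode, n_samples=len(table), denominator=denom,
                           table=out, subset=subset)


def screen_risk_alleles(table: GenotypeTable,
                        risk: Sequence[str]) -> pd.DataFrame:
    """Carriers of pharmacogenetic risk alleles.

    Matching truncates each sample allele to the risk entry's field
    count and ignores suffixes and G flags, so B*57:01:01G carries
    B*57:01. Returns one row per risk allele with carrier ids and count.
    """
    rows = []
    for entry in risk:
        rname = parse_allele_name(entry)
        nf = len(rname.fields)
        carriers = []
        for _, row in table.df.iterrows():
            for col in ("allele1", "allele2"):
                a = parse_allele_name(row[col])
                if a.locus == rname.locus and a.fields[:nf] == rname.fields:
                    carriers.append(row["sample"])
                    break
        rows.append({"risk_allele": str(rname), "n_carriers": len(carriers),
                     "carriers": ",".join(carriers)})
    return pd.DataFrame(rows, columns=["risk_allele", "n_carriers", "carriers"])
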
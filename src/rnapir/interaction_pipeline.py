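"""Promoter-interaction / RNA-contact integration.

Ingests a promoter-capture Hi-C interaction table (bait promoter <-> PIR
fragment) and an RNA-DNA contact table, applies the standard filters
(drop interchromosomal promoter interactions; drop contacts on unlocalized
or unplaced scaffolds), classifies unique PIR fragments by RNA-contact
overlap (RNA-PIR vs nonRNA-PIR), annotates consensus TFBS presence, and
derives 2x2 contingency tables and per-category gene lists.

PIR identity is the exact coordinate triple: PIRs are restriction fragments
(HindIII), so near-identical fragments are never fuzzily merged. A unique
PIR carries the union of bait gene symbols over all interactions that
involve it.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_intervals import GenomicInterval, IntervalTrack, overlap_flags

__all__ = [
    "PromoterInteraction",
    "RnaDnaContact",
    "PirRecord",
    "CountsTable",
    "SchemaError",
    "PCHIC_COLUMNS",
    "MARGI_COLUMNS",
    "load_pchic",
    "load_margi",
    "is_canonical_chrom",
    "classify_pirs",
    "annotate_tfbs",
    "build_contingency",
    "gene_lists_by_category",
    "write_gene_lists",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column is missing from an input table."""


# Default column names; override per dataset via the *columns* argument
# (the CLI exposes them through the config file).
PCHIC_COLUMNS = {
    "bait_chrom": "bait_chr",
    "bait_start": "bait_start",
    "bait_end": "bait_end",
    "bait_genes": "bait_genes",
    "pir_chrom": "pir_chr",
    "pir_start": "pir_start",
    "pir_end": "pir_end",
}

MARGI_COLUMNS = {
    "rna_chrom": "rna_chr",
    "rna_start": "rna_start",
    "rna_end": "rna_end",
    "dna_chrom": "dna_chr",
    "dna_start": "dna_start",
    "dna_end": "dna_end",
}

GENE_SEPARATOR = ";"

CATEGORIES = ("rna_and_tfbs", "rna_only", "tfbs_only", "neither")

_CANONICAL = {f"chr{i}" for i in range(1, 23)} | {"chrX", "chrY", "chrM"}


@dataclass(frozen=True)
class PromoterInteraction:
    bait: GenomicInterval
    bait_genes: tuple[str, ...]
    pir: GenomicInterval

    @property
    def intrachromosomal(self) -> bool:
        return self.bait.chrom == self.pir.chrom


@dataclass(frozen=True)
class RnaDnaContact:
    rna_locus: GenomicInterval
    dna_region: GenomicInterval
    rna_name: str | None = None


@dataclass
class PirRecord:
    """One unique PIR fragment with its classification flags.

    ``has_rna``/``has_ctcf``/``has_yy1`` are None until the corresponding
    classification or annotation step has run.
    """

    pir: GenomicInterval
    genes: tuple[str, ...] = ()
    has_rna: bool | None = None
    has_ctcf: bool | None = None
    has_yy1: bool | None = None

    @property
    def length(self) -> int:
        return self.pir.length


@dataclass(frozen=True)
class CountsTable:
    """2x2 contingency of RNA-contact status x TFBS status.

    a = RNA+/TFBS+, b = RNA+/TFBS-, c = RNA-/TFBS+, d = RNA-/TFBS-.
    """

    factor: str
    a: int
    b: int
    c: int
    d: int

    @property
    def n_rna(self) -> int:
        return self.a + self.b

    @property
    def n_nonrna(self) -> int:
        return self.c + self.d

    @property
    def pct_rna_tfbs(self) -> float:
        return 100.0 * self.a / self.n_rna if self.n_rna else float("nan")

    @property
    def pct_nonrna_tfbs(self) -> float:
        return 100.0 * self.c / self.n_nonrna if self.n_nonrna else float("nan")

    @property
    def crude_odds_ratio(self) -> float:
        """Unadjusted (a*d)/(b*c); inf/nan with zero cells."""
        if self.b == 0 or self.c == 0:
            return float("inf") if self.a * self.d > 0 else float("nan")
        return (self.a * self.d) / (self.b * self.c)

    def as_dict(self) -> dict:
        return {
            "factor": self.factor,
            "a_rna_tfbs": self.a,
            "b_rna_only": self.b,
            "c_tfbs_only": self.c,
            "d_neither": self.d,
            "n_rna": self.n_rna,
            "n_nonrna": self.n_nonrna,
            "pct_rna_tfbs": self.pct_rna_tfbs,
            "pct_nonrna_tfbs": self.pct_nonrna_tfbs,
            "crude_odds_ratio": self.crude_odds_ratio,
        }


def _require_columns(df: pd.DataFrame, columns: Mapping[str, str], what: str) -> None:
    missing = [c for c in columns.values() if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}; have {list(df.columns)}")


def is_canonical_chrom(chrom: str) -> bool:
    """True for chr1..chr22/chrX/chrY/chrM; unlocalized/unplaced scaffolds
    (chrUn*, *_random, anything with an underscore) are non-canonical."""
    return chrom in _CANONICAL and "_" not in chrom


def load_pchic(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    gene_separator: str = GENE_SEPARATOR,
) -> tuple[list[PromoterInteraction], list[PirRecord]]:
    """Load a promoter-interaction TSV; return interactions + unique PIRs.

    Interchromosomal rows (bait and PIR on different chromosomes) are
    dropped. PIR fragments are deduplicated by exact coordinates; each
    unique PIR keeps the union of bait gene symbols across all of its
    interactions (sorted for determinism).
    """
    cols = dict(PCHIC_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, cols, f"promoter-interaction table {path}")

    interactions: list[PromoterInteraction] = []
    genes_by_pir: dict[GenomicInterval, set[str]] = {}
    n_inter = 0
    for row in df.itertuples(index=False):
        r = row._asdict()
        bait = GenomicInterval(
            r[cols["bait_chrom"]], int(r[cols["bait_start"]]), int(r[cols["bait_end"]])
        ).validate()
        pir = GenomicInterval(
            r[cols["pir_chrom"]], int(r[cols["pir_start"]]), int(r[cols["pir_end"]])
        ).validate()
        raw_genes = r[cols["bait_genes"]]
        if pd.isna(raw_genes):
            genes: tuple[str, ...] = ()
        else:
            genes = tuple(
                g.strip() for g in str(raw_genes).split(gene_separator) if g.strip()
            )
        if bait.chrom != pir.chrom:
            n_inter += 1
            continue
        interactions.append(PromoterInteraction(bait, genes, pir))
        genes_by_pir.setdefault(pir, set()).update(genes)

    records = [
        PirRecord(pir=pir, genes=tuple(sorted(genes_by_pir[pir])))
        for pir in sorted(genes_by_pir)
    ]
    logger.info(
        "loaded %d promoter interactions (%d interchromosomal dropped), %d unique PIRs",
        len(interactions), n_inter, len(records),
    )
    return interactions, records


def pir_track(records: Sequence[PirRecord], name: str = "pirs") -> IntervalTrack:
    """Sorted track of the unique PIR fragments in *records*."""
    return IntervalTrack(name, sorted(r.pir for r in records), sorted=True)


def load_margi(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> tuple[list[RnaDnaContact], IntervalTrack]:
    """Load RNA-DNA contact pairs; return unique contacts + unique DNA regions.

    Rows with either end on a non-canonical chromosome (unlocalized or
    unplaced scaffolds: chrUn*, *_random, or any name with an underscore)
    are removed. Duplicate pairs collapse to one contact; DNA regions are
    deduplicated separately.
    """
    cols = dict(MARGI_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, cols, f"RNA-DNA contact table {path}")

    has_name = "rna_name" in df.columns
    seen: set[tuple] = set()
    contacts: list[RnaDnaContact] = []
    dna_regions: set[GenomicInterval] = set()
    n_dropped = 0
    for row in df.itertuples(index=False):
        r = row._asdict()
        rna = GenomicInterval(
            r[cols["rna_chrom"]], int(r[cols["rna_start"]]), int(r[cols["rna_end"]])
        ).validate()
        dna = GenomicInterval(
            r[cols["dna_chrom"]], int(r[cols["dna_start"]]), int(r[cols["dna_end"]])
        ).validate()
        if not (is_canonical_chrom(rna.chrom) and is_canonical_chrom(dna.chrom)):
            n_dropped += 1
            continue
        key = (rna, dna)
        if key in seen:
            continue
        seen.add(key)
        contacts.append(
            RnaDnaContact(rna, dna, str(r["rna_name"]) if has_name else None)
        )
        dna_regions.add(dna)
    logger.info(
        "loaded %d unique RNA-DNA contacts (%d unlocalized/unplaced rows dropped), "
        "%d unique DNA regions",
        len(contacts), n_dropped, len(dna_regions),
    )
    return contacts, IntervalTrack("rna_dna_regions", sorted(dna_regions), sorted=True)


def classify_pirs(
    records: Sequence[PirRecord], rna_regions: IntervalTrack
) -> list[PirRecord]:
    """Set ``has_rna`` on each record: does the PIR share >=1 bp with any
    RNA-interacting DNA region? Returns the same records for chaining."""
    flags = overlap_flags(pir_track(records), rna_regions)
    order = sorted(range(len(records)), key=lambda i: records[i].pir)
    for flag, i in zip(flags, order):
        records[i].has_rna = bool(flag)
    n_rna = int(flags.sum())
    logger.info("classified PIRs: %d RNA-PIRs / %d nonRNA-PIRs", n_rna, len(records) - n_rna)
    return list(records)


_FACTOR_ATTR = {"ctcf": "has_ctcf", "yy1": "has_yy1"}


def annotate_tfbs(
    records: Sequence[PirRecord], consensus: IntervalTrack, factor: str
) -> list[PirRecord]:
    """Set the per-record TFBS flag for *factor* ('ctcf' or 'yy1') by >=1 bp
    overlap with the consensus track."""
    attr = _FACTOR_ATTR.get(factor.lower())
    if attr is None:
        raise ValueError(f"unknown factor {factor!r}: expected one of {sorted(_FACTOR_ATTR)}")
    flags = overlap_flags(pir_track(records), consensus)
    order = sorted(range(len(records)), key=lambda i: records[i].pir)
    for flag, i in zip(flags, order):
        setattr(records[i], attr, bool(flag))
    return list(records)


def _factor_flags(records: Sequence[PirRecord], factor: str) -> tuple[np.ndarray, np.ndarray]:
    attr = _FACTOR_ATTR.get(factor.lower())
    if attr is None:
        raise ValueError(f"unknown factor {factor!r}: expected one of {sorted(_FACTOR_ATTR)}")
    rna, tfbs = [], []
    for i, rec in enumerate(records):
        if rec.has_rna is None:
            raise ValueError(f"record {i}: has_rna unset; run classify_pirs first")
        f = getattr(rec, attr)
        if f is None:
            raise ValueError(f"record {i}: {attr} unset; run annotate_tfbs first")
        rna.append(rec.has_rna)
        tfbs.append(f)
    return np.asarray(rna, dtype=bool), np.asarray(tfbs, dtype=bool)


def build_contingency(records: Sequence[PirRecord], factor: str) -> CountsTable:
    """2x2 table of RNA-contact status against TFBS status for *factor*."""
    rna, tfbs = _factor_flags(records, factor)
    return CountsTable(
        factor=factor.lower(),
        a=int((rna & tfbs).sum()),
        b=int((rna & ~tfbs).sum()),
        c=int((~rna & tfbs).sum()),
        d=int((~rna & ~tfbs).sum()),
    )


def gene_lists_by_category(
    records: Sequence[PirRecord], factor: str
) -> dict[str, list[str]]:
    """Unique bait-gene list per (RNA x TFBS) category for *factor*.

    Each category list is the deduplicated union of bait gene symbols over
    its PIRs, sorted. Categories are not exclusive: a gene interacting with
    PIRs of different categories appears in each corresponding list.
    """
    rna, tfbs = _factor_flags(records, factor)
    sets: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for rec, r, t in zip(records, rna, tfbs):
        cat = CATEGORIES[0] if (r and t) else (
            CATEGORIES[1] if r else (CATEGORIES[2] if t else CATEGORIES[3])
        )
        sets[cat].update(rec.genes)
    return {c: sorted(sets[c]) for c in CATEGORIES}


def write_gene_lists(
    lists: Mapping[str, Iterable[str]], outdir: str | Path, factor: str
) -> list[Path]:
    """Export one symbol-per-line text per category (for ontology tools)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for cat, genes in lists.items():
        p = outdir / f"genes_{factor.lower()}_{cat}.txt"
        p.write_text("".join(f"{g}\n" for g in genes))
        paths.append(p)
    return paths
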
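"""Coordinate model and readers/writers for the pipeline's external formats.

All coordinates are held internally as 0-based half-open intervals
(``[start, end)``); GFF3 input (1-based, inclusive) is converted on load and
report output is converted back to 1-based inclusive.  Sequences are
upper-cased on load and restricted to the ``{A, C, G, T, N}`` alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("regulonminer")

DNA_ALPHABET = frozenset("ACGTN")

#: Closed functional-category vocabulary used in candidate reports.
GENE_CATEGORIES = frozenset(
    {"transport", "regulatory", "enzymatic", "translation", "motility", "hypothetical"}
)


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A record violates a domain-type invariant."""


class ConfigError(ValueError):
    """A configuration value is invalid (e.g. an unknown IUPAC code)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (delegates to Biopython)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence (chromosome or fragment)."""

    id: str
    residues: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residues")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: non-ACGTN characters {sorted(bad)}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValidationError(f"sequence {self.id!r}: bad topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"interval on {self.seq_id}: start {self.start} < 0")
        if self.start >= self.end:
            raise ValidationError(
                f"interval on {self.seq_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"interval on {self.seq_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def to_1based(self) -> tuple[int, int]:
        """(start, end) as 1-based inclusive coordinates for reports."""
        return self.start + 1, self.end


@dataclass(frozen=True)
class GeneAnnotation:
    """An annotated ORF/gene; ``strand`` is never '.'.

    The start codon occupies the first three bases of the interval on the
    '+' strand and the last three (reverse-complemented) on the '-' strand.
    """

    gene_id: str
    interval: GenomicInterval
    product: str = ""
    category: str = "hypothetical"

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if self.category not in GENE_CATEGORIES:
            raise ValidationError(
                f"gene {self.gene_id}: unknown category {self.category!r}"
            )

    @property
    def atg_position(self) -> int:
        """Genomic 0-based index of the A of the start codon on the gene strand."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1


@dataclass(frozen=True)
class Peak:
    """A ChIP enrichment peak with fold enrichment and significance."""

    interval: GenomicInterval
    enrichment: float
    p_value: float
    summit: int | None = None

    def __post_init__(self) -> None:
        if not self.enrichment > 0:
            raise ValidationError(
                f"peak {self.interval.seq_id}:{self.interval.start}: "
                f"enrichment {self.enrichment} must be > 0"
            )
        if not (0 < self.p_value <= 1):
            raise ValidationError(
                f"peak {self.interval.seq_id}:{self.interval.start}: "
                f"p-value {self.p_value} outside (0, 1]"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[GenomicSequence]:
    """Read a FASTA file into :class:`GenomicSequence` records.

    Residues are upper-cased; characters outside ``{A,C,G,T,N}`` raise
    :class:`FormatError` naming the offending record.
    """
    path = Path(path)
    records: list[GenomicSequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        try:
            records.append(GenomicSequence(id=rec.id, residues=str(rec.seq)))
        except ValidationError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[GenomicSequence], path: str | Path) -> None:
    seqrecords = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(
    path: str | Path,
    category_attr: str = "category",
    seq_lengths: dict[str, int] | None = None,
    feature_type: str = "gene",
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 (1-based inclusive -> 0-based half-open).

    The functional category is parsed from the attribute named
    ``category_attr`` and defaults to ``hypothetical`` when absent.  When
    ``seq_lengths`` is given, coordinates outside the sequence raise
    :class:`ValidationError`.
    """
    path = Path(path)
    # gffutils is lenient with malformed input; check the tabular structure
    # up front so a corrupt file fails loudly with its name.
    with open(path, errors="replace") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(
                    f"{path}: line {lineno} is not a 9-column GFF3 record"
                )
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise FormatError(f"{path}: malformed GFF3 ({exc})") from exc

    genes: list[GeneAnnotation] = []
    for feat in db.features_of_type(feature_type, order_by=("seqid", "start")):
        gene_id = (
            feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or feat.attributes.get("Name", [None])[0]
        )
        if gene_id is None:
            raise FormatError(f"{path}: {feature_type} feature without ID at line for {feat}")
        if feat.strand not in ("+", "-"):
            raise ValidationError(f"{path}: gene {gene_id} has strand {feat.strand!r}")
        start, end = feat.start - 1, feat.end  # GFF3 1-based inclusive
        if seq_lengths is not None:
            length = seq_lengths.get(feat.seqid)
            if length is not None and end > length:
                raise ValidationError(
                    f"{path}: gene {gene_id} end {end} exceeds sequence length {length}"
                )
        category = feat.attributes.get(category_attr, ["hypothetical"])[0].lower()
        product = feat.attributes.get("product", [""])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                interval=GenomicInterval(feat.seqid, start, end, feat.strand),
                product=product,
                category=category,
            )
        )
    return genes


def write_gff3(
    genes: Iterable[GeneAnnotation],
    path: str | Path,
    source: str = "regulonminer",
) -> None:
    """Write gene annotations as GFF3 (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            start1, end1 = g.interval.to_1based()
            attrs = f"ID={g.gene_id};category={g.category}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [
                        g.interval.seq_id,
                        source,
                        "gene",
                        str(start1),
                        str(end1),
                        ".",
                        g.interval.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

_PEAK_TSV_COLUMNS = ["chrom", "start", "end", "enrichment", "p_value"]


def read_peaks(path: str | Path, dialect: str = "tsv") -> list[Peak]:
    """Read peak calls.

    Dialects:

    ``tsv``
        Five tab-separated columns ``chrom  start  end  enrichment  p_value``
        with BED-style 0-based half-open coordinates.  Lines starting with
        ``#`` and an optional header row with those exact names are skipped.
    ``narrowPeak``
        ENCODE narrowPeak (BED6+4); ``signalValue`` is the fold enrichment and
        the ``pValue`` column holds -log10(p), inverted on load.

    Peaks are returned sorted by (chrom, start, end).
    """
    path = Path(path)
    if dialect not in ("tsv", "narrowPeak"):
        raise ConfigError(f"unknown peak dialect {dialect!r}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    # optional header row in the tsv dialect (numeric start column otherwise)
    if dialect == "tsv" and str(df.iloc[0, 1]).lower() in ("start", "chromstart"):
        df = df.iloc[1:]
    peaks: list[Peak] = []
    for row in df.itertuples(index=False):
        fields = list(row)
        try:
            chrom = str(fields[0])
            start, end = int(fields[1]), int(fields[2])
            if dialect == "tsv":
                if len(fields) < 5:
                    raise FormatError(f"{path}: expected 5 columns, got {len(fields)}")
                enrichment = float(fields[3])
                p_value = float(fields[4])
                summit = None
            else:
                if len(fields) < 10:
                    raise FormatError(
                        f"{path}: narrowPeak requires 10 columns, got {len(fields)}"
                    )
                enrichment = float(fields[6])
                p_value = 10.0 ** -float(fields[7])
                summit = int(fields[9]) if int(fields[9]) >= 0 else None
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: unparseable peak row {fields!r}") from exc
        peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                enrichment=enrichment,
                p_value=p_value,
                summit=summit,
            )
        )
    peaks.sort(key=lambda p: (p.interval.seq_id, p.interval.start, p.interval.end))
    return peaks


def write_peaks_tsv(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks in the documented 5-column TSV dialect (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_PEAK_TSV_COLUMNS) + "\n")
        for p in peaks:
            fh.write(
                f"{p.interval.seq_id}\t{p.interval.start}\t{p.interval.end}"
                f"\t{p.enrichment:.6g}\t{p.p_value:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted, disjoint list (strand ignored)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda i: (i.seq_id, i.start, i.end)):
        if merged and merged[-1].seq_id == iv.seq_id and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.seq_id, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.seq_id, iv.start, iv.end))
    return merged


def intergenic_regions(
    genes: Sequence[GeneAnnotation], genome: GenomicSequence
) -> list[GenomicInterval]:
    """Complement of the merged gene intervals within ``[0, len(genome))``.

    An empty gene list yields the whole genome; empty complement pieces are
    omitted.  Output is sorted and disjoint.
    """
    length = len(genome)
    covered = merge_intervals(
        [g.interval for g in genes if g.interval.seq_id == genome.id]
    )
    regions: list[GenomicInterval] = []
    cursor = 0
    for iv in covered:
        if iv.start > cursor:
            regions.append(GenomicInterval(genome.id, cursor, iv.start))
        cursor = max(cursor, iv.end)
    if cursor < length:
        regions.append(GenomicInterval(genome.id, cursor, length))
    return regions
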
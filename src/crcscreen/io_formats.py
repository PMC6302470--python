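"""Readers and writers for every external format the pipeline touches.

All genomic coordinates held in memory are 1-based inclusive (the native
VCF/GFF3 convention); BED inputs are converted at the boundary.  Variant
identity throughout the package is the exact tuple ``(chrom, pos, ref, alt)``
with uppercase alleles and no further normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import FormatError, ParseError

__all__ = [
    "VariantRecord",
    "TranscriptModel",
    "LabeledMatrix",
    "GeneSetCollection",
    "variant_key",
    "read_vcf",
    "write_vcf",
    "read_gene_models",
    "read_matrix",
    "write_matrix",
    "read_gmt",
    "write_gmt",
    "read_blacklist",
    "write_blacklist",
]

_VALID_BASES = frozenset("ACGT")


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Canonical identity tuple for a variant: uppercase alleles, nothing else."""
    return (chrom, int(pos), ref.upper(), alt.upper())


@dataclass(frozen=True)
class VariantRecord:
    """One small-variant call (one ALT allele of one VCF line).

    ``quality`` is the variant quality score in the tumor sample (VCF QUAL);
    ``depth`` is the read depth at the site, taken from the sample FORMAT DP
    when present, else INFO DP, else ``None`` (missing).  ``is_known`` marks
    membership in the known-variant blacklist (the dbSNP/1000G emulation).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    quality: float | None
    depth: int | None
    sample_id: str
    is_known: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele, label in ((self.ref, "ref"), (self.alt, "alt")):
            if not allele or not set(allele) <= _VALID_BASES:
                raise ValueError(f"{label} allele {allele!r} is not a non-empty ACGT string")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.quality is not None and self.quality < 0:
            raise ValueError(f"negative quality {self.quality}")
        if self.depth is not None and self.depth < 0:
            raise ValueError(f"negative depth {self.depth}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript's strand and ordered CDS segments.

    ``cds_segments`` are 1-based inclusive genomic intervals, non-overlapping
    and sorted by genomic coordinate regardless of strand.  ``cds_length`` is
    the total number of coding bases.  A CDS length not divisible by 3 is
    allowed (partial models) but recorded with a warning at load time.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        prev_end = 0
        for start, end in self.cds_segments:
            if start > end:
                raise ValueError(f"segment {start}-{end} has start > end")
            if start <= prev_end:
                raise ValueError("CDS segments overlap or are unsorted")
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)

    @property
    def span(self) -> tuple[int, int]:
        """Genomic start/end of the CDS (0,0 for a non-coding model)."""
        if not self.cds_segments:
            return (0, 0)
        return (self.cds_segments[0][0], self.cds_segments[-1][1])


@dataclass
class LabeledMatrix:
    """A labelled numeric matrix (genes x samples/tissues).

    Thin wrapper around a pandas DataFrame guaranteeing unique labels, with
    an optional column -> group mapping (e.g. sample -> condition).
    """

    values: pd.DataFrame
    col_groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise FormatError(f"duplicate row label {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise FormatError(f"duplicate column label {dup!r}")
        if self.col_groups is not None:
            unknown = set(self.col_groups) - set(self.values.columns)
            if unknown:
                raise FormatError(f"group file names unknown column(s): {sorted(unknown)}")

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GeneSetCollection:
    """GMT-style gene sets: set_id -> (description, member genes)."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, (_desc, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {set_id!r} has no members")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {set_id!r} contains duplicate genes")

    def sets_for(self, gene: str) -> list[str]:
        return [sid for sid, (_d, members) in self.sets.items() if gene in members]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# VCF


def _prevalidate_vcf(path: Path) -> None:
    """Light text-level validation producing record-level errors with line
    numbers, ahead of the htslib parse (which reports less precisely)."""
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if not line.strip():
                continue
            if not saw_header:
                raise FormatError(f"{path}: data before #CHROM header (line {lineno})")
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise ParseError(f"{path} line {lineno}: fewer than 8 VCF columns")
            qual = fields[5]
            if qual != ".":
                try:
                    float(qual)
                except ValueError:
                    raise ParseError(
                        f"{path} line {lineno}: non-numeric QUAL {qual!r}"
                    ) from None
            for entry in fields[7].split(";"):
                if entry.startswith("DP="):
                    try:
                        int(entry[3:])
                    except ValueError:
                        raise ParseError(
                            f"{path} line {lineno}: non-numeric DP {entry[3:]!r}"
                        ) from None
    if not saw_header:
        raise FormatError(f"{path}: missing #CHROM header line")


def read_vcf(
    path: str | Path,
    sample_id: str,
    blacklist: set[tuple[str, int, str, str]] | None = None,
) -> list[VariantRecord]:
    """Read a VCF into one :class:`VariantRecord` per ALT allele per line.

    Depth precedence is sample-column DP (for ``sample_id`` when that sample
    is in the file, else the sole sample), then INFO DP, then missing.
    ``is_known`` is set by exact (chrom, pos, ref, alt) membership in
    ``blacklist``.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"VCF not found: {path}")
    _prevalidate_vcf(path)
    blacklist = blacklist or set()

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        file_samples = list(vcf.header.samples)
        sample_col = sample_id if sample_id in file_samples else (
            file_samples[0] if len(file_samples) == 1 else None
        )
        for rec in vcf:
            depth = None
            if sample_col is not None:
                fmt = rec.samples[sample_col]
                if "DP" in fmt and fmt["DP"] is not None:
                    depth = int(fmt["DP"])
            if depth is None and "DP" in rec.info:
                info_dp = rec.info["DP"]
                if isinstance(info_dp, tuple):
                    info_dp = info_dp[0]
                depth = int(info_dp)
            for alt in rec.alts or ():
                key = variant_key(rec.chrom, rec.pos, rec.ref, alt)
                records.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref.upper(),
                        alt=alt.upper(),
                        quality=rec.qual,
                        depth=depth,
                        sample_id=sample_id,
                        is_known=key in blacklist,
                    )
                )
    return records


def write_vcf(records: Sequence[VariantRecord], path: str | Path, sample_id: str) -> None:
    """Write records to a minimal single-sample VCF 4.2 file (text, sorted
    as given).  QUAL is printed without trailing zeros; DP goes to both the
    INFO and the sample FORMAT column."""
    path = Path(path)
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    ]
    for chrom in dict.fromkeys(r.chrom for r in records):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for r in records:
        qual = "." if r.quality is None else f"{r.quality:g}"
        info = "." if r.depth is None else f"DP={r.depth}"
        fmt, sample = ("GT", "0/1") if r.depth is None else ("GT:DP", f"0/1:{r.depth}")
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{qual}\tPASS\t{info}\t{fmt}\t{sample}"
        )
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene models


def _check_frame(model: TranscriptModel) -> TranscriptModel:
    if model.cds_length % 3 != 0:
        warnings.warn(
            f"transcript {model.transcript_id}: CDS length {model.cds_length} "
            "is not divisible by 3 (partial model?)",
            stacklevel=3,
        )
    return model


def _split_name(name: str) -> tuple[str, str]:
    """BED name field 'gene|transcript' -> ids; a bare name serves as both."""
    if "|" in name:
        gene, tx = name.split("|", 1)
        return gene, tx
    return name, name


def _read_bed12(path: Path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path} line {lineno}: BED12 needs 12 columns")
            chrom = fields[0]
            chrom_start, chrom_end = int(fields[1]), int(fields[2])
            gene_id, tx_id = _split_name(fields[3])
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise FormatError(f"{path} line {lineno}: blockCount mismatch")
            segments = []
            prev = -1
            for off, size in zip(starts, sizes):
                b_start = chrom_start + off          # 0-based half-open
                b_end = b_start + size
                if b_start < chrom_start or b_end > chrom_end:
                    raise FormatError(f"{path} line {lineno}: block outside chrom span")
                if b_start <= prev:
                    raise FormatError(f"{path} line {lineno}: blocks unsorted/overlapping")
                prev = b_end
                cds_start = max(b_start, thick_start)
                cds_end = min(b_end, thick_end)
                if cds_start < cds_end:
                    segments.append((cds_start + 1, cds_end))  # -> 1-based inclusive
            model = TranscriptModel(gene_id, tx_id, chrom, strand, tuple(segments))
            if not segments:
                warnings.warn(
                    f"transcript {tx_id}: thickStart == thickEnd, non-coding model",
                    stacklevel=2,
                )
                models.append(model)
            else:
                models.append(_check_frame(model))
    return models


def _read_gff3(path: Path) -> list[TranscriptModel]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises assorted sqlite/value errors
        raise FormatError(f"{path}: not parseable as GFF3 ({exc})") from exc

    by_tx: dict[str, list] = {}
    for cds in db.features_of_type("CDS"):
        parents = cds.attributes.get("Parent") or [cds.id or "unknown"]
        for parent in parents:
            by_tx.setdefault(parent, []).append(cds)
    models = []
    for tx_id, feats in by_tx.items():
        chroms = {f.seqid for f in feats}
        strands = {f.strand for f in feats}
        if len(chroms) > 1 or len(strands) > 1:
            raise FormatError(f"{path}: transcript {tx_id} spans chroms/strands")
        segments = sorted((f.start, f.end) for f in feats)
        gene_id = feats[0].attributes.get("gene_id", [None])[0]
        if gene_id is None:
            gene_id = _split_name(tx_id)[0]
        models.append(
            _check_frame(
                TranscriptModel(gene_id, tx_id, chroms.pop(), strands.pop(), tuple(segments))
            )
        )
    return models


def read_gene_models(path: str | Path, dialect: str = "BED12") -> list[TranscriptModel]:
    """Read transcript CDS models from BED12 or GFF3.

    BED12 thickStart/thickEnd intersected with the blocks define the CDS;
    coordinates are converted to 1-based inclusive.  GFF3 CDS features are
    grouped by their Parent transcript.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"gene-model file not found: {path}")
    dialect = dialect.upper()
    if dialect == "BED12":
        return _read_bed12(path)
    if dialect == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown dialect {dialect!r} (use BED12 or GFF3)")


# ---------------------------------------------------------------------------
# Matrices, gene sets, blacklists


def read_matrix(path: str | Path, groups: str | Path | None = None) -> LabeledMatrix:
    """Read a TSV matrix (header row = column labels, first column = row
    labels); an optional two-column TSV maps columns to group labels."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise FormatError(f"{path}: unreadable TSV ({exc})") from exc
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        where = bad.index[0] if len(bad) else "?"
        raise FormatError(f"{path}: non-numeric cell at row {where!r}, column {col!r}")
    col_groups = None
    if groups is not None:
        gdf = pd.read_csv(groups, sep="\t", header=None, names=["col", "group"])
        col_groups = dict(zip(gdf["col"].astype(str), gdf["group"].astype(str)))
    return LabeledMatrix(values=df, col_groups=col_groups)


def write_matrix(matrix: LabeledMatrix, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a LabeledMatrix as TSV with fixed precision (bit-stable on
    re-read for values representable at that precision)."""
    matrix.values.to_csv(path, sep="\t", float_format=float_format)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT-style gene-set file: set_id TAB description TAB gene..."""
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path} line {lineno}: GMT needs set, description, >=1 gene")
            set_id, desc, *genes = fields
            genes = [g for g in genes if g]
            if set_id in sets:
                raise FormatError(f"{path} line {lineno}: duplicate set id {set_id!r}")
            sets[set_id] = (desc, tuple(genes))
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection:
            fh.write("\t".join([set_id, desc, *members]) + "\n")


def read_blacklist(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Read a 4-column TSV (chrom, pos, ref, alt) of known variants."""
    keys = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path} line {lineno}: blacklist needs 4 columns")
            try:
                keys.add(variant_key(fields[0], int(fields[1]), fields[2], fields[3]))
            except ValueError:
                raise ParseError(f"{path} line {lineno}: non-integer position") from None
    return keys


def write_blacklist(keys: Iterable[tuple[str, int, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, ref, alt in sorted(keys):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
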
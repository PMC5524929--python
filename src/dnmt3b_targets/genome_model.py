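"""Coordinate-safe genomic primitives: intervals, genes, peaks and their readers.

All coordinates are internally 0-based half-open (BED convention). GTF input,
which is 1-based inclusive, is converted on read and back-converted on write,
so round-trips are exact. Abutting half-open intervals do *not* overlap unless
a positive ``min_gap`` is requested.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """A record violated a coordinate or schema invariant."""


class ParseError(ValueError):
    """A file could not be parsed under the declared dialect."""


class ChromosomeMismatchError(ValidationError):
    """Peak and gene-model chromosome namespaces do not match."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValidationError(f"bad strand {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:[{self.start},{self.end})"
            )

    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", min_gap: int = 0) -> bool:
        """True when the intervals overlap or lie within ``min_gap`` bp.

        With ``min_gap=0`` abutting intervals ([0,10) and [10,20)) do not
        overlap, matching BED semantics.
        """
        if self.chrom != other.chrom:
            return False
        return self.start < other.end + min_gap and other.start < self.end + min_gap

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def center(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Gene:
    """A gene with strand-aware TSS/TES and optional exon/UTR structure."""

    gene_id: str
    symbol: str
    body: GenomicInterval
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()
    is_pseudogene: bool = False

    def __post_init__(self) -> None:
        if self.body.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be + or - (got {self.body.strand!r})"
            )
        if not self.exons:
            object.__setattr__(self, "exons", (self.body,))
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for e in exons:
            if e.chrom != self.body.chrom or e.start < self.body.start or e.end > self.body.end:
                raise ValidationError(f"gene {self.gene_id}: exon {e} outside body")
        for a, b in zip(exons, exons[1:]):
            if b.start < a.end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base (strand-aware)."""
        return self.body.start if self.strand == "+" else self.body.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site: last transcribed base (strand-aware)."""
        return self.body.end - 1 if self.strand == "+" else self.body.start


class GeneModel:
    """Collection of genes with a per-chromosome interval index."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: dict[str, Gene] = {}
        self._by_symbol: dict[str, list[Gene]] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
            self._by_symbol.setdefault(g.symbol, []).append(g)
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                g.body.start, g.body.end, g.gene_id
            )

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def by_symbol(self, symbol: str) -> list[Gene]:
        """All genes sharing ``symbol`` (ids are unique, symbols need not be)."""
        return list(self._by_symbol.get(symbol, []))

    def query(self, chrom: str, start: int, end: int) -> list[Gene]:
        """Genes whose body overlaps ``[start, end)``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in sorted(tree.overlap(start, end))]

    def genes_on(self, chrom: str) -> list[Gene]:
        return sorted(
            (g for g in self if g.chrom == chrom), key=lambda g: g.body.start
        )

    def check_chromosomes(self, chroms: Iterable[str]) -> None:
        """Raise if any foreign chromosome name is absent from this model.

        Silent namespace mismatch ("1" vs "chr1") is the classic annotation
        bug; it is surfaced as a named error instead.
        """
        missing = set(chroms) - self.chromosomes
        if missing:
            raise ChromosomeMismatchError(
                f"chromosomes {sorted(missing)} absent from gene model "
                f"(model has {sorted(self.chromosomes)})"
            )


@dataclass(frozen=True)
class Peak:
    """A called enrichment region, optionally with score and summit offset."""

    interval: GenomicInterval
    score: float | None = None
    summit: int | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.summit is not None and not (0 <= self.summit < self.interval.length()):
            raise ValidationError(
                f"summit offset {self.summit} outside peak of length "
                f"{self.interval.length()}"
            )

    def anchor(self, use_summit: bool = False) -> int:
        """Anchor position: summit if requested and present, else the center."""
        if use_summit and self.summit is not None:
            return self.interval.start + self.summit
        return self.interval.center()


@dataclass
class PeakSet:
    """Peaks from one pool (and optionally one ChIP replicate within it)."""

    pool_id: str
    peaks: list[Peak] = field(default_factory=list)
    replicate_id: str | None = None

    def __post_init__(self) -> None:
        self.peaks = sorted(
            self.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
        )

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]

    def chromosomes(self) -> set[str]:
        return {p.interval.chrom for p in self.peaks}


# ---------------------------------------------------------------------------
# interval algebra


def merge_overlapping(
    intervals: Sequence[GenomicInterval], min_gap: int = 0
) -> list[GenomicInterval]:
    """Union intervals that overlap or lie within ``min_gap`` bp of each other.

    Returns maximal merged intervals, sorted and pairwise disjoint. Strand is
    ignored (output strand is "."). Idempotent for fixed ``min_gap``.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    if not intervals:
        return []
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = (
        ordered[0].chrom,
        ordered[0].start,
        ordered[0].end,
    )
    for iv in ordered[1:]:
        if iv.chrom == cur_chrom and iv.start < cur_end + min_gap:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return merged


# ---------------------------------------------------------------------------
# readers / writers

_TSV_COLUMNS = [
    "gene_id",
    "symbol",
    "chrom",
    "start",
    "end",
    "strand",
    "exon_starts",
    "exon_ends",
    "utr5",
    "utr3",
    "is_pseudogene",
]


def _intervals_from_blocks(chrom: str, strand: str, blocks: str) -> tuple[GenomicInterval, ...]:
    """Parse 'start-end,start-end' block notation into intervals."""
    if not blocks or blocks == ".":
        return ()
    out = []
    for token in blocks.split(","):
        s, e = token.split("-")
        out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return tuple(out)


def _blocks_from_intervals(ivs: Sequence[GenomicInterval]) -> str:
    return ",".join(f"{iv.start}-{iv.end}" for iv in ivs) or "."


def read_gene_model(path: str | os.PathLike, format: str = "auto") -> GeneModel:
    """Read a gene model from GTF or the simplified gene-model TSV.

    GTF coordinates (1-based inclusive) are converted to the internal 0-based
    half-open convention. Genes without exon records get their body as a
    single exon. Unstranded genes are rejected.
    """
    path = os.fspath(path)
    if format == "auto":
        format = "gtf" if path.endswith((".gtf", ".gff", ".gtf.gz")) else "tsv"
    if format == "gtf":
        return _read_gtf(path)
    if format == "tsv":
        return _read_model_tsv(path)
    raise ValueError(f"unknown gene model format {format!r}")


def _read_gtf(path: str) -> GeneModel:
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise ParseError(f"cannot parse GTF {path}: {exc}") from exc

    genes: list[Gene] = []
    for rec in db.features_of_type("gene"):
        gene_id = rec.attributes.get("gene_id", [rec.id])[0]
        symbol = rec.attributes.get("gene_name", [gene_id])[0]
        if rec.strand not in ("+", "-"):
            raise ValidationError(f"gene {gene_id}: unstranded genes are rejected")
        body = GenomicInterval(rec.seqid, rec.start - 1, rec.end, rec.strand)
        exons, utr5, utr3 = [], [], []
        for child in db.region(
            seqid=rec.seqid, start=rec.start, end=rec.end, featuretype=("exon", "five_prime_utr", "three_prime_utr")
        ):
            if child.attributes.get("gene_id", [None])[0] != gene_id:
                continue
            iv = GenomicInterval(child.seqid, child.start - 1, child.end, child.strand)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "five_prime_utr":
                utr5.append(iv)
            else:
                utr3.append(iv)
        pseudo = "pseudogene" in ";".join(rec.attributes.get("gene_biotype", []))
        genes.append(
            Gene(gene_id, symbol, body, tuple(exons), tuple(utr5), tuple(utr3), pseudo)
        )
    return GeneModel(genes)


def _read_model_tsv(path: str) -> GeneModel:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"cannot parse gene-model TSV {path}: {exc}") from exc
    missing = set(_TSV_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"gene-model TSV {path} missing columns {sorted(missing)}")
    genes = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            body = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
            # exon_starts/exon_ends are parallel comma lists
            if row.exon_starts not in ("", ".") and row.exon_ends not in ("", "."):
                starts = [int(x) for x in row.exon_starts.split(",")]
                ends = [int(x) for x in row.exon_ends.split(",")]
                if len(starts) != len(ends):
                    raise ValidationError("exon_starts/exon_ends length mismatch")
                exons = tuple(
                    GenomicInterval(row.chrom, s, e, row.strand)
                    for s, e in zip(starts, ends)
                )
            else:
                exons = ()
            genes.append(
                Gene(
                    gene_id=row.gene_id,
                    symbol=row.symbol,
                    body=body,
                    exons=exons,
                    utr5=_intervals_from_blocks(row.chrom, row.strand, row.utr5),
                    utr3=_intervals_from_blocks(row.chrom, row.strand, row.utr3),
                    is_pseudogene=row.is_pseudogene.lower() in ("1", "true", "yes"),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ParseError(f"{path} line {i}: {exc}") from exc
    return GeneModel(genes)


def write_gene_model(model: GeneModel, path: str | os.PathLike, format: str = "tsv") -> None:
    """Write a gene model as simplified TSV or GTF (back-converted to 1-based)."""
    path = os.fspath(path)
    if format == "tsv":
        rows = []
        for g in model:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "symbol": g.symbol,
                    "chrom": g.chrom,
                    "start": g.body.start,
                    "end": g.body.end,
                    "strand": g.strand,
                    "exon_starts": ",".join(str(e.start) for e in g.exons),
                    "exon_ends": ",".join(str(e.end) for e in g.exons),
                    "utr5": _blocks_from_intervals(g.utr5),
                    "utr3": _blocks_from_intervals(g.utr3),
                    "is_pseudogene": str(g.is_pseudogene).lower(),
                }
            )
        pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if format == "gtf":
        with open(path, "w") as fh:
            for g in model:
                attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
                if g.is_pseudogene:
                    attrs += ' gene_biotype "pseudogene";'
                fh.write(
                    f"{g.chrom}\tdnmt3b_targets\tgene\t{g.body.start + 1}\t{g.body.end}"
                    f"\t.\t{g.strand}\t.\t{attrs}\n"
                )
                for e in g.exons:
                    fh.write(
                        f"{e.chrom}\tdnmt3b_targets\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{g.strand}\t.\t{attrs}\n"
                    )
                for kind, ivs in (("five_prime_utr", g.utr5), ("three_prime_utr", g.utr3)):
                    for iv in ivs:
                        fh.write(
                            f"{iv.chrom}\tdnmt3b_targets\t{kind}\t{iv.start + 1}\t{iv.end}"
                            f"\t.\t{g.strand}\t.\t{attrs}\n"
                        )
        return
    raise ValueError(f"unknown gene model format {format!r}")


def read_peaks(
    path: str | os.PathLike,
    pool_id: str,
    replicate_id: str | None = None,
) -> PeakSet:
    """Read a BED3+ peak file (0-based half-open, no coordinate shift).

    Optional column 4 is the peak name, column 5 the score.
    """
    path = os.fspath(path)
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path} line {lineno}: expected >=3 BED columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path} line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ValidationError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            peaks.append(Peak(GenomicInterval(chrom, start, end), score=score, name=name))
    return PeakSet(pool_id=pool_id, replicate_id=replicate_id, peaks=peaks)


def write_peaks(peakset: PeakSet, path: str | os.PathLike) -> None:
    """Write peaks as BED (name and score columns emitted when present)."""
    with open(os.fspath(path), "w") as fh:
        for p in peakset:
            iv = p.interval
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if p.name is not None or p.score is not None:
                cols.append(p.name if p.name is not None else ".")
            if p.score is not None:
                cols.append(f"{p.score:g}")
            fh.write("\t".join(cols) + "\n")
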
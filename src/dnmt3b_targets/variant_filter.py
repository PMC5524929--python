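"""Rare-variant selection and cohort summarization.

A variant is "rare" when its minor allele frequency (MAF) is below a
threshold (default 0.01) in at least one population database — the
permissive ``any_database`` rule — or in every database where it is present
(``all_databases``). Variants absent from every database are treated as
novel and pass the rare filter. Pathogenicity prediction strings (SIFT /
PolyPhen) are carried through untouched; they are upstream annotations, not
quantities computed here.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_DATABASES = ("KG_ALL", "KG_EUR", "EVS", "ExAC", "MGP")
LOCATIONS = ("exon", "utr5", "utr3", "intron", "splice", "other")
_ABSENT = {"", ".", "N", "NA", "NAN", "NONE"}


@dataclass(frozen=True)
class VariantRecord:
    """One annotated rare-variant row (the WES-table schema)."""

    gene: str
    refseq: str
    chrom: str
    position: int
    ref: str
    alt: str
    coding_change: str
    location: str
    patient_id: str
    inheritance: str = "unknown"
    phenotype: str = ""
    familial: bool = False
    zygosity: str = "het"
    rs_id: str | None = None
    maf: Mapping[str, float] = field(default_factory=dict)
    predictions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(
                f"{self.gene} {self.coding_change}: unknown location {self.location!r}"
            )
        for db, f in self.maf.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"{self.gene} {self.coding_change}: MAF {f} for {db} outside [0,1]"
                )

    def variant_type(self) -> str:
        """snv / deletion / insertion / mnv, from ref/alt lengths with the
        coding-change notation as fallback."""
        ref, alt = self.ref, self.alt
        if ref and alt and ref not in ("-",) and alt not in ("-",):
            if len(ref) == 1 and len(alt) == 1:
                return "snv"
            if len(alt) < len(ref):
                return "deletion"
            if len(alt) > len(ref):
                return "insertion"
            return "mnv"
        if alt in ("-", "") and ref:
            return "deletion"
        if ref in ("-", "") and alt:
            return "insertion"
        c = self.coding_change
        if "del" in c:
            return "deletion"
        if "ins" in c or "dup" in c:
            return "insertion"
        if re.search(r"[ACGT]>[ACGT]", c):
            return "snv"
        log.warning("cannot classify variant %s %s", self.gene, c)
        return "unknown"


@dataclass(frozen=True)
class RareFilterConfig:
    """Threshold and rule of the rare filter."""

    threshold: float = 0.01
    rule: str = "any_database"
    databases: tuple[str, ...] = DEFAULT_DATABASES
    novel_passes: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie strictly between 0 and 1")
        if self.rule not in ("any_database", "all_databases"):
            raise ValueError(f"unknown rule {self.rule!r}")


def classify_variant_type(record: VariantRecord) -> str:
    return record.variant_type()


def parse_variants(
    path,
    format: str = "tsv",
    databases: Sequence[str] = DEFAULT_DATABASES,
    vcf_info_map: Mapping[str, str] | None = None,
) -> list[VariantRecord]:
    """Read an annotated variant table (TSV) or a minimal VCF.

    In the TSV, per-database MAF cells containing "N"/"NA"/empty mean
    *absent from that database* and are stored as absent, never as 0. For
    VCF input, ``vcf_info_map`` maps INFO keys to database names (e.g.
    ``{"AF": "KG_ALL"}``).
    """
    if format == "tsv":
        return _parse_tsv(path, databases)
    if format == "vcf":
        return _parse_vcf(path, vcf_info_map or {})
    raise ValueError(f"unknown variant format {format!r}")


def _parse_tsv(path, databases: Sequence[str]) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records: list[VariantRecord] = []
    for i, row in df.iterrows():
        maf: dict[str, float] = {}
        for db in databases:
            cell = str(row.get(db, "")).strip()
            if cell.upper() in _ABSENT:
                continue
            try:
                f = float(cell.replace(",", "."))
            except ValueError as exc:
                raise ValueError(f"row {i + 2}: bad MAF {cell!r} for {db}") from exc
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"row {i + 2}: MAF {f} for {db} outside [0,1]")
            maf[db] = f
        predictions = {
            k: row[col]
            for k, col in (("SIFT", "sift"), ("PolyPhen", "polyphen"))
            if col in row and str(row[col]).upper() not in _ABSENT
        }
        rs = str(row.get("rs_id", "")).strip()
        records.append(
            VariantRecord(
                gene=row["gene"],
                refseq=row.get("refseq", ""),
                chrom=str(row["chrom"]),
                position=int(row["position"]),
                ref=row["ref"],
                alt=row["alt"],
                coding_change=row.get("coding_change", ""),
                location=row["location"],
                patient_id=str(row["patient_id"]),
                inheritance=row.get("inheritance", "unknown") or "unknown",
                phenotype=row.get("phenotype", ""),
                familial=str(row.get("familial", "false")).lower()
                in ("1", "true", "yes"),
                zygosity=row.get("zygosity", "het") or "het",
                rs_id=None if rs.upper() in _ABSENT else rs,
                maf=maf,
                predictions=predictions,
            )
        )
    return records


def _parse_vcf(path, info_map: Mapping[str, str]) -> list[VariantRecord]:
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    for v in VCF(str(path)):
        maf: dict[str, float] = {}
        for info_key, db in info_map.items():
            val = v.INFO.get(info_key)
            if val is None:
                continue
            f = float(val[0] if isinstance(val, tuple) else val)
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{v.CHROM}:{v.POS}: MAF {f} outside [0,1]")
            maf[db] = f
        gene = v.INFO.get("GENE") or ""
        records.append(
            VariantRecord(
                gene=str(gene),
                refseq="",
                chrom=v.CHROM,
                position=v.POS,
                ref=v.REF,
                alt=v.ALT[0] if v.ALT else "",
                coding_change="",
                location=str(v.INFO.get("LOC") or "other"),
                patient_id=str(v.INFO.get("PATIENT") or "unknown"),
                rs_id=v.ID,
                maf=maf,
            )
        )
    return records


def packaged_variant_table() -> list[VariantRecord]:
    """The rare-variant table shipped with the package (the HSCR WES panel)."""
    from importlib import resources

    ref = resources.files("dnmt3b_targets.data") / "rare_variants_hscr.tsv"
    with resources.as_file(ref) as p:
        return parse_variants(p, format="tsv")


def rare_filter(
    records: Iterable[VariantRecord], cfg: RareFilterConfig | None = None
) -> list[VariantRecord]:
    """Variants passing the MAF rule.

    any_database: rare in >= 1 database where present, or novel (absent from
    all). all_databases: rare in every database where present (novelty
    passes unless ``novel_passes`` is False).
    """
    cfg = cfg or RareFilterConfig()
    out = []
    for r in records:
        present = {db: f for db, f in r.maf.items() if db in cfg.databases}
        if not present:
            if cfg.novel_passes:
                out.append(r)
            continue
        if cfg.rule == "any_database":
            if any(f < cfg.threshold for f in present.values()):
                out.append(r)
        else:
            if all(f < cfg.threshold for f in present.values()):
                out.append(r)
    return out


@dataclass
class VariantSummary:
    """Cohort-level tallies of a variant set."""

    n_variants: int
    by_type: dict[str, int]
    by_location: dict[str, int]
    n_utr: int
    n_genes: int
    genes: list[str]
    n_patients: int
    patients_with_multiple: dict[str, list[str]]  # patient -> genes carried
    by_inheritance: dict[str, int]
    by_phenotype: dict[str, int]

    def to_dict(self) -> dict:
        return dict(vars(self))


def summarize_variants(records: Iterable[VariantRecord]) -> VariantSummary:
    """Tallies by type, location (UTR = utr5 + utr3), gene, patient,
    inheritance and phenotype; permutation-invariant in the input order."""
    records = list(records)
    by_type = Counter(r.variant_type() for r in records)
    by_location = Counter(r.location for r in records)
    genes = sorted({r.gene for r in records})
    per_patient: dict[str, list[str]] = {}
    for r in sorted(records, key=lambda r: (r.patient_id, r.gene, r.position)):
        per_patient.setdefault(r.patient_id, []).append(r.gene)
    multiple = {p: gs for p, gs in per_patient.items() if len(gs) >= 2}
    return VariantSummary(
        n_variants=len(records),
        by_type=dict(sorted(by_type.items())),
        by_location=dict(sorted(by_location.items())),
        n_utr=by_location.get("utr5", 0) + by_location.get("utr3", 0),
        n_genes=len(genes),
        genes=genes,
        n_patients=len(per_patient),
        patients_with_multiple=multiple,
        by_inheritance=dict(sorted(Counter(r.inheritance for r in records).items())),
        by_phenotype=dict(sorted(Counter(r.phenotype for r in records).items())),
    )
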
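"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its scenario (the seed is a scenario
field), so identical scenarios give identical outputs, byte for byte. Ground
truth (planted targets, planted expression shifts, rare-by-construction
labels) is returned alongside the data for recovery testing.

The packaged "paper_shape" scenarios reproduce the study's dimensional
skeleton: 3 sequencing pools of 4 ChIP replicates over 15 planted target
genes; a 32-gene expression panel measured in 14 case and 5 control
neurosphere cultures; and a 56-patient variant screen.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .expression import DEFAULT_CEILINGS, CtTable
from .genome_model import Gene, GeneModel, GenomicInterval, Peak, PeakSet
from .variant_filter import DEFAULT_DATABASES as DEFAULT_VARIANT_DATABASES
from .variant_filter import VariantRecord

MIN_PEAK_WIDTH = 50  # sonication fragments are a few hundred bp; never thinner
MIN_GENE_LENGTH = 2_000


def _load_yaml(name: str) -> dict:
    ref = resources.files("dnmt3b_targets.data") / name
    with ref.open() as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class PeakScenario:
    """Replicated ChIP peak sets enriched at planted target-gene TSSs."""

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 20_000_000
    n_genes: int = 200
    gene_length_mean: float = 20_000.0
    gene_length_sd: float = 8_000.0
    planted_targets: tuple[str, ...] = ()
    n_pools: int = 3
    replicates_per_pool: int = 4
    peaks_per_target_per_replicate: int = 1
    background_peaks_per_replicate: int = 25
    peak_width_mean: float = 400.0
    peak_width_sd: float = 150.0
    jitter_sd: float = 300.0
    target_dropout: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_targets", tuple(self.planted_targets))
        if not (0.0 <= self.target_dropout <= 1.0):
            raise ValueError("target_dropout must lie in [0, 1]")
        if min(
            self.n_pools,
            self.replicates_per_pool,
            self.peaks_per_target_per_replicate,
        ) < 0 or self.background_peaks_per_replicate < 0:
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "PeakScenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @classmethod
    def paper_shape(cls) -> "PeakScenario":
        return cls(**_load_yaml("paper_shape_peaks.yaml"))


def simulate_gene_model(scenario: PeakScenario) -> GeneModel:
    """Non-overlapping genes with exon/UTR structure on both strands.

    Genes are placed one per slot on an even grid so they can never overlap;
    lengths follow a truncated normal. Deterministic for a fixed seed.
    """
    if scenario.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([scenario.seed, 0])
    per_chrom = [
        scenario.n_genes // scenario.n_chromosomes
        + (1 if c < scenario.n_genes % scenario.n_chromosomes else 0)
        for c in range(scenario.n_chromosomes)
    ]
    genes: list[Gene] = []
    idx = 0
    for c, n_c in enumerate(per_chrom):
        if n_c == 0:
            continue
        chrom = f"chr{c + 1}"
        slot = scenario.chrom_length // n_c
        if slot < 2 * MIN_GENE_LENGTH:
            raise ValueError(
                "genes cannot be placed without overlap at this density; "
                "increase chrom_length or reduce n_genes"
            )
        for s in range(n_c):
            idx += 1
            max_len = int(slot * 0.8)
            length = int(
                np.clip(
                    rng.normal(scenario.gene_length_mean, scenario.gene_length_sd),
                    MIN_GENE_LENGTH,
                    max_len,
                )
            )
            start = int(slot * s + rng.integers(0, slot - length))
            strand = "+" if rng.random() < 0.5 else "-"
            body = GenomicInterval(chrom, start, start + length, strand)
            n_exons = int(rng.integers(2, 9))
            sub = length // n_exons
            exons = []
            for e in range(n_exons):
                lo = start + e * sub
                exon_len = int(rng.integers(max(sub // 10, 20), max(sub // 2, 40)))
                exon_start = int(lo + rng.integers(0, max(sub - exon_len, 1)))
                exons.append(
                    GenomicInterval(chrom, exon_start, exon_start + exon_len, strand)
                )
            exons.sort(key=lambda iv: iv.start)
            first, last = exons[0], exons[-1]
            utr_left = GenomicInterval(
                chrom, first.start, first.start + max(first.length() // 4, 1), strand
            )
            utr_right = GenomicInterval(
                chrom, last.end - max(last.length() // 4, 1), last.end, strand
            )
            utr5, utr3 = (
                ((utr_left,), (utr_right,))
                if strand == "+"
                else ((utr_right,), (utr_left,))
            )
            genes.append(
                Gene(
                    gene_id=f"g{idx:04d}",
                    symbol=f"GENE{idx}",
                    body=body,
                    exons=tuple(exons),
                    utr5=utr5,
                    utr3=utr3,
                )
            )
    return GeneModel(genes)


def simulate_peaks(
    scenario: PeakScenario, model: GeneModel
) -> tuple[list[PeakSet], dict]:
    """One PeakSet per pool x replicate: target-proximal peaks (TSS + jitter,
    minus dropout) plus uniform background peaks. Returns the peak sets and
    the ground truth (planted target ids)."""
    missing = [t for t in scenario.planted_targets if t not in model]
    if missing:
        raise ValueError(f"planted targets absent from model: {missing}")
    rng = np.random.default_rng([scenario.seed, 1])
    chroms = sorted(model.chromosomes)
    peaksets: list[PeakSet] = []
    for p in range(1, scenario.n_pools + 1):
        for r in range(1, scenario.replicates_per_pool + 1):
            peaks: list[Peak] = []
            for target in scenario.planted_targets:
                for _ in range(scenario.peaks_per_target_per_replicate):
                    if rng.random() < scenario.target_dropout:
                        continue
                    gene = model[target]
                    center = int(round(gene.tss + rng.normal(0, scenario.jitter_sd)))
                    width = int(
                        max(
                            rng.normal(scenario.peak_width_mean, scenario.peak_width_sd),
                            MIN_PEAK_WIDTH,
                        )
                    )
                    start = max(center - width // 2, 0)
                    peaks.append(
                        Peak(
                            GenomicInterval(gene.chrom, start, start + width),
                            score=float(rng.uniform(50, 200)),
                        )
                    )
            for _ in range(scenario.background_peaks_per_replicate):
                chrom = chroms[int(rng.integers(0, len(chroms)))]
                width = int(
                    max(
                        rng.normal(scenario.peak_width_mean, scenario.peak_width_sd),
                        MIN_PEAK_WIDTH,
                    )
                )
                start = int(rng.integers(0, scenario.chrom_length - width))
                peaks.append(
                    Peak(
                        GenomicInterval(chrom, start, start + width),
                        score=float(rng.uniform(10, 60)),
                    )
                )
            peaksets.append(
                PeakSet(pool_id=f"pool{p}", replicate_id=f"chip{r}", peaks=peaks)
            )
    truth = {"planted_targets": list(scenario.planted_targets)}
    return peaksets, truth


# ---------------------------------------------------------------------------
# expression


@dataclass(frozen=True)
class GeneAssay:
    """Per-gene simulation parameters of one qPCR assay."""

    symbol: str
    chemistry: str = "probe_array"
    expressed: bool = True
    baseline_ct: float = 26.0
    sd: float = 0.5
    ddct: float = 0.0  # negative = up-regulated in cases


@dataclass(frozen=True)
class ExpressionScenario:
    """Group-shifted Ct tables with ceiling-censored non-expressed genes."""

    seed: int = 0
    genes: tuple[GeneAssay, ...] = ()
    n_case: int = 14
    n_control: int = 5
    controls: dict = field(
        default_factory=lambda: {
            "probe_array": {"symbol": "S18", "ct_mean": 12.0, "ct_sd": 0.3},
            "dye": {"symbol": "GAPDH", "ct_mean": 16.0, "ct_sd": 0.3},
        }
    )
    missing_rate_nonexpressed: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "genes",
            tuple(
                g if isinstance(g, GeneAssay) else GeneAssay(**g) for g in self.genes
            ),
        )
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need >= 2 samples per group for testable genes")

    @classmethod
    def from_yaml(cls, path) -> "ExpressionScenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @classmethod
    def paper_shape(cls) -> "ExpressionScenario":
        return cls(**_load_yaml("paper_shape_expression.yaml"))

    def truth(self) -> dict:
        return {
            "expressed": sorted(g.symbol for g in self.genes if g.expressed),
            "up_regulated": sorted(
                g.symbol for g in self.genes if g.expressed and g.ddct < 0
            ),
            "down_regulated": sorted(
                g.symbol for g in self.genes if g.expressed and g.ddct > 0
            ),
        }


def simulate_ct_table(scenario: ExpressionScenario) -> tuple[CtTable, dict]:
    """Draw a CtTable under the scenario's planted truth.

    Expressed genes draw Ct ~ Normal(baseline, sd) with the case group
    shifted by +ddct (up-regulation is a negative shift: more template,
    earlier threshold). Non-expressed genes draw above their chemistry's
    ceiling or come back undetermined (missing). Endogenous controls are
    never shifted.
    """
    rng = np.random.default_rng([scenario.seed, 2])
    samples = [f"H{i:02d}" for i in range(1, scenario.n_case + 1)] + [
        f"C{i:02d}" for i in range(1, scenario.n_control + 1)
    ]
    groups = {s: ("case" if s.startswith("H") else "control") for s in samples}
    n = len(samples)
    case_mask = np.array([groups[s] == "case" for s in samples])

    data: dict[str, np.ndarray] = {}
    chemistry: dict[str, str] = {}
    for g in scenario.genes:
        ceiling = DEFAULT_CEILINGS[g.chemistry]
        if g.expressed:
            ct = rng.normal(g.baseline_ct, g.sd, size=n)
            ct[case_mask] += g.ddct
        else:
            ct = ceiling + rng.uniform(0.0, 5.0, size=n)
            miss = rng.random(n) < scenario.missing_rate_nonexpressed
            ct[miss] = np.nan
        data[g.symbol] = ct
        chemistry[g.symbol] = g.chemistry
    endo: dict[str, str] = {}
    for chem, spec in scenario.controls.items():
        sym = spec["symbol"]
        data[sym] = rng.normal(spec["ct_mean"], spec["ct_sd"], size=n)
        chemistry[sym] = chem
        endo[chem] = sym

    ct = pd.DataFrame(data, index=samples)
    table = CtTable(ct, groups, chemistry, endo)
    return table, scenario.truth()


# ---------------------------------------------------------------------------
# variants


@dataclass(frozen=True)
class VariantScenario:
    """Annotated variant tables with MAF draws straddling the rare threshold.

    Each variant is drawn from a three-way mixture: "rare" (every present
    database below 0.01), "common" (every present database well above it)
    and "absent" (no database entries — novel). The mixture class is the
    ground-truth label for filter recovery tests.
    """

    seed: int = 0
    n_patients: int = 56
    genes: tuple[str, ...] = ("GENE1",)
    n_variants: int = 40
    weight_rare: float = 0.3
    weight_common: float = 0.5
    weight_absent: float = 0.2
    db_presence: float = 0.7
    databases: tuple[str, ...] = ("KG_ALL", "KG_EUR", "EVS", "ExAC", "MGP")

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "databases", tuple(self.databases))
        total = self.weight_rare + self.weight_common + self.weight_absent
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights sum to {total}, not 1")

    @classmethod
    def from_yaml(cls, path) -> "VariantScenario":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @classmethod
    def paper_shape(cls) -> "VariantScenario":
        return cls(**_load_yaml("paper_shape_variants.yaml"))


_BASES = ("A", "C", "G", "T")


def simulate_variant_table(
    scenario: VariantScenario,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Variant records plus a truth frame with the per-variant mixture class
    and the implied rare-filter label (any-database rule, threshold 0.01)."""
    rng = np.random.default_rng([scenario.seed, 3])
    records: list[VariantRecord] = []
    truth_rows = []
    for i in range(scenario.n_variants):
        gene = scenario.genes[int(rng.integers(0, len(scenario.genes)))]
        patient = f"P{int(rng.integers(1, scenario.n_patients + 1)):03d}"
        position = int(rng.integers(1_000, 100_000_000))
        cls = rng.choice(
            ["rare", "common", "absent"],
            p=[scenario.weight_rare, scenario.weight_common, scenario.weight_absent],
        )
        maf: dict[str, float] = {}
        if cls != "absent":
            present = [
                db for db in scenario.databases if rng.random() < scenario.db_presence
            ]
            if not present:  # guarantee the class is observable
                present = [
                    scenario.databases[int(rng.integers(0, len(scenario.databases)))]
                ]
            for db in present:
                if cls == "rare":
                    maf[db] = float(10 ** rng.uniform(-5, math.log10(0.009)))
                else:
                    maf[db] = float(rng.uniform(0.02, 0.5))
        if rng.random() < 0.85:
            ref = _BASES[int(rng.integers(0, 4))]
            alt = _BASES[int(rng.integers(0, 4))]
            while alt == ref:
                alt = _BASES[int(rng.integers(0, 4))]
            change = f"c.{int(rng.integers(1, 3000))}{ref}>{alt}"
        else:
            span = int(rng.integers(1, 4))
            ref = "".join(_BASES[int(rng.integers(0, 4))] for _ in range(span))
            alt = "-"
            pos0 = int(rng.integers(1, 3000))
            change = f"c.{pos0}_{pos0 + span - 1}del{ref}"
        location = ["exon", "utr5", "utr3", "intron"][
            int(rng.choice(4, p=[0.6, 0.15, 0.15, 0.1]))
        ]
        records.append(
            VariantRecord(
                gene=gene,
                refseq="",
                chrom=str(int(rng.integers(1, 23))),
                position=position,
                ref=ref,
                alt=alt,
                coding_change=change,
                location=location,
                patient_id=patient,
                inheritance=["father", "mother", "unknown"][int(rng.integers(0, 3))],
                phenotype=["S-HSCR", "L-HSCR", "TCA"][
                    int(rng.choice(3, p=[0.7, 0.2, 0.1]))
                ],
                maf=maf,
            )
        )
        truth_rows.append(
            {
                "index": i,
                "gene": gene,
                "patient_id": patient,
                "class": str(cls),
                "is_rare": cls in ("rare", "absent"),
            }
        )
    return records, pd.DataFrame(truth_rows)


def write_variant_tsv(records: Sequence[VariantRecord], path) -> None:
    """Write records in the annotated-table TSV schema (absent MAFs as N)."""
    rows = []
    for r in records:
        row = {
            "gene": r.gene,
            "refseq": r.refseq,
            "chrom": r.chrom,
            "position": r.position,
            "ref": r.ref,
            "alt": r.alt,
            "coding_change": r.coding_change,
            "location": r.location,
            "rs_id": r.rs_id or "N",
            "patient_id": r.patient_id,
            "inheritance": r.inheritance,
            "phenotype": r.phenotype,
            "familial": str(r.familial).lower(),
            "zygosity": r.zygosity,
        }
        for db in DEFAULT_VARIANT_DATABASES:
            row[db] = f"{r.maf[db]:.6g}" if db in r.maf else "N"
        row["sift"] = r.predictions.get("SIFT", "N")
        row["polyphen"] = r.predictions.get("PolyPhen", "N")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
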
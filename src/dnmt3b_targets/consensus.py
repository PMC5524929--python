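"""Consensus target selection: two voting routes and the panel arithmetic.

Route 1 ("pooled"): peaks are called per pool on merged libraries, annotated
with three tools; a gene is selected when at least ``min_tools`` annotators
report it in each of at least ``min_pools`` pools.

Route 2 ("clustered"): peaks are called per individual ChIP replicate;
overlapping replicate peaks are merged into clusters, clusters supported by
too few replicates are dropped, the survivors are annotated with two tools,
and a gene is selected when it is called from clusters in enough distinct
pools (default) or from enough clusters anywhere (alternative reading).

Panel assembly maps the selected mouse genes to their human orthologs,
removes pseudogenes and appends curated interactor genes, emitting the counts
at every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .genome_model import GeneModel, GenomicInterval, PeakSet, merge_overlapping
from .peak_annotation import AnnotatorConfig, annotate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VoteConfig:
    """Thresholds of the two consensus routes.

    method2_count_pools selects the default reading of route 2 ("clusters
    from >= min_clusters_or_pools distinct pools"); set it False for the
    literal ">= min_clusters_or_pools clusters anywhere" reading.
    """

    min_tools: int = 2
    min_pools: int = 2
    min_clusters_or_pools: int = 2
    cluster_min_replicates: int = 2
    method2_count_pools: bool = True

    def __post_init__(self) -> None:
        if min(
            self.min_tools,
            self.min_pools,
            self.min_clusters_or_pools,
            self.cluster_min_replicates,
        ) < 1:
            raise ValueError("all vote thresholds must be >= 1")


class GeneCallTable:
    """Per-(gene, annotator, pool[, cluster]) presence records.

    Records are unique on the full key; re-adding an existing record is a
    no-op, so call accumulation is idempotent.
    """

    def __init__(self) -> None:
        self._records: set[tuple[str, str, str, str | None]] = set()

    def add(
        self,
        gene_id: str,
        annotator: str,
        pool_id: str,
        cluster_id: str | None = None,
    ) -> None:
        self._records.add((gene_id, annotator, pool_id, cluster_id))

    def add_calls(
        self,
        gene_ids: Iterable[str],
        annotator: str,
        pool_id: str,
        cluster_id: str | None = None,
    ) -> None:
        for g in gene_ids:
            self.add(g, annotator, pool_id, cluster_id)

    def __len__(self) -> int:
        return len(self._records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self._records),
            columns=["gene_id", "annotator", "pool_id", "cluster_id"],
        )

    @property
    def pools(self) -> set[str]:
        return {r[2] for r in self._records}

    @property
    def genes(self) -> set[str]:
        return {r[0] for r in self._records}


def method1_select(gene_calls: GeneCallTable, cfg: VoteConfig) -> set[str]:
    """Route-1 vote: >= min_tools annotators in each of >= min_pools pools."""
    if len(gene_calls.pools) < cfg.min_pools:
        log.warning(
            "only %d pool(s) present but min_pools=%d: empty selection",
            len(gene_calls.pools),
            cfg.min_pools,
        )
        return set()
    tools_per_gene_pool: dict[tuple[str, str], set[str]] = {}
    for gene_id, annotator, pool_id, _ in gene_calls._records:
        tools_per_gene_pool.setdefault((gene_id, pool_id), set()).add(annotator)
    qualifying_pools: dict[str, int] = {}
    for (gene_id, _pool), tools in tools_per_gene_pool.items():
        if len(tools) >= cfg.min_tools:
            qualifying_pools[gene_id] = qualifying_pools.get(gene_id, 0) + 1
    return {g for g, n in qualifying_pools.items() if n >= cfg.min_pools}


@dataclass(frozen=True)
class PeakCluster:
    """A merged region of overlapping replicate peaks within one pool."""

    cluster_id: str
    interval: GenomicInterval
    replicate_ids: frozenset[str]
    pool_id: str


def method2_clusters(
    replicate_peaks: Sequence[PeakSet], cfg: VoteConfig
) -> list[PeakCluster]:
    """Merge per-replicate peaks of one pool into reproducibility clusters.

    Clusters are the maximal merged intervals over the pooled replicate
    peaks; a cluster is retained only when >= cluster_min_replicates distinct
    replicates contribute a peak to it.
    """
    if not replicate_peaks:
        return []
    pools = {ps.pool_id for ps in replicate_peaks}
    if len(pools) != 1:
        raise ValueError(f"replicate peak sets span several pools: {sorted(pools)}")
    pool_id = pools.pop()
    for ps in replicate_peaks:
        if ps.replicate_id is None:
            raise ValueError("replicate_id required for clustering")
    if len(replicate_peaks) == 1 and cfg.cluster_min_replicates > 1:
        log.warning(
            "single replicate in pool %s with cluster_min_replicates=%d: "
            "no clusters retained",
            pool_id,
            cfg.cluster_min_replicates,
        )

    tagged = [
        (p.interval, ps.replicate_id) for ps in replicate_peaks for p in ps
    ]
    merged = merge_overlapping([iv for iv, _ in tagged])
    clusters: list[PeakCluster] = []
    n = 0
    for region in merged:
        contributors = frozenset(rep for iv, rep in tagged if region.overlaps(iv))
        if len(contributors) >= cfg.cluster_min_replicates:
            n += 1
            clusters.append(
                PeakCluster(f"{pool_id}.c{n}", region, contributors, pool_id)
            )
    return clusters


def method2_select(
    clusters_per_pool: Mapping[str, Sequence[PeakCluster]],
    model: GeneModel,
    annotators: Sequence[AnnotatorConfig],
    cfg: VoteConfig,
    combine: str = "union",
) -> set[str]:
    """Route-2 vote over retained clusters.

    Each cluster is annotated by the union (default) or intersection of the
    configured annotators; a gene is selected when its supporting clusters
    come from >= min_clusters_or_pools distinct pools (default reading) or
    number >= min_clusters_or_pools anywhere (method2_count_pools=False).
    """
    if combine not in ("union", "intersection"):
        raise ValueError(f"unknown combine mode {combine!r}")
    support: dict[str, set[str]] = {}  # gene -> pool ids or cluster ids
    for pool_id, clusters in clusters_per_pool.items():
        for cluster in clusters:
            pseudo = PeakSet(
                pool_id=pool_id,
                peaks=[_interval_peak(cluster.interval)],
                replicate_id=None,
            )
            gene_sets = [annotate(pseudo, model, a) for a in annotators]
            genes: set[str] = set.union(*gene_sets) if combine == "union" else set.intersection(*gene_sets)
            tag = pool_id if cfg.method2_count_pools else cluster.cluster_id
            for g in genes:
                support.setdefault(g, set()).add(tag)
    return {g for g, tags in support.items() if len(tags) >= cfg.min_clusters_or_pools}


def _interval_peak(iv: GenomicInterval):
    from .genome_model import Peak

    return Peak(GenomicInterval(iv.chrom, iv.start, iv.end))


# ---------------------------------------------------------------------------
# panel tables and assembly


@dataclass
class PanelTables:
    """Curated lookup tables: gene blocks, ortholog map, interactor genes."""

    shared_genes: list[str]
    method_exclusive_genes: list[str]
    curated_functional_genes: list[str]
    ortholog_map: dict[str, tuple[str, float | None]]
    excluded_pseudogenes: list[str]
    related_genes: list[str]

    def __post_init__(self) -> None:
        blocks = [
            set(self.shared_genes),
            set(self.method_exclusive_genes),
            set(self.curated_functional_genes),
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                common = blocks[i] & blocks[j]
                if common:
                    raise ValueError(f"gene blocks overlap: {sorted(common)}")

    @classmethod
    def from_yaml(cls, path_or_stream) -> "PanelTables":
        if hasattr(path_or_stream, "read"):
            raw = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream) as fh:
                raw = yaml.safe_load(fh)
        omap = {
            mouse: (entry["human"], entry.get("similarity"))
            for mouse, entry in (raw.get("ortholog_map") or {}).items()
        }
        return cls(
            shared_genes=[str(g) for g in raw["shared_genes"]],
            method_exclusive_genes=[str(g) for g in raw["method_exclusive_genes"]],
            curated_functional_genes=[str(g) for g in raw["curated_functional_genes"]],
            ortholog_map=omap,
            excluded_pseudogenes=[str(g) for g in raw.get("excluded_pseudogenes", [])],
            related_genes=[str(g) for g in raw.get("related_genes", [])],
        )

    @classmethod
    def packaged(cls) -> "PanelTables":
        """The curated tables shipped with the package."""
        ref = resources.files("dnmt3b_targets.data") / "panel_tables.yaml"
        with ref.open() as fh:
            return cls.from_yaml(fh)

    def map_to_human(self, mouse_symbol: str) -> str:
        """Human ortholog symbol; genes absent from the map use the uppercase
        symbol (the standard mouse->human symbol convention)."""
        if mouse_symbol in self.ortholog_map:
            return self.ortholog_map[mouse_symbol][0]
        return mouse_symbol.upper()


@dataclass
class PanelReport:
    """Step-by-step gene-panel assembly with the count at every stage."""

    method1: set[str]
    method2: set[str]
    shared: set[str]
    union: set[str]
    with_curated: set[str]
    human_mapped: set[str]
    after_pseudogene_exclusion: set[str]
    final_panel: set[str]
    unmapped: set[str] = field(default_factory=set)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "method1": len(self.method1),
            "method2": len(self.method2),
            "shared": len(self.shared),
            "union": len(self.union),
            "with_curated": len(self.with_curated),
            "human_mapped": len(self.human_mapped),
            "after_pseudogene_exclusion": len(self.after_pseudogene_exclusion),
            "final_panel": len(self.final_panel),
        }

    def to_dict(self) -> dict:
        d = {k: sorted(getattr(self, k)) for k in (
            "method1", "method2", "shared", "union", "with_curated",
            "human_mapped", "after_pseudogene_exclusion", "final_panel",
            "unmapped",
        )}
        d["counts"] = self.counts
        return d


def assemble_target_panel(
    method1: Iterable[str], method2: Iterable[str], tables: PanelTables
) -> PanelReport:
    """Assemble the human expression panel from the two selections.

    Pipeline: union of the two routes -> add curated functional genes ->
    map every mouse gene to its human ortholog -> drop pseudogenes -> append
    curated interactor genes. Genes without a map entry fall back to the
    uppercase-symbol convention and are listed as unmapped only when that
    convention is clearly inapplicable (symbols containing "Rik" or "os"
    suffixes used by unnamed mouse loci), never silently dropped.
    """
    m1, m2 = set(method1), set(method2)
    shared = m1 & m2
    union = m1 | m2
    with_curated = union | set(tables.curated_functional_genes)

    human_mapped: set[str] = set()
    unmapped: set[str] = set()
    for mouse in with_curated:
        if mouse in tables.ortholog_map:
            human_mapped.add(tables.ortholog_map[mouse][0])
        elif "Rik" in mouse or mouse.endswith("os"):
            # unnamed mouse locus with no curated ortholog: flag, keep visible
            unmapped.add(mouse)
            human_mapped.add(mouse)
        else:
            human_mapped.add(mouse.upper())

    after_excl = human_mapped - set(tables.excluded_pseudogenes)
    final_panel = after_excl | set(tables.related_genes)
    return PanelReport(
        method1=m1,
        method2=m2,
        shared=shared,
        union=union,
        with_curated=with_curated,
        human_mapped=human_mapped,
        after_pseudogene_exclusion=after_excl,
        final_panel=final_panel,
        unmapped=unmapped,
    )


def packaged_panel_report() -> PanelReport:
    """Panel assembly over the packaged curated tables.

    The shared block enters as the two-route intersection; the exclusive
    block is attributed to route 1 (the per-route membership of the exclusive
    genes is not recorded in the curated tables, so the split is a labeling
    convention — union, shared and all downstream counts are unaffected).
    """
    tables = PanelTables.packaged()
    m1 = set(tables.shared_genes) | set(tables.method_exclusive_genes)
    m2 = set(tables.shared_genes)
    return assemble_target_panel(m1, m2, tables)
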
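"""Ct-based expression calling, ΔCt differential expression and clustering.

The qPCR model: Ct is the amplification cycle at which a gene's signal
crosses threshold — more template means an *earlier* (lower) Ct. Expression
relative to an endogenous control is ΔCt = Ct(gene) - Ct(control); the
between-group effect is ΔΔCt = mean ΔCt(case) - mean ΔCt(control) and the
fold change is 2^-ΔΔCt, so up-regulation in cases means a *negative* ΔΔCt.

Each assay chemistry (hydrolysis-probe array plates vs intercalating-dye
assays) has its own detection ceiling — Ct values at or above the ceiling
are treated as non-detection — and its own designated endogenous control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

CHEMISTRIES = ("probe_array", "dye")
DEFAULT_CEILINGS: dict[str, float] = {"probe_array": 32.0, "dye": 35.0}
GROUPS = ("case", "control")


class CtTable:
    """Sample x gene Ct matrix with group labels, chemistries and controls.

    ct is a DataFrame (rows = sample ids, columns = gene symbols); NaN means
    undetermined (no amplification before the run's cycle limit). groups maps
    sample -> {case, control}; chemistry maps gene -> assay chemistry;
    endogenous_controls maps chemistry -> its reference gene, which must be
    present in the table.
    """

    def __init__(
        self,
        ct: pd.DataFrame,
        groups: Mapping[str, str],
        chemistry: Mapping[str, str],
        endogenous_controls: Mapping[str, str],
    ):
        self.ct = ct.astype(float)
        self.groups = pd.Series(dict(groups), name="group").reindex(self.ct.index)
        self.chemistry = pd.Series(dict(chemistry), name="chemistry").reindex(
            self.ct.columns
        )
        self.endogenous_controls = dict(endogenous_controls)
        self._validate()

    def _validate(self) -> None:
        if self.groups.isna().any():
            missing = list(self.ct.index[self.groups.isna()])
            raise ValueError(f"samples without group label: {missing}")
        bad = set(self.groups) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        if self.chemistry.isna().any():
            missing = list(self.ct.columns[self.chemistry.isna()])
            raise ValueError(f"genes without chemistry: {missing}")
        bad = set(self.chemistry) - set(CHEMISTRIES)
        if bad:
            raise ValueError(f"unknown chemistries {sorted(bad)}")
        for chem in self.chemistry.unique():
            control = self.endogenous_controls.get(chem)
            if control is None:
                raise ValueError(f"no endogenous control designated for {chem!r}")
            if control not in self.ct.columns:
                raise ValueError(f"endogenous control {control!r} absent from table")
        with np.errstate(invalid="ignore"):
            if (self.ct.to_numpy() <= 0).any():
                raise ValueError("Ct values must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.ct.index)

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def control_genes(self) -> set[str]:
        return set(self.endogenous_controls.values())

    @property
    def target_genes(self) -> list[str]:
        return [g for g in self.genes if g not in self.control_genes]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read_tsv(cls, path) -> "CtTable":
        """Read the long-format TSV (sample_id, group, gene, chemistry, ct,
        is_endogenous_control); empty/Undetermined ct cells become NaN."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        need = {"sample_id", "group", "gene", "chemistry", "ct", "is_endogenous_control"}
        missing = need - set(df.columns)
        if missing:
            raise ValueError(f"Ct TSV missing columns {sorted(missing)}")
        df["ct_val"] = pd.to_numeric(
            df["ct"].replace({"": np.nan, "Undetermined": np.nan, "NA": np.nan}),
            errors="raise",
        )
        ct = df.pivot(index="sample_id", columns="gene", values="ct_val")
        groups = df.drop_duplicates("sample_id").set_index("sample_id")["group"]
        chem = df.drop_duplicates("gene").set_index("gene")["chemistry"]
        controls = (
            df[df["is_endogenous_control"].str.lower().isin(("1", "true", "yes"))]
            .drop_duplicates("gene")
            .set_index("gene")["chemistry"]
        )
        endo = {chemistry: gene for gene, chemistry in controls.items()}
        return cls(ct, groups.to_dict(), chem.to_dict(), endo)

    def write_tsv(self, path) -> None:
        rows = []
        for sample in self.samples:
            for gene in self.genes:
                v = self.ct.at[sample, gene]
                rows.append(
                    {
                        "sample_id": sample,
                        "group": self.groups[sample],
                        "gene": gene,
                        "chemistry": self.chemistry[gene],
                        "ct": "" if math.isnan(v) else f"{v:.4f}",
                        "is_endogenous_control": str(gene in self.control_genes).lower(),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def call_expressed(
    table: CtTable,
    ceilings: Mapping[str, float] | None = None,
    expressed_fraction: float = 0.5,
) -> set[str]:
    """Genes positively expressed under the chemistry-specific Ct ceilings.

    A Ct counts as detection only when *strictly below* its chemistry's
    ceiling; missing values count as non-detection. A target gene is called
    expressed when the detected fraction of samples reaches
    ``expressed_fraction`` in both the case and the control group.
    Endogenous controls are reference assays, not targets, and are excluded
    from the returned set.
    """
    ceilings = dict(DEFAULT_CEILINGS, **(ceilings or {}))
    expressed: set[str] = set()
    for gene in table.target_genes:
        ceiling = ceilings[table.chemistry[gene]]
        values = table.ct[gene]
        if values.isna().all():
            log.info("gene %s: all Ct missing -> not expressed", gene)
            continue
        detected = values < ceiling  # NaN compares False: non-detection
        ok = True
        for group in GROUPS:
            mask = table.groups == group
            n = int(mask.sum())
            if n == 0 or detected[mask].sum() / n < expressed_fraction:
                ok = False
                break
        if ok:
            expressed.add(gene)
    return expressed


def delta_ct(table: CtTable) -> pd.DataFrame:
    """Per-sample ΔCt matrix (samples x target genes).

    ΔCt(g, s) = Ct(g, s) - Ct(control_gene(chemistry(g)), s); missing Ct on
    either side propagates to NaN. Samples missing their endogenous-control
    Ct are excluded (NaN) for the affected chemistry's genes.
    """
    out = pd.DataFrame(index=table.ct.index, columns=table.target_genes, dtype=float)
    for gene in table.target_genes:
        control = table.endogenous_controls[table.chemistry[gene]]
        ref = table.ct[control]
        if ref.isna().any():
            log.warning(
                "endogenous control %s missing for samples %s: excluded",
                control,
                list(table.ct.index[ref.isna()]),
            )
        out[gene] = table.ct[gene] - ref
    return out


@dataclass(frozen=True)
class DiffExpResult:
    """Per-gene two-group comparison of ΔCt."""

    gene: str
    mean_case: float
    sem_case: float
    n_case: int
    mean_control: float
    sem_control: float
    n_control: int
    t_statistic: float
    p_value: float
    direction: str  # up = higher expression (lower ΔCt) in cases
    fold_change: float  # 2^-ΔΔCt
    significant: bool
    testable: bool = True
    p_adjusted: float | None = None


class DiffExpResults:
    """Container for the per-gene results with a summary table."""

    def __init__(self, results: Sequence[DiffExpResult], alpha: float):
        self.results = list(results)
        self.alpha = alpha

    def __iter__(self):
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, gene: str) -> DiffExpResult:
        for r in self.results:
            if r.gene == gene:
                return r
        raise KeyError(gene)

    @property
    def significant_up(self) -> list[str]:
        return [r.gene for r in self.results if r.significant and r.direction == "up"]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.results]).set_index("gene")
        return df.sort_values("p_value")

    def summary(self) -> str:
        df = self.to_frame()
        cols = ["mean_case", "mean_control", "t_statistic", "p_value",
                "fold_change", "direction", "significant"]
        lines = [
            "Differential expression (Student's t on per-sample ΔCt, "
            f"alpha={self.alpha:g})",
            f"genes tested: {sum(r.testable for r in self.results)}"
            f" / {len(self.results)}; significant up-regulated: "
            f"{len(self.significant_up)}",
            "",
            df[cols].to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")


def differential_expression(
    dct: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.05,
    equal_var: bool = True,
    adjust: str | None = None,
) -> DiffExpResults:
    """Two-sided t-test on per-sample ΔCt for every gene column.

    The default is the classical pooled-variance (Student's) test;
    ``equal_var=False`` selects Welch's variant. Genes with fewer than two
    non-missing values in either group are flagged untestable rather than
    dropped. When both groups are constant and equal the test is degenerate
    and reported as t=0, p=1; constant but different groups get p=0 with an
    infinite t (the zero-variance limit). ``adjust="bh"`` adds
    Benjamini-Hochberg adjusted p values; the significance flag always uses
    the raw p value against alpha, matching the uncorrected contract.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    results: list[DiffExpResult] = []
    for gene in dct.columns:
        x = dct[gene][groups.reindex(dct.index) == "case"].dropna().to_numpy()
        y = dct[gene][groups.reindex(dct.index) == "control"].dropna().to_numpy()
        mean_case = float(np.mean(x)) if len(x) else float("nan")
        mean_control = float(np.mean(y)) if len(y) else float("nan")
        ddct = mean_case - mean_control
        direction = "up" if ddct < 0 else "down"
        base = dict(
            gene=gene,
            mean_case=mean_case,
            sem_case=_sem(x),
            n_case=len(x),
            mean_control=mean_control,
            sem_control=_sem(y),
            n_control=len(y),
            direction=direction,
            fold_change=float(2.0 ** -ddct) if not math.isnan(ddct) else float("nan"),
        )
        if len(x) < 2 or len(y) < 2:
            log.warning("gene %s: <2 values per group, untestable", gene)
            results.append(
                DiffExpResult(
                    **base,
                    t_statistic=float("nan"),
                    p_value=float("nan"),
                    significant=False,
                    testable=False,
                )
            )
            continue
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            # zero-variance limit: identical constants are a null result,
            # different constants an arbitrarily strong one
            if mean_case == mean_control:
                t_stat, p = 0.0, 1.0
            else:
                t_stat = float("inf") if mean_case > mean_control else float("-inf")
                p = 0.0
        else:
            t_stat, p = stats.ttest_ind(x, y, equal_var=equal_var)
            t_stat, p = float(t_stat), float(p)
        results.append(
            DiffExpResult(
                **base, t_statistic=t_stat, p_value=p, significant=p <= alpha
            )
        )
    out = DiffExpResults(results, alpha)
    if adjust == "bh":
        tested = [r for r in out.results if r.testable]
        order = np.argsort([r.p_value for r in tested])
        m = len(tested)
        adj = np.empty(m)
        prev = 1.0
        for rank, idx in enumerate(reversed(order), start=0):
            i = m - rank
            prev = min(prev, tested[idx].p_value * m / i)
            adj[idx] = prev
        lookup = {r.gene: a for r, a in zip(tested, adj)}
        out.results = [
            DiffExpResult(**{**vars(r), "p_adjusted": lookup.get(r.gene)})
            for r in out.results
        ]
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return out


@dataclass
class ClusterResult:
    """Average-linkage clustering of ΔCt profiles (genes and samples)."""

    gene_order: list[str]
    sample_order: list[str]
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray


def _pearson_distance_matrix(X: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson r distances; zero-variance rows get distance 2."""
    n = X.shape[0]
    D = np.zeros((n, n))
    sd = X.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d zero-variance profile(s): distance set to 2", degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X)
    for i in range(n):
        for j in range(i + 1, n):
            if degenerate[i] or degenerate[j]:
                D[i, j] = D[j, i] = 2.0
            else:
                D[i, j] = D[j, i] = 1.0 - C[i, j]
    return squareform(D, checks=False)


def cluster_profiles(dct: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster genes and samples by Pearson correlation with
    average linkage (UPGMA); distance is 1 - r, so proportional profiles
    merge at height 0 and anti-correlated ones at height 2.

    Rows (samples) or columns (genes) containing missing values are dropped
    before clustering; at least two complete genes are required.
    """
    complete = dct.dropna(axis=0, how="any")
    if complete.shape[1] < 2 or complete.shape[0] < 2:
        raise ValueError("need >= 2 genes and >= 2 complete samples to cluster")
    gene_matrix = complete.to_numpy().T  # genes x samples
    sample_matrix = complete.to_numpy()  # samples x genes
    gene_link = linkage(_pearson_distance_matrix(gene_matrix), method="average")
    sample_link = linkage(_pearson_distance_matrix(sample_matrix), method="average")
    return ClusterResult(
        gene_order=[complete.columns[i] for i in leaves_list(gene_link)],
        sample_order=[complete.index[i] for i in leaves_list(sample_link)],
        gene_linkage=gene_link,
        sample_linkage=sample_link,
    )


def plot_heatmap(
    dct: pd.DataFrame,
    clustering: ClusterResult | None = None,
    path=None,
):
    """ΔCt heat map in the red/green convention (red = lower ΔCt = higher
    expression in that sample). Returns the matplotlib Figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if clustering is None:
        clustering = cluster_profiles(dct)
    data = dct.loc[clustering.sample_order, clustering.gene_order].to_numpy().T
    fig, ax = plt.subplots(
        figsize=(max(4, 0.4 * data.shape[1]), max(3, 0.3 * data.shape[0]))
    )
    im = ax.imshow(data, aspect="auto", cmap="RdYlGn")
    ax.set_yticks(range(len(clustering.gene_order)), clustering.gene_order, fontsize=7)
    ax.set_xticks(
        range(len(clustering.sample_order)),
        clustering.sample_order,
        rotation=90,
        fontsize=7,
    )
    fig.colorbar(im, ax=ax, label="ΔCt")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
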
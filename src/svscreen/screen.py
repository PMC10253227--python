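"""Gene-level enrichment analysis of a pooled knockout screen.

The analysis takes a guide-by-sample count table and asks, per gene,
whether its guides changed abundance under treatment relative to a
control population:

1. guides with zero reads in any control sample are removed, then genes
   left with fewer than four guides are dropped entirely;
2. each sample is depth-normalized to reads per million (RPM);
3. replicate samples are averaged within each (condition, dose,
   timepoint);
4. per guide and treated condition, the log2 ratio
   ``log2((treated + c) / (control + c))`` is computed against the
   timepoint-matched control column (pseudocount ``c`` keeps treated
   zeros finite);
5. each guide's logFC is the mean of its ratios across the treated
   conditions and a gene's logFC is the mean over its guides; the gene's
   significance comes from a two-sample Kolmogorov-Smirnov test of its
   guides' logFC values against the logFC values of all guides (the
   gene's own guides included in the background) — guide-level values
   are independent across guides, which keeps the test calibrated,
   whereas pooling per-condition ratios would correlate values within a
   guide through the shared control denominator;
6. Benjamini-Hochberg adjustment across genes; a *hit* is a gene with
   logFC > 0 and FDR < 0.05.

The statsmodels-style surface is :class:`ScreenModel` (data + options)
whose :meth:`ScreenModel.fit` returns a :class:`ScreenResults` carrying
the per-gene table, the intermediate log-ratio matrix, the filter report
and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ConfigError, DataError, StatError
from .io import (
    CountMatrix,
    NormalizedMatrix,
    SgRNALibrary,
    write_gene_results,
)

RPM_SCALE = 1e6
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_ALPHA = 0.05
#: "over 3" guides must survive filtering for a gene to be analyzed
MIN_SGRNAS = 4


@dataclass
class FilterReport:
    """Accounting of the sgRNA/gene filtering stage."""

    n_guides_in: int
    n_genes_in: int
    guides_zero_in_control: list[str]
    genes_too_few_guides: list[str]
    n_guides_out: int
    n_genes_out: int

    def __str__(self) -> str:
        return (
            f"filter: {self.n_guides_in} guides / {self.n_genes_in} genes in; "
            f"{len(self.guides_zero_in_control)} guides with a zero control "
            f"count removed; {len(self.genes_too_few_guides)} genes with "
            f"< {MIN_SGRNAS} surviving guides removed; "
            f"{self.n_guides_out} guides / {self.n_genes_out} genes retained"
        )


def filter_sgrnas(
    counts: CountMatrix,
    library: SgRNALibrary,
    control_condition: str = "control",
    min_sgrnas: int = MIN_SGRNAS,
) -> tuple[CountMatrix, FilterReport]:
    """Remove control-zero guides, then under-covered genes.

    A guide is removed if it has zero reads in *any* sample of the
    control condition (before replicate averaging); a gene is removed —
    with all its remaining guides — if fewer than ``min_sgrnas`` of its
    guides survive.
    """
    counts.check_library(library)
    control_samples = counts.samples_where(control_condition)
    if len(control_samples) == 0:
        raise ConfigError(
            f"no samples with condition {control_condition!r} in metadata"
        )
    genes = library.genes.reindex(counts.guides)
    ctrl = counts.counts[control_samples]
    zero_any = (ctrl == 0).any(axis=1)
    dropped_guides = list(counts.guides[zero_any])
    kept = counts.counts.index[~zero_any]

    sizes = genes.loc[kept].groupby(genes.loc[kept]).size()
    small_genes = sorted(sizes.index[sizes < min_sgrnas])
    keep_final = [g for g in kept if genes[g] not in set(small_genes)]

    report = FilterReport(
        n_guides_in=len(counts.guides),
        n_genes_in=int(genes.nunique()),
        guides_zero_in_control=dropped_guides,
        genes_too_few_guides=small_genes,
        n_guides_out=len(keep_final),
        n_genes_out=int(genes.loc[keep_final].nunique()),
    )
    return counts.subset_guides(keep_final), report


def normalize_counts(counts: CountMatrix) -> NormalizedMatrix:
    """Depth-normalize each sample to reads per million."""
    totals = counts.counts.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise DataError(f"sample {zero[0]!r} has zero total reads")
    values = counts.counts / totals * RPM_SCALE
    return NormalizedMatrix(values, counts.samples.copy())


def average_replicates(norm: NormalizedMatrix) -> NormalizedMatrix:
    """Arithmetic mean per guide across replicates of each condition.

    Output has one column per (condition, dose, timepoint), named
    ``<condition>|<dose>|t<timepoint>``, in sorted key order.
    """
    keys = norm.samples[["condition", "dose", "timepoint"]].copy()
    keys["dose"] = keys["dose"].fillna("")
    groups = sorted(
        keys.groupby(["condition", "dose", "timepoint"], sort=True).groups.items()
    )
    cols = {}
    meta_rows = []
    for (cond, dose, t), sample_ids in groups:
        label = f"{cond}|{dose}|t{t:g}"
        cols[label] = norm.values[list(sample_ids)].mean(axis=1)
        meta_rows.append((label, cond, dose, t, len(sample_ids)))
    meta = pd.DataFrame(
        meta_rows,
        columns=["sample_id", "condition", "dose", "timepoint", "replicate"],
    ).set_index("sample_id")
    return NormalizedMatrix(pd.DataFrame(cols), meta)


def compute_log_ratios(
    norm: NormalizedMatrix,
    control_condition: str = "control",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-guide log2 ratios of each treated condition vs the control.

    Expects a replicate-averaged matrix.  Each treated column is divided
    by the control column with the same timepoint when one exists,
    otherwise by the unique control column; the pseudocount is added to
    both numerator and denominator on the RPM scale, so every ratio is
    finite.
    """
    meta = norm.samples
    treated_cols = meta.index[meta["condition"] == "treated"]
    control_cols = meta.index[meta["condition"] == control_condition]
    if len(control_cols) == 0:
        raise ConfigError(f"no {control_condition!r} column in matrix")
    if len(treated_cols) == 0:
        raise ConfigError("no treated columns in matrix")
    by_time = {meta.loc[c, "timepoint"]: c for c in control_cols}
    out = {}
    for col in treated_cols:
        t = meta.loc[col, "timepoint"]
        if t in by_time:
            ctrl = by_time[t]
        elif len(control_cols) == 1:
            ctrl = control_cols[0]
        else:
            raise ConfigError(
                f"no {control_condition!r} column at timepoint {t:g} for {col!r} "
                f"and more than one control column to choose from"
            )
        out[col] = np.log2(
            (norm.values[col] + pseudocount) / (norm.values[ctrl] + pseudocount)
        )
    return pd.DataFrame(out)


def gene_logfc(ratios: pd.DataFrame, library: SgRNALibrary) -> pd.Series:
    """Flat mean of a gene's guide ratios over guides x treated conditions.

    The table is rectangular (every guide has every condition), so the
    flat mean equals the gene-wise mean of per-guide row means.
    """
    genes = library.genes.reindex(ratios.index)
    return ratios.mean(axis=1).groupby(genes).mean()


def guide_logfc(ratios: pd.DataFrame) -> pd.Series:
    """Per-guide logFC: mean log2 ratio across the treated conditions."""
    return ratios.mean(axis=1)


def gene_ks_test(
    ratios: pd.DataFrame, library: SgRNALibrary, gene: str
) -> tuple[float, float]:
    """Two-sample KS test of one gene's guide logFCs vs all guides'.

    The gene sample is its guides' logFC values (one value per guide:
    the mean ratio over treated conditions); the background is every
    guide's logFC, the tested gene's own guides included.  Returns the
    sup ECDF gap and the asymptotic two-sided p-value, clamped into
    (0, 1].
    """
    genes = library.genes.reindex(ratios.index)
    mask = (genes == gene).to_numpy()
    if not mask.any():
        raise StatError(f"gene {gene!r} not present in ratio table")
    per_guide = guide_logfc(ratios).to_numpy()
    return _ks_against_background(per_guide[mask], per_guide)


def _ks_against_background(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if x.size < 2:
        raise StatError("need at least 2 values in the gene sample")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    p = float(min(max(res.pvalue, np.finfo(float).tiny), 1.0))
    return float(res.statistic), p


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR, returned in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any() or np.isnan(p).any():
        raise StatError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class ScreenModel:
    """Enrichment model for one screen: counts + library + options.

    Parameters
    ----------
    counts : CountMatrix
        Raw guide counts with sample metadata.
    library : SgRNALibrary
        guide -> gene map; every counted guide must be in it.
    control_condition : str
        Metadata condition used as the log-ratio denominator
        (default ``"control"``, the vehicle/DMSO arm).
    pseudocount : float
        Added to both sides of each ratio, RPM scale.
    alpha : float
        FDR threshold for hit calling.
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: SgRNALibrary,
        control_condition: str = "control",
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        alpha: float = DEFAULT_ALPHA,
        min_sgrnas: int = MIN_SGRNAS,
    ) -> None:
        counts.check_library(library)
        self.counts = counts
        self.library = library
        self.control_condition = control_condition
        self.pseudocount = float(pseudocount)
        self.alpha = float(alpha)
        self.min_sgrnas = int(min_sgrnas)

    def fit(self) -> "ScreenResults":
        """Run the full filter -> normalize -> ratio -> test pipeline."""
        filtered, report = filter_sgrnas(
            self.counts,
            self.library,
            control_condition=self.control_condition,
            min_sgrnas=self.min_sgrnas,
        )
        norm = normalize_counts(filtered)
        averaged = average_replicates(norm)
        ratios = compute_log_ratios(
            averaged, self.control_condition, self.pseudocount
        )
        genes = self.library.genes.reindex(ratios.index)
        logfc = gene_logfc(ratios, self.library)

        per_guide = guide_logfc(ratios).to_numpy()
        gene_order = sorted(genes.unique())
        rows = []
        for g in gene_order:
            mask = (genes == g).to_numpy()
            stat, p = _ks_against_background(per_guide[mask], per_guide)
            rows.append((g, int(mask.sum()), float(logfc[g]), stat, p))
        table = pd.DataFrame(
            rows, columns=["gene", "n_sgrnas", "logFC", "ks_stat", "p_value"]
        )
        table["fdr"] = bh_adjust(table["p_value"])
        table["hit"] = (table["logFC"] > 0) & (table["fdr"] < self.alpha)
        table = table.sort_values(
            ["logFC", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        return ScreenResults(self, table, ratios, report)


@dataclass
class ScreenResults:
    """Fitted screen: per-gene statistics and intermediates.

    ``gene_table`` has one row per analyzed gene with columns
    ``gene, n_sgrnas, logFC, ks_stat, p_value, fdr, hit``, sorted by
    descending logFC.
    """

    model: ScreenModel
    gene_table: pd.DataFrame
    log_ratios: pd.DataFrame
    filter_report: FilterReport

    @property
    def hits(self) -> pd.DataFrame:
        """Enriched genes: logFC > 0 and FDR below the model's alpha."""
        return self.gene_table[self.gene_table["hit"]]

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.gene_table["gene"])

    def ranks(self) -> pd.Series:
        """Gene ranks by logFC, 1 = highest; ties get average ranks."""
        from .compare import rank_by_logfc

        return rank_by_logfc(self.gene_table)

    def compare(self, control: "ScreenResults") -> "ScreenComparison":
        """Relative-rank comparison of this (treated) screen vs a control."""
        from .compare import compare_screens

        return compare_screens(self.gene_table, control.gene_table)

    def to_tsv(self, path) -> None:
        write_gene_results(self.gene_table, path)

    def summary(self, top: int = 10) -> str:
        t = self.gene_table
        lines = [
            "Pooled screen gene enrichment",
            "=" * 64,
            str(self.filter_report),
            f"control condition: {self.model.control_condition!r}; "
            f"pseudocount {self.model.pseudocount}; alpha {self.model.alpha}",
            f"genes tested: {len(t)}; hits (logFC > 0, FDR < "
            f"{self.model.alpha:g}): {int(t['hit'].sum())}",
            "-" * 64,
            f"top {min(top, len(t))} genes by logFC:",
            t.head(top).to_string(
                index=False,
                float_format=lambda v: f"{v:.4g}",
            ),
        ]
        return "\n".join(lines)


def analyze_screen(
    counts: CountMatrix,
    library: SgRNALibrary,
    control_condition: str = "control",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    alpha: float = DEFAULT_ALPHA,
    min_sgrnas: int = MIN_SGRNAS,
) -> ScreenResults:
    """Functional wrapper: build a :class:`ScreenModel` and fit it."""
    return ScreenModel(
        counts,
        library,
        control_condition=control_condition,
        pseudocount=pseudocount,
        alpha=alpha,
        min_sgrnas=min_sgrnas,
    ).fit()
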
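"""Cross-screen synthetic-viability scoring.

A gene that rescues fitness specifically under treatment should rank
near the top of the treated screen but not of an untreated control
screen.  Both screens' genes are ranked by logFC (rank 1 = highest) and
each shared gene gets a *relative score* = control rank / treated rank:
a score above 1 means the gene's knockout helps more under treatment,
and very large scores (the field's informal threshold is 100) mark
strongly treatment-specific rescues.

Whether a whole gene set (e.g. a pathway) is skewed toward scores > 1 is
tested with the hypergeometric distribution: the population is every
gene present in both screens, successes are those with score > 1, and
the draw is the set's shared members.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .exceptions import DataError, StatError
from .io import GeneSet, write_comparison

#: relative score above which a gene is reported as strongly treatment-specific
NOTABLE_SCORE = 100.0


def rank_by_logfc(results: pd.DataFrame) -> pd.Series:
    """Rank genes by logFC, 1 = highest; ties get average positional ranks."""
    if len(results) == 0:
        raise DataError("cannot rank an empty result table")
    r = results.set_index("gene")["logFC"].rank(ascending=False, method="average")
    return r.rename("rank")


def relative_scores(
    ranks_control: pd.Series, ranks_treated: pd.Series
) -> pd.DataFrame:
    """Per-gene relative score = control rank / treated rank.

    Genes present in only one ranking are kept with ``expressed=False``
    and no score; an empty intersection is an error.
    """
    shared = ranks_control.index.intersection(ranks_treated.index)
    if len(shared) == 0:
        raise DataError("no genes shared between the two screens")
    all_genes = ranks_control.index.union(ranks_treated.index).sort_values()
    df = pd.DataFrame(index=pd.Index(all_genes, name="gene"))
    df["rank_control"] = ranks_control.reindex(all_genes)
    df["rank_treated"] = ranks_treated.reindex(all_genes)
    df["expressed"] = df.index.isin(shared)
    df["relative_score"] = df["rank_control"] / df["rank_treated"]
    df.loc[~df["expressed"], "relative_score"] = np.nan
    return df.reset_index()


@dataclass
class ScreenComparison:
    """Joined rankings of a treated and a control screen.

    ``table`` has columns gene, rank_control, rank_treated, expressed,
    relative_score (NaN for genes absent from either screen).
    """

    table: pd.DataFrame

    @property
    def expressed(self) -> pd.DataFrame:
        return self.table[self.table["expressed"]]

    def score(self, gene: str) -> float:
        row = self.table[self.table["gene"] == gene]
        if len(row) == 0:
            raise KeyError(gene)
        return float(row["relative_score"].iloc[0])

    def swapped(self) -> "ScreenComparison":
        """The comparison with the two screens exchanged (reciprocal scores)."""
        t = self.table.copy()
        t[["rank_control", "rank_treated"]] = t[["rank_treated", "rank_control"]].to_numpy()
        t["relative_score"] = t["rank_control"] / t["rank_treated"]
        t.loc[~t["expressed"], "relative_score"] = np.nan
        return ScreenComparison(t)

    def set_test(self, gene_set: GeneSet | frozenset[str]) -> "SetScoreTest":
        return set_relative_score_test(self, gene_set)

    def to_tsv(self, path) -> None:
        write_comparison(self.table, path)

    def summary(self, top: int = 10) -> str:
        e = self.expressed.sort_values(
            ["relative_score", "gene"], ascending=[False, True]
        )
        n_above = int((e["relative_score"] > 1).sum())
        n_notable = int((e["relative_score"] > NOTABLE_SCORE).sum())
        return "\n".join(
            [
                "Cross-screen relative-rank comparison",
                "=" * 64,
                f"genes in both screens: {len(e)}; score > 1: {n_above}; "
                f"score > {NOTABLE_SCORE:g}: {n_notable}",
                "-" * 64,
                f"top {min(top, len(e))} genes by relative score:",
                e.head(top).to_string(index=False, float_format=lambda v: f"{v:.4g}"),
            ]
        )


def compare_screens(
    treated_results: pd.DataFrame, control_results: pd.DataFrame
) -> ScreenComparison:
    """Build the relative-rank comparison from two gene result tables."""
    rc = rank_by_logfc(control_results)
    rt = rank_by_logfc(treated_results)
    return ScreenComparison(relative_scores(rc, rt))


def hypergeom_upper(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n`` draws without replacement from a
    population of ``N`` containing ``K`` successes.  Computed by exact
    summation of the PMF in log space.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise StatError(
            f"inconsistent hypergeometric arguments k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    upper = min(n, K)
    xs = np.arange(k, upper + 1)
    if xs.size == 0:
        return 0.0
    log_pmf = (
        _log_comb(K, xs)
        + _log_comb(N - K, n - xs)
        - _log_comb(N, n)
    )
    return float(min(1.0, np.exp(logsumexp(log_pmf))))


def _log_comb(a: int | np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where((b < 0) | (b > a), -np.inf, out)


@dataclass(frozen=True)
class SetScoreTest:
    """Over-representation of relative scores > 1 within one gene set."""

    set_name: str
    n_expressed: int
    n_above_1: int
    population: int
    population_above_1: int
    p: float
    members_above_1: tuple[str, ...]
    members_above_100: tuple[str, ...]


def set_relative_score_test(
    comparison: ScreenComparison, gene_set: GeneSet | frozenset[str]
) -> SetScoreTest:
    """Hypergeometric test for a set's excess of relative scores > 1.

    Population = genes expressed in both screens; successes = those with
    score strictly above 1 (ties at exactly 1 count as not-above);
    draws = the set's expressed members.  A set with no expressed member
    returns p = 1 by convention.  Members with score > 100 are reported
    alongside.
    """
    if isinstance(gene_set, GeneSet):
        name, members = gene_set.name, gene_set.genes
    else:
        name, members = "<set>", frozenset(gene_set)
    e = comparison.expressed.set_index("gene")["relative_score"]
    N = len(e)
    K = int((e > 1).sum())
    in_set = e.loc[e.index.intersection(members)]
    n = len(in_set)
    above = in_set[in_set > 1]
    k = len(above)
    p = 1.0 if n == 0 else hypergeom_upper(k, n, K, N)
    return SetScoreTest(
        set_name=name,
        n_expressed=n,
        n_above_1=k,
        population=N,
        population_above_1=K,
        p=p,
        members_above_1=tuple(sorted(above.index)),
        members_above_100=tuple(sorted(in_set[in_set > NOTABLE_SCORE].index)),
    )
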
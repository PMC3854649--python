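"""Fold-change-weighted and classical over-representation enrichment tests.

Four tests over a gene-set collection and per-gene statistics:

``hypergeometric``
    Classical ORA.  With ``N`` genes on the array, ``m`` of them
    significant, ``n`` in the pathway and ``k`` both, the p-value is the
    strict upper hypergeometric tail ``P(X > k)``.

``chi2``
    The 2x2 contingency approximation to the same question, with rows
    in/not-in pathway and columns genes-on-array / significant-genes,
    tested against a chi-squared distribution with 1 degree of freedom.

``weighted_hypergeometric``
    Every gene carries a weight ``g_i = |log2 fold change|^a``.  Member
    scores are rounded to whole numbers and summed into a discrete
    pathway score ``k``.  A *pseudo pathway* makes this compatible with
    the discrete hypergeometric law: with ``Q`` the rounded maximum
    member score, each of the ``N`` array genes is replicated ``Q``
    times (population ``N*Q``), of which ``S`` copies — the rounded
    score summed over the whole array — count as significant, and the
    pathway draws ``n*Q`` copies.  The p-value is ``P(X > k)`` under
    that law.  When every gene score is the 0/1 significance indicator
    this reduces exactly to the classical test.

``weighted_chi2``
    The same weighting without discretization: the significant-genes
    column of the 2x2 table is replaced by the unrounded pathway score
    ``k`` and the array-wide score total ``S``.

All tests report Benjamini-Hochberg FDR alongside raw p-values and a
deterministic rank (p ascending, ties broken by larger score then
set identifier).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geneset_io import GeneSet, GeneSetCollection

__all__ = [
    "ArrayContext",
    "ContingencyTable",
    "ScoredPathway",
    "METHODS",
    "gene_score",
    "score_pathway",
    "array_context",
    "hypergeom_tail",
    "chi2_statistic",
    "bh_fdr",
    "enrich_hypergeometric",
    "enrich_chi2",
    "enrich_weighted_hypergeometric",
    "enrich_weighted_chi2",
    "enrich",
    "rank_and_report",
]

METHODS = ("hypergeometric", "chi2", "weighted_hypergeometric", "weighted_chi2")

RESULT_COLUMNS = [
    "set_id",
    "name",
    "p_value",
    "fdr",
    "pathway_score",
    "n_genes",
    "rank",
    "flag",
]


def _round_half_up(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the nearest whole number, halves away from zero.

    Gene scores are non-negative, so this is floor(x + 0.5); numpy's
    ``round`` (banker's rounding) is deliberately not used.
    """
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def gene_score(fold_change, a: float = 1.0):
    """Per-gene weight ``|log2(fold change)|`` raised to the power ``a``.

    Accepts a scalar or array of positive linear-scale fold changes.
    ``a = 0`` is the edge configuration where every changed gene counts
    1 and unchanged genes (fold change exactly 1) count 0; the usual
    ``0**0 = 1`` convention is overridden so null genes never contribute.
    """
    fc = np.asarray(fold_change, dtype=float)
    if a < 0:
        raise ValueError("power a must be >= 0")
    if np.any(fc <= 0) or not np.all(np.isfinite(fc)):
        raise ValueError("fold changes must be positive and finite")
    base = np.abs(np.log2(fc))
    if a == 0:
        out = (base != 0).astype(float)
    else:
        out = base**a
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ScoredPathway:
    """A pathway's member scores and their continuous/discrete summaries.

    ``n`` counts only members measured on the array; ``k`` is the sum of
    member scores, ``Q`` their maximum, and the ``_discrete`` variants
    apply per-gene rounding first.
    """

    set_id: str
    gene_scores: pd.Series
    n: int
    k: float
    Q: float
    k_discrete: int
    Q_discrete: int

    @property
    def testable(self) -> bool:
        return self.n > 0


def score_pathway(gene_set: GeneSet, stats: pd.DataFrame, a: float = 1.0) -> ScoredPathway:
    """Score a pathway against per-gene statistics.

    ``stats`` is indexed by gene ID with a ``fold_change`` column; set
    members absent from the index are excluded from ``n`` and all
    scores.  An empty intersection yields an untestable result with
    ``n = k = 0``.
    """
    members = sorted(gene_set.members & set(stats.index))
    if not members:
        empty = pd.Series(dtype=float)
        return ScoredPathway(gene_set.set_id, empty, 0, 0.0, 0.0, 0, 0)
    scores = pd.Series(
        gene_score(stats.loc[members, "fold_change"].to_numpy(), a), index=members
    )
    rounded = _round_half_up(scores.to_numpy())
    return ScoredPathway(
        set_id=gene_set.set_id,
        gene_scores=scores,
        n=len(members),
        k=float(scores.sum()),
        Q=float(scores.max()),
        k_discrete=int(rounded.sum()),
        Q_discrete=int(_round_half_up(scores.max())),
    )


@dataclass(frozen=True)
class ArrayContext:
    """Array-wide totals shared by every pathway's test.

    N: genes measured; m: significant genes at the chosen alpha;
    S: sum of all gene scores; S_discrete: sum of per-gene rounded scores.
    """

    N: int
    m: int
    S: float
    S_discrete: int

    def __post_init__(self) -> None:
        if not 0 <= self.m <= self.N:
            raise ValueError("need 0 <= m <= N")
        if self.S < 0:
            raise ValueError("S must be non-negative")


def array_context(stats: pd.DataFrame, a: float = 1.0, alpha: float = 0.01) -> ArrayContext:
    scores = gene_score(stats["fold_change"].to_numpy(), a)
    return ArrayContext(
        N=len(stats),
        m=int((stats["p_value"].to_numpy() < alpha).sum()),
        S=float(np.sum(scores)),
        S_discrete=int(np.sum(_round_half_up(scores))),
    )


def hypergeom_tail(N: int, m: int, n: int, k: int) -> float:
    """Strict upper tail ``P(X > k)`` of Hypergeometric(N, m, n).

    ``X`` is the number of significant genes among ``n`` drawn without
    replacement from ``N`` genes of which ``m`` are significant.  Note
    the strict inequality: the observed count itself is excluded, so
    ``k = min(m, n)`` gives exactly 0.
    """
    if not (0 <= m <= N and 0 <= n <= N):
        raise ValueError("need 0 <= m <= N and 0 <= n <= N")
    if not 0 <= k <= min(m, n):
        raise ValueError("need 0 <= k <= min(m, n)")
    return float(sps.hypergeom.sf(k, N, m, n))


@dataclass(frozen=True)
class ContingencyTable:
    """A 2x2 table: rows in/not-in pathway, columns per the chosen test."""

    n11: float
    n12: float
    n21: float
    n22: float

    def __post_init__(self) -> None:
        if min(self.n11, self.n12, self.n21, self.n22) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def row_margins(self) -> tuple[float, float]:
        return (self.n11 + self.n12, self.n21 + self.n22)

    @property
    def col_margins(self) -> tuple[float, float]:
        return (self.n11 + self.n21, self.n12 + self.n22)

    @property
    def total(self) -> float:
        return self.n11 + self.n12 + self.n21 + self.n22

    @property
    def df(self) -> int:
        """Degrees of freedom (rows-1)(cols-1) = 1 for any 2x2 table."""
        return 1


def chi2_statistic(table: ContingencyTable) -> float:
    """Uncorrected chi-squared statistic of a 2x2 table.

    ``N (n11 n22 - n12 n21)^2 / (N1r N2r N1c N2c)``; undefined (raises)
    when any margin is zero.  No continuity correction.
    """
    n1r, n2r = table.row_margins
    n1c, n2c = table.col_margins
    denom = n1r * n2r * n1c * n2c
    if denom == 0:
        raise ValueError("chi-squared statistic undefined: zero margin")
    det = table.n11 * table.n22 - table.n12 * table.n21
    return float(table.total * det**2 / denom)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalize(rows: list[dict]) -> pd.DataFrame:
    """Attach FDR and deterministic ranks; return sorted by rank."""
    df = pd.DataFrame(rows, columns=[c for c in RESULT_COLUMNS if c != "rank" and c != "fdr"])
    df["fdr"] = bh_fdr(df["p_value"].to_numpy()) if len(df) else []
    df = df.sort_values(
        by=["p_value", "pathway_score", "set_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[RESULT_COLUMNS]


def enrich_hypergeometric(
    sets: GeneSetCollection, stats: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Classical ORA: strict hypergeometric tail on significant-member counts."""
    N = len(stats)
    significant = set(stats.index[stats["p_value"] < alpha])
    m = len(significant)
    measured = set(stats.index)
    rows = []
    for s in sets:
        members = s.members & measured
        n = len(members)
        k = len(members & significant)
        if n == 0:
            rows.append(_row(s, 1.0, 0, 0, "untestable"))
            continue
        p = hypergeom_tail(N, m, n, k)
        rows.append(_row(s, p, k, n, ""))
    return _finalize(rows)


def enrich_chi2(
    sets: GeneSetCollection, stats: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Contingency-table ORA: 1-df chi-squared on the 2x2 membership table."""
    N = len(stats)
    significant = set(stats.index[stats["p_value"] < alpha])
    m = len(significant)
    measured = set(stats.index)
    rows = []
    for s in sets:
        members = s.members & measured
        n = len(members)
        k = len(members & significant)
        table = ContingencyTable(n11=n, n12=k, n21=N - n, n22=m - k)
        try:
            stat = chi2_statistic(table)
        except ValueError:
            rows.append(_row(s, 1.0, k, n, "degenerate"))
            continue
        p = float(sps.chi2.sf(stat, table.df))
        rows.append(_row(s, p, k, n, ""))
    return _finalize(rows)


def enrich_weighted_hypergeometric(
    sets: GeneSetCollection,
    stats: pd.DataFrame,
    a: float = 1.0,
    scores: pd.Series | None = None,
) -> pd.DataFrame:
    """Weighted ORA via the pseudo-pathway hypergeometric construction.

    Per pathway: population ``N * Q``, significant copies ``S`` (capped
    at the population size), draws ``n * Q``, p-value ``P(X > k)`` with
    all quantities rounded to whole numbers.  A pathway whose largest
    member score rounds to 0 cannot form a pseudo pathway and is
    reported degenerate with p = 1.

    ``scores`` overrides the fold-change-derived gene scores (indexed
    like ``stats``); the 0/1 significance indicator recovers the
    classical test exactly.
    """
    stats, scores = _with_scores(stats, a, scores)
    N = len(stats)
    rounded = _round_half_up(scores.to_numpy())
    S_discrete = int(rounded.sum())
    rows = []
    for s in sets:
        members = sorted(s.members & set(stats.index))
        n = len(members)
        if n == 0:
            rows.append(_row(s, 1.0, 0, 0, "untestable"))
            continue
        member_scores = scores.loc[members].to_numpy()
        k_discrete = int(_round_half_up(member_scores).sum())
        Q_discrete = int(_round_half_up(member_scores.max()))
        if Q_discrete == 0:
            rows.append(_row(s, 1.0, k_discrete, n, "degenerate"))
            continue
        population = N * Q_discrete
        successes = min(S_discrete, population)
        flag = "successes_capped" if S_discrete > population else ""
        draws = n * Q_discrete
        p = float(sps.hypergeom.sf(k_discrete, population, successes, draws))
        rows.append(_row(s, p, k_discrete, n, flag))
    return _finalize(rows)


def enrich_weighted_chi2(
    sets: GeneSetCollection,
    stats: pd.DataFrame,
    a: float = 1.0,
    scores: pd.Series | None = None,
    exclusive_not_in_pathway: bool = True,
) -> pd.DataFrame:
    """Weighted ORA via the chi-squared table, no discretization needed.

    The significant-genes column holds the unrounded pathway score ``k``
    against the array-wide total ``S``: n11 = n, n12 = k, n21 = N - n,
    n22 = S - k (or S itself when ``exclusive_not_in_pathway`` is off,
    for sensitivity analysis).  Reported pathway_score is the unrounded
    ``k``.
    """
    stats, scores = _with_scores(stats, a, scores)
    N = len(stats)
    S = float(scores.sum())
    rows = []
    for s in sets:
        members = sorted(s.members & set(stats.index))
        n = len(members)
        if n == 0:
            rows.append(_row(s, 1.0, 0.0, 0, "untestable"))
            continue
        k = float(scores.loc[members].sum())
        if S == 0:
            rows.append(_row(s, 1.0, k, n, "degenerate"))
            continue
        n22 = S - k if exclusive_not_in_pathway else S
        table = ContingencyTable(n11=n, n12=k, n21=N - n, n22=n22)
        try:
            stat = chi2_statistic(table)
        except ValueError:
            rows.append(_row(s, 1.0, k, n, "degenerate"))
            continue
        p = float(sps.chi2.sf(stat, table.df))
        rows.append(_row(s, p, k, n, ""))
    return _finalize(rows)


def enrich(
    sets: GeneSetCollection,
    stats: pd.DataFrame,
    method: str,
    a: float = 1.0,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Dispatch to one of the four enrichment tests by name."""
    if method == "hypergeometric":
        return enrich_hypergeometric(sets, stats, alpha=alpha)
    if method == "chi2":
        return enrich_chi2(sets, stats, alpha=alpha)
    if method == "weighted_hypergeometric":
        return enrich_weighted_hypergeometric(sets, stats, a=a)
    if method == "weighted_chi2":
        return enrich_weighted_chi2(sets, stats, a=a)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def rank_and_report(
    results: pd.DataFrame, top_k: int = 10, p_cutoff: float | None = None
) -> pd.DataFrame:
    """Select the top pathways from a result table.

    Re-applies the deterministic ordering (p ascending, larger score
    first on ties, then set_id), optionally filters at ``p_cutoff``,
    and returns at most ``top_k`` rows with ranks 1..len.
    """
    if results.empty:
        raise ValueError("no results to rank")
    df = results.sort_values(
        by=["p_value", "pathway_score", "set_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if p_cutoff is not None:
        df = df[df["p_value"] < p_cutoff]
    return df.head(top_k).reset_index(drop=True)


def _with_scores(
    stats: pd.DataFrame, a: float, scores: pd.Series | None
) -> tuple[pd.DataFrame, pd.Series]:
    if scores is None:
        scores = pd.Series(
            gene_score(stats["fold_change"].to_numpy(), a), index=stats.index
        )
    else:
        scores = scores.astype(float)
        if not scores.index.equals(stats.index):
            raise ValueError("scores must be indexed like stats")
        if (scores < 0).any():
            raise ValueError("gene scores must be non-negative")
    return stats, scores


def _row(gene_set: GeneSet, p: float, score, n: int, flag: str) -> dict:
    return {
        "set_id": gene_set.set_id,
        "name": gene_set.name,
        "p_value": p,
        "pathway_score": score,
        "n_genes": n,
        "flag": flag,
    }
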
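"""Single-sample gene-set scoring, tertile stratification, and ORA.

The cyclic-gene signature is scored per cohort sample by single-sample
gene-set enrichment (ssGSEA): genes are ranked by decreasing expression
and the score is the sum over ranks of the difference between the
weighted cumulative in-set mass and the uniform cumulative out-of-set
mass.  Because the score is rank-based it is invariant to any strictly
increasing transform of the expression vector.  Samples are stratified
into a high group (top tertile of scores) versus low.  Over-representation
of a query gene list in GMT collections is tested by the hypergeometric
upper tail with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cyclic_detect import bh_adjust
from .exceptions import InputError

__all__ = [
    "GeneSet",
    "ssgsea_score",
    "score_samples",
    "tertile_stratify",
    "ora_enrichment",
]


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (GMT line)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise InputError(f"gene set {self.name!r} contains duplicate ids")

    def __len__(self) -> int:
        return len(self.genes)


def ssgsea_score(values: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """ssGSEA running-sum score of one sample.

    Genes are ranked by decreasing value (ties broken by the stable order
    of the input vector, i.e. gene-id order as supplied).  With N genes
    and the gene at descending position ``i`` (1-based) carrying rank
    weight ``(N + 1 - i) ** alpha``, the score is::

        sum_i [ P_in(i) - P_out(i) ]

    where ``P_in`` is the cumulative rank-weight mass of set genes
    (normalised to 1 over the set) and ``P_out`` the cumulative uniform
    mass of non-set genes.  This is the sum-of-deviations (ssGSEA)
    convention, not the max-deviation (GSEA) convention.
    """
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else tuple(gene_set)
    in_set = values.index.isin(genes)
    m = int(in_set.sum())
    n = len(values)
    if m == 0 or m == n:
        raise InputError("gene set must cover at least one and not all ranked genes")

    # stable mergesort on negated values preserves input order among ties
    order = np.argsort(-values.to_numpy(float), kind="stable")
    mask = in_set[order]
    weights = (np.arange(n, 0, -1, dtype=float)) ** alpha  # N, N-1, ..., 1
    w_in = np.where(mask, weights, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~mask) / (n - m)
    return float(np.sum(p_in - p_out))


def score_samples(expression: pd.DataFrame, gene_set, alpha: float = 0.25) -> pd.Series:
    """ssGSEA score for every column (sample) of a genes x samples frame."""
    scores = {s: ssgsea_score(expression[s], gene_set, alpha=alpha) for s in expression.columns}
    return pd.Series(scores, name="score")


def tertile_stratify(scores: pd.Series) -> pd.Series:
    """Label the top tertile of scores ``high`` and the rest ``low``.

    Samples are sorted by decreasing score; the top ``ceil(n/3)`` are
    high.  Ties at the boundary are resolved by the stable input order of
    the sample ids and reported with a warning.
    """
    n = len(scores)
    if n < 3:
        raise InputError("tertile stratification needs at least 3 samples")
    k = int(np.ceil(n / 3))
    order = np.argsort(-scores.to_numpy(float), kind="stable")
    vals = scores.to_numpy(float)
    if k < n and vals[order[k - 1]] == vals[order[k]]:
        warnings.warn(
            "tied scores at the tertile boundary; resolved by stable sample-id order"
        )
    labels = np.full(n, "low", dtype=object)
    labels[order[:k]] = "high"
    return pd.Series(labels, index=scores.index, name="group")


def ora_enrichment(
    query: list[str],
    collection: list[GeneSet],
    universe: list[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in gene sets.

    ``p = P(X >= overlap)`` drawing ``len(query)`` genes from a universe
    of size M containing the set's K genes; BH-adjusted q across sets.
    Sets are intersected with the universe first.
    """
    uni = list(dict.fromkeys(universe))
    if not uni:
        raise InputError("universe must be non-empty")
    uni_set = set(uni)
    q_genes = set(query)
    stray = q_genes - uni_set
    if stray:
        raise InputError(f"query genes outside the universe: {sorted(stray)[:5]} ...")

    m_total = len(uni)
    n_query = len(q_genes)
    rows = []
    for gs in collection:
        members = uni_set & set(gs.genes)
        k = len(members)
        overlap = len(q_genes & members)
        if k == m_total:
            warnings.warn(f"set {gs.name!r} covers the whole universe; p degenerate at 1")
        p = float(stats.hypergeom.sf(overlap - 1, m_total, k, n_query)) if k else 1.0
        expected = n_query * k / m_total
        fold = overlap / expected if expected > 0 else np.nan
        rows.append((gs.name, k, overlap, fold, p))
    out = pd.DataFrame(rows, columns=["set", "n_set", "overlap", "fold", "p"]).set_index("set")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
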
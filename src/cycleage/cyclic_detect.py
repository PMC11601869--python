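"""Detection of cyclical (zigzag) temporal patterns in a 4-timepoint design.

The biological question: over the ages 3, 11, 14 and 19 months, does a
feature's level alternate (down-up-down or up-down-up across the three
adjacent transitions), so that the 11- and 19-month states resemble each
other and the 3- and 14-month states resemble each other?  This module
calls such "cyclic" genes from replicated log2 expression, calls cyclic
proteins from presence/absence proteomics with missing values, and checks
the phase pairing by hierarchical clustering of per-timepoint profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError, ParameterError

__all__ = [
    "TimecourseMatrix",
    "TransitionStats",
    "CyclicCallSet",
    "ProteomeTable",
    "ClusterResult",
    "transition_stats",
    "bh_adjust",
    "call_cyclic_genes",
    "call_cyclic_proteins",
    "differential_proteins",
    "cluster_timepoints",
]

ORIENTATIONS = ("UDU", "DUD")
_SIGN_PATTERN = {"UDU": (1, -1, 1), "DUD": (-1, 1, -1)}


@dataclass
class TimecourseMatrix:
    """Replicated log2 expression over an ordered multi-age design.

    ``values`` is a genes x samples frame whose columns form a MultiIndex
    ``(timepoint_months, replicate)``; columns are sorted by age on
    construction so timepoints are strictly increasing.
    """

    values: pd.DataFrame
    genotype: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex):
            raise InputError("TimecourseMatrix expects (timepoint, replicate) columns")
        self.values = self.values.sort_index(axis=1)

    @property
    def timepoints(self) -> list[int]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def replicates(self, timepoint: int) -> pd.DataFrame:
        return self.values.xs(timepoint, axis=1, level=0)

    def replicate_means(self) -> pd.DataFrame:
        """Genes x timepoints frame of per-timepoint replicate means."""
        return self.values.T.groupby(level=0).mean().T

    def validate_for_cyclic(self) -> None:
        tps = self.timepoints
        if len(tps) != 4:
            raise InputError(f"cyclic calling needs exactly 4 timepoints, got {len(tps)}")
        for tp in tps:
            if self.replicates(tp).shape[1] < 2:
                raise InputError(f"timepoint {tp} has <2 replicates")


@dataclass
class TransitionStats:
    """Per-gene statistics for each adjacent timepoint transition.

    Each attribute is a genes x transitions frame; transition columns are
    labelled ``"<a>m-<b>m"``.  log2FC is mean(t_{i+1}) - mean(t_i); p is a
    two-sided unpaired t (Welch by default); q is BH-adjusted across genes
    within each transition.
    """

    lfc: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    timepoints: tuple[int, ...]
    genotype: str = ""

    @property
    def transitions(self) -> list[str]:
        return list(self.lfc.columns)


@dataclass
class CyclicCallSet:
    """Genes passing the zigzag criteria, with orientation and statistics.

    ``calls`` has one row per called gene: orientation plus the three
    transition log2FCs and q-values that justified the call.
    """

    calls: pd.DataFrame
    tau: float
    q_max: float
    orientations: tuple[str, ...]

    @property
    def genes(self) -> list[str]:
        return list(self.calls.index)

    def __len__(self) -> int:
        return len(self.calls)


def _welch_rows(b: np.ndarray, a: np.ndarray, equal_var: bool) -> np.ndarray:
    """Row-wise two-sided unpaired t p-values of b vs a, with the
    zero-variance convention: equal means -> p=1, unequal -> p=0."""
    import warnings

    with warnings.catch_warnings():
        # noise-free groups trigger scipy's precision-loss warning; the
        # degenerate cases are handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    diff = b.mean(axis=1) - a.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p[degenerate & (diff == 0)] = 1.0
    p[degenerate & (diff != 0)] = 0.0
    return p


def transition_stats(tc: TimecourseMatrix, equal_var: bool = False) -> TransitionStats:
    """log2FC, p and BH q for every adjacent timepoint transition.

    Welch (unequal-variance) t by default; set ``equal_var=True`` for the
    pooled-variance Student t.
    """
    tps = tc.timepoints
    if len(tps) < 2:
        raise InputError("need at least 2 timepoints")
    for tp in tps:
        if tc.replicates(tp).shape[1] < 2:
            raise InputError(f"timepoint {tp} has <2 replicates")
    if not np.isfinite(tc.values.to_numpy()).all():
        raise InputError("non-finite values in expression matrix")

    lfc, p, q, labels = {}, {}, {}, []
    for t0, t1 in itertools.pairwise(tps):
        lab = f"{t0}m-{t1}m"
        labels.append(lab)
        a = tc.replicates(t0).to_numpy(float)
        b = tc.replicates(t1).to_numpy(float)
        lfc[lab] = b.mean(axis=1) - a.mean(axis=1)
        p[lab] = _welch_rows(b, a, equal_var)
        q[lab] = bh_adjust(p[lab])

    idx = tc.genes
    return TransitionStats(
        lfc=pd.DataFrame(lfc, index=idx, columns=labels),
        p=pd.DataFrame(p, index=idx, columns=labels),
        q=pd.DataFrame(q, index=idx, columns=labels),
        timepoints=tuple(tps),
        genotype=tc.genotype,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; NaN entries (untested features) propagate
    and are excluded from the number of tests m.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise InputError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def call_cyclic_genes(
    ts: TransitionStats,
    tau: float = 1.0,
    q_max: float = 0.05,
    orientations: tuple[str, ...] = ORIENTATIONS,
) -> CyclicCallSet:
    """Call genes whose three transition log2FCs alternate in sign.

    A gene is called iff its transition signs exactly match a requested
    orientation (UDU = +,-,+ ; DUD = -,+,-), every ``|log2FC| >= tau`` and
    every ``q <= q_max``.  Raising tau or lowering q_max can only remove
    calls.
    """
    if tau < 0:
        raise ParameterError("tau must be >= 0")
    if not (0 < q_max <= 1):
        raise ParameterError("q_max must lie in (0, 1]")
    unknown = set(orientations) - set(ORIENTATIONS)
    if unknown:
        raise ParameterError(f"unknown orientations: {sorted(unknown)}")
    if ts.lfc.shape[1] != 3:
        raise InputError("cyclic calling needs exactly 3 transitions (4 timepoints)")

    lfc = ts.lfc.to_numpy()
    q = ts.q.to_numpy()
    signs = np.sign(lfc)
    passes = (np.abs(lfc) >= tau).all(axis=1) & (q <= q_max).all(axis=1)

    orientation = np.full(len(ts.lfc), "", dtype=object)
    for name in orientations:
        match = (signs == np.array(_SIGN_PATTERN[name])).all(axis=1)
        orientation[match & passes] = name

    called = orientation != ""
    calls = pd.DataFrame(index=ts.lfc.index[called])
    calls["orientation"] = orientation[called]
    for j, lab in enumerate(ts.transitions):
        calls[f"lfc_{lab}"] = lfc[called, j]
    for j, lab in enumerate(ts.transitions):
        calls[f"q_{lab}"] = q[called, j]
    return CyclicCallSet(calls=calls, tau=tau, q_max=q_max, orientations=tuple(orientations))


@dataclass
class ProteomeTable:
    """Protein intensities with missing values over genotypes x timepoints.

    ``values`` is proteins x samples with MultiIndex columns
    ``(genotype, timepoint_months, replicate)``; NaN marks a missing
    (undetected) measurement.  ``floor`` is the detection floor on the
    intensity scale; ``min_detect`` is the minimum number of non-missing
    above-floor replicates for a protein to count as detected at a
    timepoint (default: replicate majority, ceil(n_rep/2)).
    """

    values: pd.DataFrame
    floor: float = 0.0
    min_detect: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex) or self.values.columns.nlevels != 3:
            raise InputError("ProteomeTable expects (genotype, timepoint, replicate) columns")
        if self.floor < 0:
            raise ParameterError("detection floor must be >= 0")
        self.values = self.values.sort_index(axis=1)
        n_rep = max(
            self.values[gt].xs(tp, axis=1, level=0).shape[1]
            for gt in self.genotypes
            for tp in self.timepoints(gt)
        )
        if self.min_detect is None:
            self.min_detect = int(np.ceil(n_rep / 2))
        if self.min_detect > n_rep:
            raise ParameterError("min_detect exceeds replicate count")

    @property
    def genotypes(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def timepoints(self, genotype: str) -> list[int]:
        return list(dict.fromkeys(self.values[genotype].columns.get_level_values(0)))

    def detected(self, genotype: str) -> pd.DataFrame:
        """Proteins x timepoints boolean detection matrix for one genotype."""
        if genotype not in self.genotypes:
            raise InputError(f"genotype {genotype!r} not in table")
        block = self.values[genotype]
        above = block.notna() & (block > self.floor)
        return above.T.groupby(level=0).sum().T >= self.min_detect


def call_cyclic_proteins(pt: ProteomeTable, genotype: str) -> list[str]:
    """Proteins detected only at the 2nd and 4th timepoints of one genotype.

    The call mirrors the ECM criterion: detected at 11 and 19 months in the
    designated genotype, absent at 3 and 14 months there, and absent at
    every timepoint of every other genotype.
    """
    if genotype not in pt.genotypes:
        raise InputError(f"genotype {genotype!r} not in table")
    tps = pt.timepoints(genotype)
    if len(tps) != 4:
        raise InputError("cyclic protein calling needs 4 timepoints")
    det = pt.detected(genotype)
    want = det[tps[1]] & det[tps[3]] & ~det[tps[0]] & ~det[tps[2]]
    for other in pt.genotypes:
        if other == genotype:
            continue
        want &= ~pt.detected(other).any(axis=1)
    return list(pt.values.index[want])


def differential_proteins(
    pt: ProteomeTable,
    group_a: list[tuple[str, int]],
    group_b: list[tuple[str, int]],
    equal_var: bool = False,
    q_sig: float = 0.05,
) -> pd.DataFrame:
    """Unpaired t on log2 intensities between two sample groups.

    ``group_a`` / ``group_b`` are lists of (genotype, timepoint) blocks
    whose replicates are pooled.  Proteins with fewer than 2 non-missing
    values on either side are reported untested (NaN statistics).  BH is
    applied across tested proteins; ``significant`` flags q < q_sig.
    """
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")

    def block(cols: list[tuple[str, int]]) -> np.ndarray:
        parts = []
        for gt, tp in cols:
            if gt not in pt.genotypes or tp not in pt.timepoints(gt):
                raise InputError(f"group member ({gt!r}, {tp}) not in table")
            parts.append(pt.values[gt].xs(tp, axis=1, level=0).to_numpy(float))
        return np.hstack(parts)

    a = np.log2(np.maximum(block(group_a), np.finfo(float).tiny))
    b = np.log2(np.maximum(block(group_b), np.finfo(float).tiny))
    a[np.isnan(block(group_a))] = np.nan
    b[np.isnan(block(group_b))] = np.nan

    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    tested = (n_a >= 2) & (n_b >= 2)

    lfc = np.full(len(a), np.nan)
    p = np.full(len(a), np.nan)
    rows = np.where(tested)[0]
    for i in rows:
        ai = a[i][~np.isnan(a[i])]
        bi = b[i][~np.isnan(b[i])]
        lfc[i] = bi.mean() - ai.mean()
        if ai.var() == 0 and bi.var() == 0:
            p[i] = 1.0 if bi.mean() == ai.mean() else 0.0
        else:
            p[i] = stats.ttest_ind(bi, ai, equal_var=equal_var).pvalue
    q = bh_adjust(p)

    out = pd.DataFrame(
        {
            "n_a": n_a,
            "n_b": n_b,
            "log2fc": lfc,
            "p": p,
            "q": q,
            "tested": tested,
            "significant": (q < q_sig) & tested,
        },
        index=pt.values.index,
    )
    return out


@dataclass
class ClusterResult:
    """Average-linkage clustering of per-timepoint profiles."""

    labels: tuple[str, ...]
    linkage: np.ndarray
    partition: tuple[frozenset, frozenset]
    newick: str = field(repr=False, default="")

    def partition_sets(self) -> set[frozenset]:
        return {self.partition[0], self.partition[1]}


def _to_newick(tree, labels) -> str:
    if tree.is_leaf():
        return labels[tree.id]
    left = _to_newick(tree.left, labels)
    right = _to_newick(tree.right, labels)
    dl = max(tree.dist - tree.left.dist, 0.0)
    dr = max(tree.dist - tree.right.dist, 0.0)
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def cluster_timepoints(profiles: pd.DataFrame) -> ClusterResult:
    """Hierarchically cluster per-timepoint mean profiles and cut at 2.

    ``profiles`` is genes x timepoints (column labels are the timepoint
    names).  Distance is correlation distance (1 - Pearson across genes),
    linkage is average.  SciPy's deterministic lowest-index-first merge
    order breaks ties.  Returns the unordered 2-group partition of the
    timepoint labels plus the dendrogram (linkage matrix and Newick).
    """
    if profiles.shape[1] < 2:
        raise InputError("need at least 2 profiles to cluster")
    sd = profiles.std(axis=0, ddof=0)
    flat = sd[sd == 0]
    if len(flat):
        raise InputError(f"constant profile(s) {list(flat.index)}: correlation undefined")

    d = pdist(profiles.T.to_numpy(float), metric="correlation")
    z = hierarchy.linkage(d, method="average")
    cut = hierarchy.fcluster(z, t=2, criterion="maxclust")
    labels = tuple(str(c) for c in profiles.columns)
    part = (
        frozenset(l for l, c in zip(labels, cut) if c == 1),
        frozenset(l for l, c in zip(labels, cut) if c == 2),
    )
    newick = _to_newick(hierarchy.to_tree(z), labels) + ";"
    return ClusterResult(labels=labels, linkage=z, partition=part, newick=newick)
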
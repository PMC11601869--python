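"""Marker-panel cell-type assignment and composition ratios.

Replaces interactive cluster browsing with deterministic score-based
gating: each cell gets a log2 feature-sum score per lineage panel
(luminal hormone-sensitive HS, luminal alveolar AV, myoepithelial ME),
is labelled by the best panel above threshold, and HS/AV co-expression
within a relative margin yields the mixed HS-AV label.  Proliferation
and regulon panels are gated by the half-of-maximum log2 feature-sum
rule; their conjunction defines the PPBC-like subpopulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ComputationError, ConfigError, InputError

__all__ = [
    "MarkerPanel",
    "default_panel",
    "annotate_cells",
    "feature_sum_gate",
    "composition_ratios",
    "LUMINAL_LABELS",
]

LUMINAL_LABELS = ("HS", "AV", "HS-AV")

# "Bud1" is a nonstandard symbol but is kept verbatim from the source
# marker list; absent panel genes are warned about and skipped at use.
_AV_MARKERS = ("Mfge8", "Trf", "Csn3", "Wfdc18", "Ltf")
_HS_MARKERS = ("Prlr", "Pgr", "Esr1", "Cited1", "Prom1")
_ME_MARKERS = ("Krt17", "Krt14", "Krt5")
_PROLIFERATING = ("Cenpe", "Ccna2", "Ccnb2", "Mcm6", "Ccnf", "Bud1")
_REGULON = (
    "Bclaf1", "Cux1", "E2f1", "E2f4", "Esr1", "Foxm1", "Gtf2b",
    "Max", "Myc", "Nfya", "Nr4a1", "Nrf1", "Smarca4", "Taf1",
)


@dataclass
class MarkerPanel:
    """Named marker-gene lists for lineage and state gating."""

    hs: list[str] = field(default_factory=lambda: list(_HS_MARKERS))
    av: list[str] = field(default_factory=lambda: list(_AV_MARKERS))
    me: list[str] = field(default_factory=lambda: list(_ME_MARKERS))
    proliferating: list[str] = field(default_factory=lambda: list(_PROLIFERATING))
    regulon: list[str] = field(default_factory=lambda: list(_REGULON))

    def __post_init__(self) -> None:
        for name in ("hs", "av", "me", "proliferating", "regulon"):
            genes = getattr(self, name)
            if not genes:
                raise ConfigError(f"marker list {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ConfigError(f"marker list {name!r} contains duplicate gene ids")

    def lineages(self) -> dict[str, list[str]]:
        return {"HS": self.hs, "AV": self.av, "ME": self.me}


def default_panel() -> MarkerPanel:
    return MarkerPanel()


def _as_counts(counts) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Accept an AnnData or a cells x genes DataFrame; return dense array."""
    try:
        import anndata as ad

        if isinstance(counts, ad.AnnData):
            x = counts.X
            x = x.toarray() if hasattr(x, "toarray") else np.asarray(x)
            return np.asarray(x, dtype=float), counts.obs_names, counts.var_names
    except ImportError:  # pragma: no cover - anndata is a hard dependency
        pass
    if isinstance(counts, pd.DataFrame):
        return counts.to_numpy(dtype=float), counts.index, counts.columns
    raise InputError("counts must be an AnnData or a cells x genes DataFrame")


def _panel_score(x: np.ndarray, var: pd.Index, genes: list[str], name: str) -> np.ndarray:
    present = [g for g in genes if g in var]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"panel {name!r}: genes absent from matrix, skipped: {missing}")
    if not present:
        return None
    cols = var.get_indexer(present)
    return np.log2(1.0 + x[:, cols].sum(axis=1))


def feature_sum_gate(counts, feature_list: list[str]) -> pd.Series:
    """Half-of-maximum gate on the log2 feature sum.

    Per cell, ``s = log2(1 + sum of listed-gene counts)``; a cell is
    gated in when ``s >= max(s) / 2``.  If every feature sum is zero the
    gate is all-False (with a warning).
    """
    if not feature_list:
        raise InputError("feature list must be non-empty")
    x, obs, var = _as_counts(counts)
    s = _panel_score(x, var, list(feature_list), "feature_sum_gate")
    if s is None:
        raise InputError("no feature-list gene present in the matrix")
    mx = s.max() if len(s) else 0.0
    if mx == 0.0:
        warnings.warn("all feature sums are zero; gate is all-False")
        return pd.Series(False, index=obs)
    return pd.Series(s >= mx / 2.0, index=obs)


def annotate_cells(
    counts,
    panel: MarkerPanel | None = None,
    min_score: float | dict[str, float] | None = None,
    margin: float = 0.25,
) -> pd.DataFrame:
    """Assign each cell a lineage label plus boolean state gates.

    Per-cell panel score = ``log2(1 + sum of panel counts)``.  A cell is
    labelled by the highest-scoring lineage among those reaching
    ``min_score`` (default: half of that panel's maximum score across
    cells, reusing the half-max convention); when the HS and AV scores
    both qualify and sit within a relative ``margin`` of each other the
    mixed HS-AV label is assigned; cells reaching no panel are
    ``unassigned``.  The proliferating and regulon gates use
    :func:`feature_sum_gate`; ``ppbc_like`` is their conjunction.
    """
    panel = panel or default_panel()
    if not (0 <= margin <= 1):
        raise InputError("margin must lie in [0, 1]")
    x, obs, var = _as_counts(counts)
    if (x < 0).any():
        raise InputError("counts must be non-negative")

    scores = {}
    for name, genes in panel.lineages().items():
        s = _panel_score(x, var, genes, name)
        if s is None:
            raise InputError(f"no gene of panel {name!r} present in the matrix")
        scores[name] = s

    if min_score is None:
        thr = {name: s.max() / 2.0 for name, s in scores.items()}
    elif isinstance(min_score, dict):
        thr = {name: float(min_score[name]) for name in scores}
    else:
        thr = {name: float(min_score) for name in scores}

    hs, av, me = scores["HS"], scores["AV"], scores["ME"]
    ok = {name: (scores[name] >= thr[name]) & (scores[name] > 0) for name in scores}

    stacked = np.stack([hs, av, me])
    eligible = np.stack([ok["HS"], ok["AV"], ok["ME"]])
    masked = np.where(eligible, stacked, -np.inf)
    best = np.argmax(masked, axis=0)  # ties: first wins (HS > AV > ME order)
    labels = np.where(eligible.any(axis=0), np.array(["HS", "AV", "ME"])[best], "unassigned")

    both = ok["HS"] & ok["AV"]
    close = np.abs(hs - av) <= margin * np.maximum(hs, av)
    labels = np.where(both & close, "HS-AV", labels)

    def _state_gate(genes: list[str], name: str) -> np.ndarray:
        s = _panel_score(x, var, genes, name)
        if s is None:
            warnings.warn(f"no gene of panel {name!r} present; gate is all-False")
            return np.zeros(len(obs), dtype=bool)
        mx = s.max() if len(s) else 0.0
        if mx == 0.0:
            warnings.warn(f"panel {name!r}: all feature sums zero; gate is all-False")
            return np.zeros(len(obs), dtype=bool)
        return s >= mx / 2.0

    prolif = _state_gate(panel.proliferating, "proliferating")
    regulon = _state_gate(panel.regulon, "regulon")

    return pd.DataFrame(
        {
            "label": labels,
            "score_HS": hs,
            "score_AV": av,
            "score_ME": me,
            "proliferating": prolif,
            "regulon": regulon,
            "ppbc_like": prolif & regulon,
        },
        index=obs,
    )


def composition_ratios(
    annotation: pd.DataFrame | pd.Series,
    sample: pd.Series | str | None = None,
) -> pd.DataFrame:
    """Per-sample cell-type ratios over total luminal epithelial cells.

    LE = #HS + #AV + #HS-AV is the common denominator; the returned frame
    has columns ``HS/LE``, ``AV/LE``, ``HS-AV/LE``, ``ME/LE`` (the three
    luminal ratios sum to 1).  ``sample`` may be a column name of the
    annotation frame, an aligned Series, or None for a single pooled
    sample.
    """
    labels = annotation["label"] if isinstance(annotation, pd.DataFrame) else annotation
    if isinstance(sample, str):
        groups = annotation[sample]
    elif sample is None:
        groups = pd.Series("all", index=labels.index)
    else:
        groups = sample

    out = {}
    for g, lab in labels.groupby(groups):
        counts = lab.value_counts()
        le = int(sum(counts.get(t, 0) for t in LUMINAL_LABELS))
        if le == 0:
            raise ComputationError(f"sample {g!r} has no luminal epithelial cells (LE = 0)")
        out[g] = {
            "HS/LE": counts.get("HS", 0) / le,
            "AV/LE": counts.get("AV", 0) / le,
            "HS-AV/LE": counts.get("HS-AV", 0) / le,
            "ME/LE": counts.get("ME", 0) / le,
        }
    return pd.DataFrame(out).T.rename_axis("sample")
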
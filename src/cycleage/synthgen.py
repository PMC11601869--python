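"""Synthetic data generators with planted cyclical structure.

Every generator emulates one of the study's data modalities so that each
downstream stage has a no-download parameter-recovery test:

* :func:`gen_timecourse` -- replicated log2 expression over the 4-age
  design (3, 11, 14, 19 months; 5 replicates per timepoint per genotype)
  with planted zigzag (UDU/DUD), monotonic and null genes.
* :func:`gen_proteome` -- two-genotype ECM-style intensity tables with
  missing values and planted proteins present only at 11 and 19 months of
  one genotype.
* :func:`gen_single_cell` -- marker-structured counts for the four
  mammary epithelial populations (HS, AV, HS-AV, ME) with a planted
  per-timepoint composition cycle.
* :func:`gen_cohort` -- a breast-cancer-cohort-like table with
  mixture-of-normals ages at diagnosis, group-dependent exponential
  survival, and a signature-shifted expression matrix.

Expression is simulated on the log2 scale (transitions are defined as
log2 fold changes); the linear scale is ``2**x``.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

from .cell_annot import MarkerPanel, default_panel
from .cyclic_detect import ProteomeTable, TimecourseMatrix
from .exceptions import ConfigError

__all__ = [
    "AGES_MONTHS",
    "TimecourseConfig",
    "ProteomeConfig",
    "SingleCellConfig",
    "CohortConfig",
    "gen_timecourse",
    "gen_proteome",
    "gen_single_cell",
    "gen_cohort",
]

#: the study's age design, in months
AGES_MONTHS = (3, 11, 14, 19)

# planted mean log2 offsets per transition class (amplitude = 1 unit)
_PROFILE = {
    "udu": np.array([0.0, 1.0, 0.0, 1.0]),  # transitions +, -, +
    "dud": np.array([0.0, -1.0, 0.0, -1.0]),  # transitions -, +, -
    "monotonic": np.array([0.0, 1.0, 2.0, 3.0]),
    "null": np.zeros(4),
}


@dataclass
class TimecourseConfig:
    """Design of a replicated 4-timepoint expression simulation."""

    n_genes: int = 2000
    timepoints: tuple[int, ...] = AGES_MONTHS
    n_replicates: int = 5
    n_cyclic_udu: int = 50
    n_cyclic_dud: int = 50
    n_monotonic: int = 0
    amplitude: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 6.0
    baseline_sd: float = 1.0
    genotype_label: str = "nzb"
    seed: int = 0

    def validate(self) -> None:
        planted = self.n_cyclic_udu + self.n_cyclic_dud + self.n_monotonic
        if min(self.n_cyclic_udu, self.n_cyclic_dud, self.n_monotonic) < 0:
            raise ConfigError("planted counts must be >= 0")
        if planted > self.n_genes:
            raise ConfigError("n_cyclic_udu + n_cyclic_dud + n_monotonic exceeds n_genes")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if len(self.timepoints) != 4:
            raise ConfigError("cyclic designs require exactly 4 timepoints")
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ConfigError("timepoints must be strictly increasing")
        if self.amplitude < 0:
            raise ConfigError("amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def gen_timecourse(cfg: TimecourseConfig) -> tuple[TimecourseMatrix, pd.DataFrame]:
    """Simulate replicated log2 expression with planted transition classes.

    Gene order is: UDU genes, DUD genes, monotonic genes (random
    direction), then null genes.  Planted classes are realised as mean
    profiles with alternating +/- ``amplitude`` transitions; replicate
    noise is i.i.d. Gaussian(0, ``noise_sd``).

    Returns the matrix and a planted-truth table (``gene``, ``pattern``,
    ``direction``).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, n_rep = cfg.n_genes, cfg.n_replicates

    patterns = np.array(
        ["udu"] * cfg.n_cyclic_udu
        + ["dud"] * cfg.n_cyclic_dud
        + ["monotonic"] * cfg.n_monotonic
        + ["null"] * (n - cfg.n_cyclic_udu - cfg.n_cyclic_dud - cfg.n_monotonic),
        dtype=object,
    )
    direction = np.ones(n)
    mono = patterns == "monotonic"
    direction[mono] = rng.choice([-1.0, 1.0], size=int(mono.sum()))

    offsets = np.stack([_PROFILE[p] for p in patterns]) * cfg.amplitude
    offsets *= direction[:, None]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
    means = baseline[:, None] + offsets  # genes x 4

    data = np.repeat(means[:, :, None], n_rep, axis=2)
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, size=(n, 4, n_rep))

    genes = pd.Index([f"gene{i + 1:05d}" for i in range(n)], name="gene")
    cols = pd.MultiIndex.from_product(
        [list(cfg.timepoints), range(1, n_rep + 1)], names=["timepoint", "replicate"]
    )
    values = pd.DataFrame(data.reshape(n, 4 * n_rep), index=genes, columns=cols)
    truth = pd.DataFrame({"gene": genes, "pattern": patterns, "direction": direction}).set_index(
        "gene"
    )
    return TimecourseMatrix(values=values, genotype=cfg.genotype_label), truth


@dataclass
class ProteomeConfig:
    """Two-genotype proteomics simulation with temporally restricted proteins.

    Planted "cyclic" proteins carry intensity only at the 2nd and 4th
    timepoints (11 and 19 months) of ``cyclic_genotype``; background
    proteins are present in every sample.  Missing-completely-at-random
    dropout is applied to present measurements at ``missing_rate``;
    intensity-dependent dropout (``dropout_slope`` > 0 makes weak
    intensities likelier to drop) is off by default.
    """

    n_background: int = 200
    n_cyclic: int = 16
    genotypes: tuple[str, str] = ("c57", "nzb")
    cyclic_genotype: str = "nzb"
    timepoints: tuple[int, ...] = AGES_MONTHS
    n_replicates: int = 5
    missing_rate: float = 0.0
    log2_mean: float = 20.0
    log2_sd: float = 1.0
    dropout_slope: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.missing_rate <= 1):
            raise ConfigError("missing_rate must lie in [0, 1]")
        if len(self.genotypes) != 2:
            raise ConfigError("genotypes must name exactly two genotypes")
        if self.cyclic_genotype not in self.genotypes:
            raise ConfigError("cyclic_genotype must be one of genotypes")
        if len(self.timepoints) != 4:
            raise ConfigError("timepoints must list exactly 4 ages")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if self.n_background < 0 or self.n_cyclic < 0:
            raise ConfigError("protein counts must be >= 0")


def gen_proteome(cfg: ProteomeConfig) -> tuple[ProteomeTable, pd.DataFrame]:
    """Simulate an intensity table with planted 11/19-month-only proteins."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_background + cfg.n_cyclic
    proteins = pd.Index(
        [f"bgprot{i + 1:04d}" for i in range(cfg.n_background)]
        + [f"cycprot{i + 1:02d}" for i in range(cfg.n_cyclic)],
        name="protein",
    )
    cols = pd.MultiIndex.from_product(
        [list(cfg.genotypes), list(cfg.timepoints), range(1, cfg.n_replicates + 1)],
        names=["genotype", "timepoint", "replicate"],
    )
    present = np.zeros((n, len(cols)), dtype=bool)
    present[: cfg.n_background] = True
    cyc_cols = np.array(
        [
            (gt == cfg.cyclic_genotype) and (tp in (cfg.timepoints[1], cfg.timepoints[3]))
            for gt, tp, _ in cols
        ]
    )
    present[cfg.n_background :, cyc_cols] = True

    log2_int = rng.normal(cfg.log2_mean, cfg.log2_sd, size=present.shape)
    values = np.where(present, np.exp2(log2_int), np.nan)

    if cfg.missing_rate > 0 or cfg.dropout_slope > 0:
        p_drop = np.full(present.shape, cfg.missing_rate)
        if cfg.dropout_slope > 0:
            # weaker intensities drop out more often, capped at 1
            p_drop = np.clip(
                p_drop + cfg.dropout_slope * (cfg.log2_mean - log2_int), 0.0, 1.0
            )
        values[present & (rng.random(present.shape) < p_drop)] = np.nan

    table = ProteomeTable(values=pd.DataFrame(values, index=proteins, columns=cols))
    truth = pd.DataFrame(
        {"protein": proteins, "cyclic": [False] * cfg.n_background + [True] * cfg.n_cyclic}
    ).set_index("protein")
    return table, truth


def _largest_remainder(fracs: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` cells matching ``fracs`` exactly."""
    raw = fracs * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


@dataclass
class SingleCellConfig:
    """Marker-structured single-cell count simulation.

    ``composition`` maps each timepoint to the fraction of cells of each
    type (HS, AV, HS-AV, ME; must sum to 1).  Cells of a type draw
    Poisson(``marker_rate``) counts on each gene of their panel (HS-AV
    cells on both the HS and AV panels) and Poisson(``background_rate``)
    counts on every gene.  Defaults plant the composition cycle the
    analysis looks for: a higher HS/LE share at 3 and 14 months than at
    11 and 19 months.
    """

    composition: dict[int, dict[str, float]] = field(
        default_factory=lambda: {
            3: {"HS": 0.40, "AV": 0.24, "HS-AV": 0.16, "ME": 0.20},
            11: {"HS": 0.315, "AV": 0.315, "HS-AV": 0.27, "ME": 0.10},
            14: {"HS": 0.40, "AV": 0.24, "HS-AV": 0.16, "ME": 0.20},
            19: {"HS": 0.315, "AV": 0.315, "HS-AV": 0.27, "ME": 0.10},
        }
    )
    n_cells_per_sample: int = 1000
    n_samples_per_timepoint: int = 3
    marker_rate: float = 5.0
    background_rate: float = 0.0
    n_extra_genes: int = 40
    panel: MarkerPanel | None = None
    seed: int = 0

    def validate(self) -> None:
        for tp, comp in self.composition.items():
            if set(comp) != {"HS", "AV", "HS-AV", "ME"}:
                raise ConfigError(f"composition at {tp} must cover HS, AV, HS-AV, ME")
            if abs(sum(comp.values()) - 1.0) > 1e-8:
                raise ConfigError(f"composition at timepoint {tp} does not sum to 1")
        if self.n_cells_per_sample < 1 or self.n_samples_per_timepoint < 1:
            raise ConfigError("cell and sample counts must be >= 1")
        if self.marker_rate < 0 or self.background_rate < 0:
            raise ConfigError("rates must be >= 0")


def gen_single_cell(cfg: SingleCellConfig) -> tuple[ad.AnnData, MarkerPanel]:
    """Simulate sparse counts with known cell types and composition.

    Returns an :class:`anndata.AnnData` (cells x genes) whose ``obs``
    carries ``sample``, ``timepoint`` and the planted ``true_label``,
    together with the marker panel used.  Per-sample type counts follow
    the planted composition exactly (largest-remainder apportionment), so
    with ``background_rate=0`` the annotation stage can recover the
    planted ratios exactly.
    """
    cfg.validate()
    panel = cfg.panel or default_panel()
    rng = np.random.default_rng(cfg.seed)

    genes = list(
        dict.fromkeys(
            panel.hs
            + panel.av
            + panel.me
            + panel.proliferating
            + panel.regulon
            + [f"filler{i + 1:03d}" for i in range(cfg.n_extra_genes)]
        )
    )
    gidx = {g: i for i, g in enumerate(genes)}
    panel_cols = {
        "HS": [gidx[g] for g in panel.hs],
        "AV": [gidx[g] for g in panel.av],
        "ME": [gidx[g] for g in panel.me],
    }
    type_cols = {
        "HS": panel_cols["HS"],
        "AV": panel_cols["AV"],
        "ME": panel_cols["ME"],
        "HS-AV": panel_cols["HS"] + panel_cols["AV"],
    }

    rows, obs_rows = [], []
    types = ("HS", "AV", "HS-AV", "ME")
    for tp in sorted(cfg.composition):
        fracs = np.array([cfg.composition[tp][t] for t in types])
        for s in range(1, cfg.n_samples_per_timepoint + 1):
            sample = f"{tp}m_s{s}"
            counts_per_type = _largest_remainder(fracs, cfg.n_cells_per_sample)
            for t, k in zip(types, counts_per_type):
                lam = np.full(len(genes), cfg.background_rate)
                lam[type_cols[t]] += cfg.marker_rate
                rows.append(rng.poisson(lam, size=(k, len(genes))))
                obs_rows.extend((sample, tp, t) for _ in range(k))

    x = sparse.csr_matrix(np.vstack(rows))
    obs = pd.DataFrame(obs_rows, columns=["sample", "timepoint", "true_label"])
    obs.index = pd.Index([f"cell{i + 1:06d}" for i in range(len(obs))], name="barcode")
    adata = ad.AnnData(X=x, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
    return adata, panel


@dataclass
class CohortConfig:
    """Cohort simulation: bimodal high-group ages, exponential survival.

    High-group ages at diagnosis are drawn from ``age_mixture`` (a list of
    ``(weight, mean_years, sd_years)`` normal components, weights summing
    to 1; the default plants the 45/65 bimodal pattern); low-group ages
    from a single normal.  Survival times are exponential with the
    group's hazard, censored by an independent exponential at
    ``censor_rate``; all rates are per year.  Signature genes are shifted
    up by ``signature_shift`` log2 units in high samples.
    """

    n_samples: int = 300
    age_mixture: tuple[tuple[float, float, float], ...] = ((0.5, 45.0, 3.0), (0.5, 65.0, 3.0))
    age_low_mean: float = 65.0
    age_low_sd: float = 8.0
    hazard_high: float = 0.10
    hazard_low: float = 0.05
    censor_rate: float = 0.04
    frac_high: float = 1.0 / 3.0
    signature_genes: tuple[str, ...] | None = None
    n_signature: int = 79
    n_background_genes: int = 921
    signature_shift: float = 2.0
    expr_mean: float = 8.0
    expr_sd: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 3:
            raise ConfigError("n_samples must be >= 3")
        if abs(sum(w for w, _, _ in self.age_mixture) - 1.0) > 1e-8:
            raise ConfigError("age_mixture weights must sum to 1")
        if self.hazard_high <= 0 or self.hazard_low <= 0:
            raise ConfigError("hazard rates must be > 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if not (0 <= self.frac_high <= 1):
            raise ConfigError("frac_high must lie in [0, 1]")
        if self.signature_genes is not None and len(self.signature_genes) == 0:
            raise ConfigError("signature_genes must not be empty")


def gen_cohort(cfg: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, tuple[str, ...]]:
    """Simulate a clinical cohort plus a signature-shifted expression matrix.

    Returns ``(cohort, expression, signature_genes)``: the cohort table
    (``sample_id``, ``age_years``, ``os_time``, ``os_event``, ``group``
    -- the planted truth), a genes x samples log2 expression frame, and
    the signature gene ids.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sig = (
        tuple(cfg.signature_genes)
        if cfg.signature_genes is not None
        else tuple(f"SIG{i + 1:03d}" for i in range(cfg.n_signature))
    )

    n_high = int(round(cfg.frac_high * n))
    high = np.zeros(n, dtype=bool)
    high[rng.permutation(n)[:n_high]] = True

    ages = np.empty(n)
    weights = np.array([w for w, _, _ in cfg.age_mixture])
    comps = rng.choice(len(cfg.age_mixture), size=n, p=weights)
    for j, (_, mu, sd) in enumerate(cfg.age_mixture):
        sel = high & (comps == j)
        ages[sel] = rng.normal(mu, sd, size=int(sel.sum()))
    ages[~high] = rng.normal(cfg.age_low_mean, cfg.age_low_sd, size=int((~high).sum()))
    ages = np.maximum(ages, 18.0)

    hazard = np.where(high, cfg.hazard_high, cfg.hazard_low)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = (
        rng.exponential(1.0 / cfg.censor_rate, size=n) if cfg.censor_rate > 0 else np.full(n, np.inf)
    )
    os_time = np.minimum(t_event, t_cens)
    os_event = (t_event <= t_cens).astype(int)

    samples = [f"S{i + 1:04d}" for i in range(n)]
    cohort = pd.DataFrame(
        {
            "sample_id": samples,
            "age_years": ages,
            "os_time": os_time,
            "os_event": os_event,
            "group": np.where(high, "high", "low"),
        }
    ).set_index("sample_id")

    genes = list(sig) + [f"bg{i + 1:04d}" for i in range(cfg.n_background_genes)]
    base = rng.normal(cfg.expr_mean, cfg.expr_sd, size=len(genes))
    expr = base[:, None] + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
    expr[: len(sig), high] += cfg.signature_shift
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="gene"), columns=samples)
    return cohort, expression, sig
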
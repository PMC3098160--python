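"""Objective matrices that pull the regulatory matrix during fitting.

An :class:`ObjectiveTerm` is an N x N evidence matrix ``O`` (entry ``O[i, j]``
= evidence that gene j regulates gene i) with a validity mask, a goal ``J``
and a weight ``theta``; the fit penalises the Euclidean distance between the
regulatory matrix ``w`` and ``O`` on the masked entries.

Four families of objectives are provided:

``DSp``
    Time-delayed Spearman rank correlation between gene pairs on the
    interpolated wild-type series.  For each ordered pair (i, j) the profile
    of gene i is shifted by every delay d in [0, max_delay] grid steps
    against gene j; the coefficient of largest magnitude and its delay are
    recorded, and pairs whose best delay falls below the minimum-delay
    threshold t_o are zeroed (instantaneous co-variation carries no
    directional information).

``Tr`` / ``Sr``
    Knockout expression ratios: expression of gene i in the mutant deleted
    for gene j over the wild type, taken at an early post-inactivation time
    t_p (Tr) or at the new steady state (Sr).

``Tc`` / ``Sc``
    Correlation between every pair of genes across the knockout conditions,
    at t_p (Tc) or steady state (Sc).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import rankdata

from .datasets import InterpolatedSeries, KnockoutPanel

__all__ = [
    "ObjectiveTerm",
    "DelayedCorrelationResult",
    "delayed_spearman_objective",
    "select_tp",
    "ratio_objective",
    "correlation_objective",
    "scale_objective",
]


@dataclass
class ObjectiveTerm:
    """An objective matrix with goal, weight and validity mask.

    ``J`` is the goal on the distance ``||w - O||`` (default 0: pull w all
    the way onto O); ``theta`` the goal-attainment weight (0 = hard goal).
    Entries where ``mask`` is False do not participate in the distance.
    """

    O: np.ndarray
    label: str = "custom"
    mask: np.ndarray | None = None
    J: float = 0.0
    theta: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.O = np.asarray(self.O, dtype=float)
        if self.O.ndim != 2 or self.O.shape[0] != self.O.shape[1]:
            raise ValueError("O must be a square matrix")
        if self.mask is None:
            self.mask = np.ones(self.O.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.O.shape:
            raise ValueError("mask shape must match O")
        if self.J < 0 or self.theta < 0:
            raise ValueError("goal J and weight theta must be non-negative")
        if not np.all(np.isfinite(self.O[self.mask])):
            raise ValueError("O has non-finite masked entries")

    @property
    def n_genes(self) -> int:
        return self.O.shape[0]


@dataclass
class DelayedCorrelationResult:
    """Max delayed Spearman coefficients and the delays attaining them."""

    d_src: np.ndarray  # N x N, in [-1, 1]
    dt: np.ndarray  # N x N best delay, grid steps
    t_o: int  # minimum-delay threshold applied to the derived objective


def _spearman_matrix(xi: np.ndarray, xj: np.ndarray) -> np.ndarray:
    """Spearman correlations between the rows of xi and the rows of xj.

    Returns an N x N matrix; rows with zero variance get correlation 0.
    """
    ri = rankdata(xi, axis=1).astype(float)
    rj = rankdata(xj, axis=1).astype(float)
    ri -= ri.mean(axis=1, keepdims=True)
    rj -= rj.mean(axis=1, keepdims=True)
    si = np.sqrt((ri**2).sum(axis=1))
    sj = np.sqrt((rj**2).sum(axis=1))
    num = ri @ rj.T
    denom = np.outer(si, sj)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(c, -1.0, 1.0)


def delayed_spearman_objective(
    series: InterpolatedSeries,
    max_delay: int = 20,
    t_o: int = 1,
    theta: float = 1.0,
) -> tuple[DelayedCorrelationResult, ObjectiveTerm]:
    """Delayed Spearman correlation matrix and the DSp objective.

    A positive delay d means the putative regulator j precedes the target i:
    gene i's profile shifted forward by d grid steps is correlated against
    gene j's unshifted profile on the overlapping window.  For each ordered
    pair the coefficient of largest magnitude wins (smallest delay on ties);
    pairs whose best delay is below ``t_o`` are zeroed in the objective, and
    the diagonal is zero by convention.
    """
    n_t = series.times.size
    if not 0 <= max_delay < n_t // 2:
        raise ValueError("max_delay must be below half the grid length")
    if t_o > max_delay:
        raise ValueError("t_o must not exceed max_delay")
    x = series.values
    n = series.n_genes
    best = np.zeros((n, n))
    best_dt = np.zeros((n, n), dtype=int)
    for d in range(max_delay + 1):
        # target rows (i) shifted forward by d against regulator rows (j)
        xi = x[:, d:]
        xj = x[:, : n_t - d]
        c = _spearman_matrix(xi, xj)
        better = np.abs(c) > np.abs(best) + 1e-12
        best = np.where(better, c, best)
        best_dt = np.where(better, d, best_dt)
    np.fill_diagonal(best, 0.0)
    np.fill_diagonal(best_dt, 0)
    result = DelayedCorrelationResult(d_src=best, dt=best_dt, t_o=t_o)

    o = np.where(best_dt >= t_o, best, 0.0)
    np.fill_diagonal(o, 0.0)
    mask = np.ones((n, n), dtype=bool)
    np.fill_diagonal(mask, False)
    term = ObjectiveTerm(
        O=o, label="DSp", mask=mask, J=0.0, theta=theta,
        meta={"max_delay": int(max_delay), "t_o": int(t_o)},
    )
    return result, term


def select_tp(
    ko_panel: KnockoutPanel, wt_series: InterpolatedSeries | None = None
) -> int:
    """Early-response time index t_p for the time-resolved objectives.

    Per gene, the time of largest absolute rate of change following gene
    inactivation is found (central differences on the knockout
    trajectories, averaged over the mutant conditions); t_p is the modal
    index across genes, the earliest on ties.  The deletion instant itself
    (index 0) is excluded: expression has not yet responded there.
    All-constant data fall back to the midpoint with a warning.
    """
    if not ko_panel.is_time_resolved:
        raise ValueError("select_tp needs a time-resolved knockout panel")
    if ko_panel.times.size < 3:
        raise ValueError("need at least 3 timepoints")
    # genes x mutants x timepoints -> mean |dx/dt| per gene and timepoint
    deriv = np.gradient(ko_panel.mutant_values, ko_panel.times, axis=2)
    mean_abs = np.abs(deriv).mean(axis=1)  # genes x timepoints
    mean_abs[:, 0] = 0.0
    if np.max(mean_abs) == 0:
        warnings.warn("all-constant knockout trajectories; "
                      "falling back to midpoint t_p")
        return ko_panel.times.size // 2
    per_gene = np.argmax(mean_abs, axis=1)
    counts = np.bincount(per_gene, minlength=ko_panel.times.size)
    return int(np.argmax(counts))  # argmax returns the earliest on ties


def ratio_objective(
    ko_panel: KnockoutPanel,
    at: int | str = "steady",
    sign_convention: str = "log",
    theta: float = 1.0,
    epsilon: float = 1e-6,
) -> ObjectiveTerm:
    """Knockout ratio objective (Tr at a time index, Sr at steady state).

    The raw statistic is ``r[i, j] = x_i(mutant j) / x_i(wild type)`` at the
    requested time.  Conventions:

    - ``"log"`` (default): ``O = log2 r`` — magnitude reflects interaction
      strength, zero for unaffected genes; note an activator's loss gives a
      *negative* entry, so entry signs are systematically opposite to the
      true regulatory sign (sign information should come from a correlation
      objective or an ensemble).
    - ``"negated_log"``: ``O = -log2 r`` — sign matches the regulatory sign.
    - ``"raw"``: the ratio itself, unscaled.

    Columns for genes without a knockout are masked out, as is each deleted
    gene's own row in its column.
    """
    if sign_convention not in ("log", "negated_log", "raw"):
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    mut, wt = ko_panel.at_time(at)
    n = ko_panel.n_genes
    idx = {g: k for k, g in enumerate(ko_panel.gene_names)}

    if np.any(wt <= 0):
        warnings.warn("non-positive wild-type expression floored at epsilon")
    wt_f = np.clip(wt, epsilon, None)
    mut_f = np.clip(mut, epsilon, None)
    r = mut_f / wt_f[:, None]  # genes x mutants

    o = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    for k, mid in enumerate(ko_panel.mutant_ids):
        j = idx[mid]
        if sign_convention == "raw":
            o[:, j] = r[:, k]
        elif sign_convention == "log":
            o[:, j] = np.log2(r[:, k])
        else:
            o[:, j] = -np.log2(r[:, k])
        mask[:, j] = True
        mask[j, j] = False  # self entry meaningless (gene clamped at zero)
        o[j, j] = 0.0
    label = "Sr" if at == "steady" else "Tr"
    return ObjectiveTerm(
        O=o, label=label, mask=mask, J=0.0, theta=theta,
        meta={"at": at, "sign_convention": sign_convention,
              "coverage": ko_panel.coverage},
    )


def correlation_objective(
    ko_panel: KnockoutPanel,
    at: int | str = "steady",
    method: str = "pearson",
    theta: float = 1.0,
) -> ObjectiveTerm:
    """Cross-mutant correlation objective (Tc at a time index, Sc at steady).

    ``O[i, j]`` is the correlation of gene i's and gene j's expression
    across the available knockout conditions; symmetric, diagonal zero.
    For each pair the conditions in which either member is itself deleted
    are left out: an engineered zero is not an observation of the gene's
    transcriptional response.  Constant rows get zero correlation.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    mut, _wt = ko_panel.at_time(at)
    if ko_panel.n_mutants < 3:
        raise ValueError("need at least 3 mutant columns for correlations")
    n = ko_panel.n_genes
    idx = {g: k for k, g in enumerate(ko_panel.gene_names)}
    col_gene = np.array([idx[m] for m in ko_panel.mutant_ids])
    x = mut.astype(float)
    c = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keep = (col_gene != i) & (col_gene != j)
            if keep.sum() < 3:
                continue
            xi, xj = x[i, keep], x[j, keep]
            if method == "spearman":
                xi, xj = rankdata(xi), rankdata(xj)
            si, sj = xi.std(), xj.std()
            if si > 0 and sj > 0:
                xic, xjc = xi - xi.mean(), xj - xj.mean()
                c[i, j] = c[j, i] = float(
                    (xic @ xjc) / (len(xi) * si * sj)
                )
    c = np.clip(c, -1.0, 1.0)
    mask = np.ones(c.shape, dtype=bool)
    np.fill_diagonal(mask, False)
    label = "Sc" if at == "steady" else "Tc"
    return ObjectiveTerm(
        O=c, label=label, mask=mask, J=0.0, theta=theta,
        meta={"at": at, "method": method, "coverage": ko_panel.coverage},
    )


def scale_objective(term: ObjectiveTerm, strategy: str = "unit_max") -> ObjectiveTerm:
    """Rescale an objective so it is commensurate with the fitted weights.

    ``unit_max`` divides the masked entries by their maximum absolute value
    (signs and zeros preserved); ``zscore`` standardises the masked entries
    to mean 0 / sd 1; ``none`` is the identity.  An all-zero objective is
    returned unchanged.
    """
    if strategy == "none":
        return term
    masked = term.O[term.mask]
    if masked.size == 0 or np.all(masked == 0):
        return term
    o = term.O.copy()
    if strategy == "unit_max":
        o[term.mask] = masked / np.max(np.abs(masked))
    elif strategy == "zscore":
        sd = masked.std()
        if sd == 0:
            return term
        o[term.mask] = (masked - masked.mean()) / sd
    else:
        raise ValueError(f"unknown scaling strategy {strategy!r}")
    new = replace(term, O=o)
    new.meta = {**term.meta, "scaled": strategy}
    return new
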
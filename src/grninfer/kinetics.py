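"""Kinetic models and synthetic-data simulation.

This module is a compact in-silico benchmark generator in the tradition of
the DREAM network-inference challenges: a signed topology is dressed with
gene-level kinetics, wild-type and knockout expression data are produced by
integrating the resulting ODE system, and multiplicative noise mimics
experimental replication.

Two kinetic modes are supported.

``hill`` (default)
    Nonlinear regulation with saturating Hill terms combined
    multiplicatively::

        dx_i/dt = m_i * prod_act (1 + a*h(x_j)) / (1 + a)
                      * prod_rep 1 / (1 + a*h(x_j))  -  delta_i * x_i

    with ``h(x) = x^n / (K^n + x^n)``.  Production is bounded in
    ``(0, m_i]`` so the wild type always admits a finite positive steady
    state.  Half-saturation constants are centred on each regulator's
    wild-type steady-state level so that knockouts and perturbations produce
    informative fold changes.

``linear``
    ``dx/dt = m + S x - delta*x`` with the signed strength matrix rescaled
    for stability; exact closed forms make this mode the work-horse of
    parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import fsolve

from .datasets import KnockoutPanel, TimeCourse
from .network import SignedNetwork

__all__ = [
    "KineticModel",
    "sample_kinetics",
    "steady_state",
    "simulate_timecourse",
    "simulate_knockout_compendium",
    "simulate_dense_series",
    "random_perturbation",
]

#: default sampling ranges for kinetic parameters.  Decay rates are chosen
#: so relaxation times (1/decay = 5-20 time units) are resolvable by the
#: standard sampling interval (200/25 = 8 time units): faster kinetics
#: would make the time course carry no recoverable dynamics.
BASAL_RANGE = (0.5, 1.5)
DECAY_RANGE = (0.05, 0.2)
STRENGTH_RANGE = (1.0, 5.0)
HILL_RANGE = (1, 3)


class SimulationError(RuntimeError):
    """ODE integration failed or did not reach a steady state."""


@dataclass
class KineticModel:
    """A signed topology plus per-gene and per-edge kinetic parameters.

    ``interaction_strengths``, ``hill_coefficients`` and
    ``half_saturations`` map each edge ``(regulator, target)`` to its
    parameters; in linear mode only strengths are used (as the magnitude of
    the signed linear coefficient).
    """

    network: SignedNetwork
    basal_rates: np.ndarray
    decay_rates: np.ndarray
    interaction_strengths: dict[tuple[str, str], float]
    hill_coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    half_saturations: dict[tuple[str, str], float] = field(default_factory=dict)
    mode: str = "hill"

    def __post_init__(self) -> None:
        self.basal_rates = np.asarray(self.basal_rates, dtype=float)
        self.decay_rates = np.asarray(self.decay_rates, dtype=float)
        n = self.network.n_genes
        if self.basal_rates.shape != (n,) or self.decay_rates.shape != (n,):
            raise ValueError("basal/decay rates must have one entry per gene")
        if np.any(self.decay_rates <= 0):
            raise ValueError("decay rates must be positive")
        if self.mode not in ("hill", "linear"):
            raise ValueError("mode must be 'hill' or 'linear'")
        if self.mode == "hill":
            for e, h in self.hill_coefficients.items():
                if h < 1:
                    raise ValueError(f"hill coefficient < 1 for edge {e}")
        self._index = {g: k for k, g in enumerate(self.network.gene_names)}
        # flat per-edge arrays for a vectorised RHS
        edges = sorted(self.network.edges)
        self._e_reg = np.array([self._index[r] for r, _t, _s in edges], dtype=int)
        self._e_tgt = np.array([self._index[t] for _r, t, _s in edges], dtype=int)
        self._e_sign = np.array([s for _r, _t, s in edges], dtype=float)
        self._e_a = np.array(
            [self.interaction_strengths[(r, t)] for r, t, _s in edges], dtype=float
        )
        self._e_hc = np.array(
            [self.hill_coefficients.get((r, t), 2.0) for r, t, _s in edges], dtype=float
        )
        self._e_K = np.array(
            [self.half_saturations.get((r, t), 1.0) for r, t, _s in edges], dtype=float
        )

    @property
    def n_genes(self) -> int:
        return self.network.n_genes

    def linear_matrix(self) -> np.ndarray:
        """Signed linear coefficient matrix S (only meaningful in linear mode)."""
        n = self.n_genes
        s = np.zeros((n, n))
        s[self._e_tgt, self._e_reg] = self._e_sign * self._e_a
        return s

    def rhs(
        self,
        x: np.ndarray,
        basal: np.ndarray | None = None,
        knockout: int | None = None,
    ) -> np.ndarray:
        """dx/dt at state ``x``; optional basal override and hard knockout."""
        m = self.basal_rates if basal is None else basal
        x = np.asarray(x, dtype=float)
        if self.mode == "linear":
            dx = m + self.linear_matrix() @ x - self.decay_rates * x
        else:
            xc = np.clip(x, 0.0, None)
            xr = xc[self._e_reg]
            with np.errstate(divide="ignore", invalid="ignore"):
                xp = xr**self._e_hc
                h = np.where(xr > 0, xp / (self._e_K**self._e_hc + xp), 0.0)
            factor = np.where(
                self._e_sign > 0,
                (1.0 + self._e_a * h) / (1.0 + self._e_a),
                1.0 / (1.0 + self._e_a * h),
            )
            prod = np.array(m, dtype=float, copy=True)
            np.multiply.at(prod, self._e_tgt, factor)
            dx = prod - self.decay_rates * x
        if knockout is not None:
            dx[knockout] = 0.0
        return dx


def sample_kinetics(
    network: SignedNetwork,
    seed: int = 0,
    mode: str = "hill",
    basal_range: tuple[float, float] = BASAL_RANGE,
    decay_range: tuple[float, float] = DECAY_RANGE,
    strength_range: tuple[float, float] = STRENGTH_RANGE,
) -> KineticModel:
    """Draw kinetic parameters for a topology.

    Hill-mode half saturations are drawn uniformly over each regulator's
    attainable expression range (production is bounded by the basal rate, so
    the ceiling is basal/decay): some edges therefore operate near
    saturation or below threshold and are intrinsically hard to detect,
    giving the heterogeneous edge detectability characteristic of in-silico
    benchmark suites.  Linear mode rescales the strength matrix until the
    system is stable with a non-negative steady state.
    """
    rng = np.random.default_rng(seed)
    n = network.n_genes
    basal = rng.uniform(*basal_range, size=n)
    decay = rng.uniform(*decay_range, size=n)
    edges = sorted(network.edges)
    strengths = {(r, t): float(rng.uniform(*strength_range)) for r, t, _s in edges}
    hills = {(r, t): float(rng.integers(HILL_RANGE[0], HILL_RANGE[1] + 1)) for r, t, _s in edges}

    if mode == "linear":
        margin = -0.5 * float(decay.min())
        for _ in range(60):
            model = KineticModel(network, basal, decay, strengths, mode="linear")
            a_mat = model.linear_matrix() - np.diag(decay)
            if np.max(np.linalg.eigvals(a_mat).real) < margin:
                ss = np.linalg.solve(-a_mat, basal)
                if np.all(ss >= 0):
                    break
            strengths = {e: v * 0.5 for e, v in strengths.items()}
        else:
            raise SimulationError("could not stabilise linear model")
        return model

    index = {g: k for k, g in enumerate(network.gene_names)}
    x_max = basal / decay
    half = {
        (r, t): float(max(rng.uniform(0.1, 1.0) * x_max[index[r]], 1e-3))
        for r, t, _s in edges
    }
    return KineticModel(network, basal, decay, strengths, hills, half, mode="hill")


def steady_state(
    model: KineticModel,
    basal: np.ndarray | None = None,
    knockout: int | None = None,
    x0: np.ndarray | None = None,
    t_horizon: float = 2000.0,
    tol: float = 1e-6,
) -> np.ndarray:
    """Numerically computed steady state (integration + root polish).

    Raises :class:`SimulationError` if ``max |dx/dt|`` does not fall below
    ``tol * max(|x|, 1)`` within the integration horizon.
    """
    n = model.n_genes
    if x0 is None:
        x0 = model.basal_rates / model.decay_rates
        if knockout is not None:
            x0 = x0.copy()
            x0[knockout] = 0.0

    def f(_t, x):
        return model.rhs(x, basal=basal, knockout=knockout)

    sol = solve_ivp(
        f, (0.0, t_horizon), x0, method="LSODA", rtol=1e-9, atol=1e-10, dense_output=False
    )
    if not sol.success:
        raise SimulationError(f"steady-state integration failed: {sol.message}")
    x = sol.y[:, -1]

    def g(x):
        return model.rhs(x, basal=basal, knockout=knockout)

    polished, info, ier, _msg = fsolve(g, x, full_output=True)
    if ier == 1 and np.all(np.isfinite(polished)):
        x = polished
    if knockout is not None:
        x[knockout] = 0.0
    x = np.where(np.abs(x) < 1e-12, 0.0, x)
    resid = np.max(np.abs(model.rhs(x, basal=basal, knockout=knockout)))
    if resid > tol * max(np.max(np.abs(x)), 1.0):
        raise SimulationError(
            f"no steady state within horizon (residual {resid:.3g})"
        )
    return x


def random_perturbation(
    n_genes: int, seed: int = 0, fold: float = 3.0, subset: float = 1.0 / 3.0
) -> np.ndarray:
    """Multifactorial perturbation: multiplicative basal-rate factors.

    A random ``subset`` of the genes gets its basal production multiplied
    by a log-uniform factor in ``[1/fold, fold]``; the rest keep factor 1.
    Perturbing only part of the genes leaves the others as passive
    reporters whose movement is purely regulatory propagation — the signal
    the lagged-correlation objective reads.
    """
    rng = np.random.default_rng(seed)
    factors = np.ones(n_genes)
    chosen = rng.random(n_genes) < subset
    if not chosen.any():
        chosen[int(rng.integers(n_genes))] = True
    factors[chosen] = fold ** rng.uniform(-1.0, 1.0, size=n_genes)[chosen]
    return factors


def _add_noise(values: np.ndarray, noise_level: float, rng) -> np.ndarray:
    if noise_level == 0:
        return values.copy()
    noisy = values * (1.0 + noise_level * rng.standard_normal(values.shape))
    return np.clip(noisy, 0.0, None)


def simulate_timecourse(
    model: KineticModel,
    perturbation: np.ndarray | None = None,
    n_timepoints: int = 26,
    t_max: float = 200.0,
    replicates: int = 3,
    noise_level: float = 0.05,
    seed: int = 0,
) -> TimeCourse:
    """Simulate a perturbation time course.

    The system starts at the unperturbed wild-type steady state; at t=0 the
    basal production rates are multiplied by ``perturbation`` (drawn by
    :func:`random_perturbation` when None) and the trajectory is sampled on
    an equally spaced grid of ``n_timepoints`` over ``[0, t_max]``.  Each
    replicate receives independent multiplicative Gaussian noise with
    standard deviation ``noise_level`` times the signal, truncated at zero.
    """
    if noise_level < 0:
        raise ValueError("noise_level must be >= 0")
    rng = np.random.default_rng(seed)
    n = model.n_genes
    if perturbation is None:
        perturbation = random_perturbation(n, seed=seed)
    perturbation = np.asarray(perturbation, dtype=float)
    basal = model.basal_rates * perturbation

    x0 = steady_state(model)
    times = np.linspace(0.0, t_max, n_timepoints)
    sol = solve_ivp(
        lambda _t, x: model.rhs(x, basal=basal),
        (0.0, t_max),
        x0,
        t_eval=times,
        method="LSODA",
        rtol=1e-9,
        atol=1e-10,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(f"time-course integration diverged: {sol.message}")
    clean = sol.y  # genes x timepoints
    reps = np.stack(
        [_add_noise(clean, noise_level, rng) for _ in range(replicates)], axis=2
    )
    return TimeCourse(
        reps,
        times,
        list(model.network.gene_names),
        meta={"seed": int(seed), "noise_level": float(noise_level)},
    )


def simulate_dense_series(
    model: KineticModel,
    perturbation: np.ndarray | None = None,
    n_points: int = 200,
    t_max: float = 200.0,
    seed: int = 0,
    displace_state: float = 0.0,
):
    """Noise-free densely sampled trajectory with *exact* model derivatives.

    Bypasses the measurement/interpolation pipeline entirely: values come
    from the ODE solution on the dense grid and derivatives from the model
    right-hand side.  This is the idealised input for estimator studies
    (parameter recovery, estimator ceilings) where interpolation error must
    be excluded.  ``displace_state > 0`` additionally kicks the initial
    state away from the steady state by random per-gene factors in
    ``[1-displace_state, 1+displace_state]``, exciting every dynamic mode —
    the well-conditioned regime for parameter identification.
    """
    from .datasets import InterpolatedSeries

    n = model.n_genes
    if perturbation is None:
        perturbation = random_perturbation(n, seed=seed)
    basal = model.basal_rates * np.asarray(perturbation, dtype=float)
    x0 = steady_state(model)
    if displace_state > 0:
        rng = np.random.default_rng(seed)
        x0 = x0 * rng.uniform(1 - displace_state, 1 + displace_state, size=n)
    times = np.linspace(0.0, t_max, n_points)
    sol = solve_ivp(
        lambda _t, x: model.rhs(x, basal=basal),
        (0.0, t_max),
        x0,
        t_eval=times,
        method="LSODA",
        rtol=1e-10,
        atol=1e-12,
    )
    if not sol.success:
        raise SimulationError(f"dense simulation failed: {sol.message}")
    values = sol.y
    derivs = np.stack(
        [model.rhs(values[:, k], basal=basal) for k in range(n_points)], axis=1
    )
    return InterpolatedSeries(
        values=values, derivatives=derivs, times=times,
        gene_names=list(model.network.gene_names),
        meta={"exact": True, "seed": int(seed)},
    )


def simulate_knockout_compendium(
    model: KineticModel,
    mode: str = "steady",
    coverage: float = 1.0,
    noise_level: float = 0.05,
    seed: int = 0,
    n_timepoints: int = 26,
    t_max: float = 200.0,
) -> KnockoutPanel:
    """Simulate the stepwise deletion of each gene.

    Deletion is hard: the gene's state is clamped at zero and its production
    removed.  ``mode="steady"`` records the post-deletion steady state;
    ``mode="timecourse"`` records the relaxation from the wild-type steady
    state on the standard grid.  ``coverage < 1`` keeps a seeded random
    subset of the knockout columns, emulating a partial mutant collection.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if mode not in ("steady", "timecourse"):
        raise ValueError("mode must be 'steady' or 'timecourse'")
    rng = np.random.default_rng(seed)
    n = model.n_genes
    genes = list(model.network.gene_names)

    n_keep = int(round(coverage * n))
    kept = sorted(rng.choice(n, size=n_keep, replace=False))

    wt_ss = steady_state(model)
    times = np.linspace(0.0, t_max, n_timepoints)
    cols = []
    for g in kept:
        if mode == "steady":
            x0 = wt_ss.copy()
            x0[g] = 0.0
            cols.append(steady_state(model, knockout=g, x0=x0))
        else:
            x0 = wt_ss.copy()
            x0[g] = 0.0
            sol = solve_ivp(
                lambda _t, x, g=g: model.rhs(x, knockout=g),
                (0.0, t_max),
                x0,
                t_eval=times,
                method="LSODA",
                rtol=1e-9,
                atol=1e-10,
            )
            if not sol.success:
                raise SimulationError(
                    f"knockout time course failed for {genes[g]}: {sol.message}"
                )
            cols.append(sol.y)

    if mode == "steady":
        mut = np.stack(cols, axis=1)  # genes x mutants
        wt = wt_ss
    else:
        mut = np.stack(cols, axis=1)  # genes x mutants x timepoints
        wt = np.tile(wt_ss[:, None], (1, n_timepoints))

    mut = _add_noise(mut, noise_level, rng)
    wt = _add_noise(wt, noise_level, rng)
    # the deleted gene itself is clamped at zero, noise or not
    for k, g in enumerate(kept):
        mut[g, k] = 0.0

    return KnockoutPanel(
        mutant_values=mut,
        mutant_ids=[genes[g] for g in kept],
        wildtype_reference=wt,
        gene_names=genes,
        t_p="steady" if mode == "steady" else 0,
        times=times if mode == "timecourse" else None,
        meta={"seed": int(seed), "noise_level": float(noise_level), "mode": mode},
    )
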
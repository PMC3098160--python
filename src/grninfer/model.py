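"""Linear-ODE network model and its single/multi-objective estimators.

The model is the additive linear ODE

    dx_i/dt = sum_j w_ij x_j(t) + b_i,

where ``w[i, j]`` is the (signed) influence of gene j on gene i and ``b_i``
the effect of the external perturbation on gene i.  Fitting matches the
model right-hand side to the derivative estimates of a densely interpolated
expression series (derivative matching), so the squared error

    E_SQE(w, b) = sum_i sum_t (dx_i/dt(t) - sum_j w_ij x_j(t) - b_i)^2

is an ordinary least-squares criterion, convex in (w, b).

Single-objective optimisation (SOO) minimises E_SQE alone.  Multi-objective
optimisation (MOO) additionally pulls ``w`` toward one or more objective
matrices O via the Euclidean distances ``E_obj_k = ||w - O_k||`` (on each
term's mask) using the goal-attainment scheme: minimise the scalar gamma
subject to ``F_k - theta_k * gamma <= J_k`` for every objective ``F_k``,
where ``F_1 = E_SQE`` is a hard goal (theta = 0).  A literal hard goal
``E_SQE <= 0`` is infeasible on noisy data, so it is implemented as
``E_SQE <= E_SQE_min * (1 + slack)`` with the minimum taken from the SOO
solution (``slack`` defaults to 0.05).

Because every F_k is convex, the attainment optimum lies on the Pareto
surface and can be located exactly by a scalarisation search (the default
``"dual"`` solver): each candidate is a per-gene regularised least-squares
solve, the Lagrange multiplier of the E_SQE constraint is found by
bisection, and for several soft terms the scalarisation weights are
balanced until all attainments ``(F_k - J_k)/theta_k`` are equal.  A direct
SLSQP transcription of the goal-attainment program from a seeded random
initial matrix is available as ``solver="slsqp"`` for cross-checking on
small problems.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .datasets import InterpolatedSeries, write_expression_tsv
from .objectives import ObjectiveTerm, scale_objective

__all__ = [
    "GRNModel",
    "GRNResults",
    "GoalAttainmentProblem",
    "sqe",
    "objective_distance",
    "soo_fit",
    "moo_fit",
    "ensemble_combine",
]


class OptimizationError(RuntimeError):
    pass


def _design(series: InterpolatedSeries) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix A = [X^T, 1] (T x (N+1)) and derivative targets (N x T)."""
    x = series.values
    t = x.shape[1]
    a = np.hstack([x.T, np.ones((t, 1))])
    return a, series.derivatives


def sqe(w: np.ndarray, b: np.ndarray, series: InterpolatedSeries) -> float:
    """Squared error of the linear ODE on the interpolated series."""
    w = np.asarray(w, dtype=float)
    b = np.asarray(b, dtype=float)
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite parameters")
    a, d = _design(series)
    z = np.hstack([w, b[:, None]])  # N x (N+1)
    resid = z @ a.T - d
    return float(np.sum(resid**2))


def objective_distance(w: np.ndarray, term: ObjectiveTerm) -> float:
    """Euclidean distance ||w - O|| over the term's masked entries."""
    w = np.asarray(w, dtype=float)
    if term.mask.shape != w.shape:
        raise ValueError("mask shape does not match w")
    if not term.mask.any():
        warnings.warn("objective term has an empty mask; distance is 0")
        return 0.0
    diff = (w - term.O)[term.mask]
    return float(np.sqrt(np.sum(diff**2)))


def _closed_form(series: InterpolatedSeries) -> tuple[np.ndarray, np.ndarray, float]:
    """Minimum-norm least-squares solution of the derivative-matching SQE."""
    a, d = _design(series)
    z, *_ = np.linalg.lstsq(a, d.T, rcond=None)
    z = z.T  # N x (N+1)
    w, b = z[:, :-1], z[:, -1]
    return w, b, sqe(w, b, series)


def soo_fit(
    series: InterpolatedSeries,
    tolerance: float = 1e-6,
    init_seed: int = 0,
    solver: str = "trust-region",
) -> "GRNResults":
    """Single-objective fit: minimise E_SQE.

    ``solver="trust-region"`` (default) runs a trust-region-reflective
    least-squares pass per gene from a seeded random initial matrix (entries
    uniform on [-0.1, 0.1]); ``solver="exact"`` returns the minimum-norm
    normal-equation solution.  Both attain the same E_SQE (the problem is
    convex); the parameters may differ along directions the data do not
    constrain.
    """
    a, d = _design(series)
    n = series.n_genes
    if solver == "exact":
        w, b, val = _closed_form(series)
    elif solver == "trust-region":
        rng = np.random.default_rng(init_seed)
        z0 = rng.uniform(-0.1, 0.1, size=(n, n + 1))
        z = np.empty_like(z0)
        for i in range(n):
            res = least_squares(
                lambda zz, i=i: a @ zz - d[i],
                z0[i],
                jac=lambda zz, a=a: a,
                method="trf",
                xtol=tolerance,
                ftol=tolerance,
                gtol=tolerance,
            )
            if not res.success:
                raise OptimizationError(
                    f"SOO did not converge for gene {series.gene_names[i]} "
                    f"(final E_SQE contribution {res.cost * 2:.4g})"
                )
            z[i] = res.x
        w, b = z[:, :-1], z[:, -1]
        val = sqe(w, b, series)
    else:
        raise ValueError(f"unknown SOO solver {solver!r}")
    return GRNResults(
        w=w, b=b, role="soo", model=None, sqe_value=val,
        provenance={"solver": solver, "init_seed": int(init_seed)},
        gene_names=list(series.gene_names),
    )


@dataclass
class GoalAttainmentProblem:
    """The multi-objective estimation problem handed to :func:`moo_fit`.

    ``terms`` are the data-derived objectives F_2..F_m; F_1 = E_SQE is
    implicit and carries goal 0 / weight 0 (hard), realised as the relaxed
    bound ``E_SQE <= E_SQE_min * (1 + sqe_slack)``.
    """

    data: InterpolatedSeries
    terms: list[ObjectiveTerm] = field(default_factory=list)
    sqe_slack: float = 0.05
    tolerance: float = 1e-6
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        n = self.data.n_genes
        for t in self.terms:
            if t.n_genes != n:
                raise ValueError("objective term size does not match the data")


def _ridge_solve(
    ata: np.ndarray,
    atd: np.ndarray,
    masks: np.ndarray,
    targets: np.ndarray,
    alphas: np.ndarray,
    lam: float,
    ridge: float = 1e-9,
) -> np.ndarray:
    """Per-gene solve of  (sum_k a_k M_k + lam A'A + r I) z = rhs.

    masks/targets: m x N x (N+1) boolean / float (objective entries padded
    with a zero column for b).  Returns z as N x (N+1).
    """
    n = atd.shape[1]
    p = ata.shape[0]
    lhs = np.broadcast_to(lam * ata + ridge * np.eye(p), (n, p, p)).copy()
    rhs = (lam * atd).T.copy()  # N x p
    for k in range(masks.shape[0]):
        mk = masks[k]  # N x p
        lhs[:, np.arange(p), np.arange(p)] += alphas[k] * mk
        rhs += alphas[k] * mk * targets[k]
    return np.linalg.solve(lhs, rhs[:, :, None])[:, :, 0]


def _pad(mat: np.ndarray) -> np.ndarray:
    """Append a zero column (the b coordinate) to an N x N matrix."""
    n = mat.shape[0]
    return np.hstack([mat, np.zeros((n, 1), dtype=mat.dtype)])


def moo_fit(problem: GoalAttainmentProblem, solver: str = "dual") -> "GRNResults":
    """Goal-attainment fit of the regulatory matrix.

    Returns a :class:`GRNResults` whose ``gamma`` is the attained value of
    the dummy variable and whose ``attainment`` maps each term label to
    ``F_k - J_k``.
    """
    series = problem.data
    if not problem.terms:
        return soo_fit(series, problem.tolerance, problem.init_seed)
    if solver == "slsqp":
        return _moo_fit_slsqp(problem)
    if solver != "dual":
        raise ValueError(f"unknown MOO solver {solver!r}")

    a, d = _design(series)
    n = series.n_genes
    ata = a.T @ a
    atd = a.T @ d.T  # (N+1) x N

    w0, b0, sqe_min = _closed_form(series)
    # absolute floor: polynomial-interpolated data is often *exactly*
    # representable (sqe_min ~ machine zero), where a purely relative
    # slack would demand an unattainable numerical target
    sqe_bound = sqe_min * (1.0 + problem.sqe_slack) + 1e-9 * float(np.sum(d**2))

    masks = np.stack([_pad(t.mask).astype(float) for t in problem.terms])
    targets = np.stack([_pad(np.where(t.mask, t.O, 0.0)) for t in problem.terms])
    thetas = np.array([t.theta for t in problem.terms])
    goals = np.array([t.J for t in problem.terms])
    m = len(problem.terms)

    def solve_at(alphas: np.ndarray, lam: float) -> np.ndarray:
        return _ridge_solve(ata, atd, masks, targets, alphas, lam)

    def sqe_of(z: np.ndarray) -> float:
        resid = z @ a.T - d
        return float(np.sum(resid**2))

    def dists_of(z: np.ndarray) -> np.ndarray:
        w = z[:, :-1]
        return np.array(
            [objective_distance(w, t) for t in problem.terms]
        )

    # SVD pieces for the exact-fit (lambda -> infinity) limit: the SQE-
    # minimising component is pinned and the objective is minimised over
    # the null space of the design
    u_svd, s_svd, vt_svd = np.linalg.svd(a, full_matrices=True)
    rank = int(np.sum(s_svd > s_svd[0] * 1e-10))
    v_range = vt_svd[:rank].T  # (N+1) x r
    v_null = vt_svd[rank:].T  # (N+1) x (N+1-r)
    z_min = ((v_range / s_svd[:rank]) @ (u_svd[:, :rank].T @ d.T)).T  # N x (N+1)

    def solve_projected(alphas: np.ndarray) -> np.ndarray:
        """Exact SQE minimiser per gene + objective fit over the null space."""
        if v_null.shape[1] == 0:
            return z_min
        z = np.empty_like(z_min)
        for i in range(n):
            mdiag = np.zeros(n + 1)
            rhs_t = np.zeros(n + 1)
            for k in range(masks.shape[0]):
                mdiag += alphas[k] * masks[k, i]
                rhs_t += alphas[k] * masks[k, i] * targets[k, i]
            q = (v_null * mdiag[:, None]).T @ v_null
            q[np.diag_indices_from(q)] += 1e-9
            rhs = v_null.T @ (rhs_t - mdiag * z_min[i])
            c = np.linalg.solve(q, rhs)
            z[i] = z_min[i] + v_null @ c
        return z

    def solve_constrained(alphas: np.ndarray) -> np.ndarray:
        """min sum_k alpha_k dist_k^2  s.t.  sqe <= sqe_bound (lam bisection)."""
        z0 = solve_at(alphas, 0.0)
        if sqe_of(z0) <= sqe_bound:
            return z0
        lo, hi = 0.0, 1.0
        while sqe_of(solve_at(alphas, hi)) > sqe_bound:
            hi *= 10.0
            if hi > 1e8:
                # numerically at the exact-fit limit
                return solve_projected(alphas)
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if sqe_of(solve_at(alphas, mid)) > sqe_bound:
                lo = mid
            else:
                hi = mid
        return solve_at(alphas, hi)

    soft = thetas > 0
    if not soft.any():
        # hard goals only: escalate weights until every goal is met
        alphas = np.ones(m)
        for _ in range(40):
            z = solve_constrained(alphas)
            viol = dists_of(z) - goals
            if np.all(viol <= problem.tolerance * 10 + 1e-8):
                break
            alphas[viol > 0] *= 4.0
        else:
            bad = [t.label for t, v in zip(problem.terms, viol) if v > 0]
            raise OptimizationError(f"infeasible hard goals: {bad}")
        gamma = 0.0
    elif m == 1:
        z = solve_constrained(np.ones(1))
        gamma = float((dists_of(z)[0] - goals[0]) / thetas[0])
    else:
        # balance the scalarisation weights until the soft attainments
        # (F_k - J_k)/theta_k coincide; hard terms get escalated weights
        alphas = np.ones(m) / m
        eta = 0.6
        z = solve_constrained(alphas)
        for _ in range(120):
            g = (dists_of(z) - goals) / np.where(soft, thetas, 1.0)
            hard_viol = (~soft) & (dists_of(z) > goals + 1e-8)
            if hard_viol.any():
                alphas[hard_viol] *= 4.0
            gs = g[soft]
            spread = gs.max() - gs.min()
            tol = max(1e-6, 1e-4 * max(abs(gs.max()), 1e-9))
            if spread <= tol and not hard_viol.any():
                break
            upd = np.exp(eta * (g - gs.mean()))
            alphas[soft] *= upd[soft]
            alphas = np.clip(alphas, 1e-9, 1e9)
            alphas /= alphas.sum()
            z = solve_constrained(alphas)
        g = (dists_of(z) - goals) / np.where(soft, thetas, np.inf)
        gamma = float(g[soft].max())

    w, b = z[:, :-1], z[:, -1]
    dists = dists_of(z)
    return GRNResults(
        w=w, b=b, role="moo", model=None, sqe_value=sqe_of(z), gamma=gamma,
        attainment={t.label: float(dv - t.J) for t, dv in zip(problem.terms, dists)},
        provenance={
            "solver": "dual",
            "init_seed": int(problem.init_seed),
            "terms": [t.label for t in problem.terms],
            "sqe_min": sqe_min,
            "sqe_bound": sqe_bound,
        },
        gene_names=list(series.gene_names),
    )


def _moo_fit_slsqp(problem: GoalAttainmentProblem) -> "GRNResults":
    """Direct SLSQP transcription of the goal-attainment program.

    Cross-check path for small problems: variables (w, b, gamma), objective
    gamma, constraints E_SQE <= bound and F_k - theta_k gamma <= J_k.
    """
    series = problem.data
    a, d = _design(series)
    n = series.n_genes
    p = n + 1
    _w0, _b0, sqe_min = _closed_form(series)
    sqe_bound = sqe_min * (1.0 + problem.sqe_slack) + 1e-9 * max(sqe_min, 1e-9)

    rng = np.random.default_rng(problem.init_seed)
    z0 = rng.uniform(-0.1, 0.1, size=n * p)

    def unpack(u):
        z = u[:-1].reshape(n, p)
        return z, u[-1]

    def f(u):
        return u[-1]

    def f_grad(u):
        g = np.zeros_like(u)
        g[-1] = 1.0
        return g

    def sqe_con(u):
        z, _ = unpack(u)
        return sqe_bound - np.sum((z @ a.T - d) ** 2)

    def sqe_con_grad(u):
        z, _ = unpack(u)
        grad = -2.0 * (z @ a.T - d) @ a  # N x p
        return np.append(grad.ravel(), 0.0)

    cons = [{"type": "ineq", "fun": sqe_con, "jac": sqe_con_grad}]
    for term in problem.terms:
        mk = _pad(term.mask)
        ok = _pad(np.where(term.mask, term.O, 0.0))

        def dist_con(u, mk=mk, ok=ok, term=term):
            z, gam = unpack(u)
            dist = np.sqrt(np.sum(((z - ok) * mk) ** 2))
            return term.J + term.theta * gam - dist

        def dist_con_grad(u, mk=mk, ok=ok, term=term):
            z, gam = unpack(u)
            diff = (z - ok) * mk
            dist = max(np.sqrt(np.sum(diff**2)), 1e-12)
            return np.append(-(diff / dist).ravel(), term.theta)

        cons.append({"type": "ineq", "fun": dist_con, "jac": dist_con_grad})

    z0m = z0.reshape(n, p)
    g0 = max(
        (np.sqrt(np.sum(((z0m - _pad(np.where(t.mask, t.O, 0.0)))
                         * _pad(t.mask)) ** 2)) - t.J) / max(t.theta, 1e-9)
        for t in problem.terms
    )
    u0 = np.append(z0, g0 + 1.0)
    res = minimize(
        f, u0, jac=f_grad, constraints=cons, method="SLSQP",
        options={"maxiter": 2000, "ftol": problem.tolerance},
    )
    if not res.success:
        raise OptimizationError(f"SLSQP goal attainment failed: {res.message}")
    z, gamma = unpack(res.x)
    w, b = z[:, :-1], z[:, -1]
    dists = [objective_distance(w, t) for t in problem.terms]
    return GRNResults(
        w=w, b=b, role="moo", model=None,
        sqe_value=sqe(w, b, series), gamma=float(gamma),
        attainment={t.label: float(dv - t.J) for t, dv in zip(problem.terms, dists)},
        provenance={"solver": "slsqp", "init_seed": int(problem.init_seed),
                    "terms": [t.label for t in problem.terms]},
        gene_names=list(series.gene_names),
    )


def ensemble_combine(w_r: "GRNResults", w_c: "GRNResults") -> "GRNResults":
    """Combine two fits: magnitudes from ``w_r``, signs from ``w_c``.

    ``|w_a| = |w_r|`` and ``sign(w_a) = sign(w_c)``; where the sign donor is
    exactly zero the entry keeps a positive sign (documented tie rule).
    """
    if w_r.w.shape != w_c.w.shape:
        raise ValueError("ensemble inputs have mismatched shapes")
    signs = np.where(w_c.w == 0, 1.0, np.sign(w_c.w))
    w = np.abs(w_r.w) * signs
    return GRNResults(
        w=w, b=w_r.b.copy(), role="ensemble", model=None,
        sqe_value=None,
        provenance={"magnitude_from": w_r.role, "sign_from": w_c.role},
        gene_names=list(w_r.gene_names),
    )


@dataclass
class GRNResults:
    """Fitted gene regulatory matrix with diagnostics.

    Attributes
    ----------
    w : ndarray
        N x N regulatory matrix; ``w[i, j]`` is the effect of gene j on
        gene i (units 1/time).
    b : ndarray
        Per-gene perturbation effect (expression/time).
    role : str
        One of ``soo``, ``moo``, ``ensemble`` (plus a free-form tag for
        matrix predictors scored directly, e.g. the raw delayed-correlation
        matrix).
    gamma : float or None
        Attained goal-attainment dummy value (MOO only).
    attainment : dict
        Per-objective ``F_k - J_k`` at the solution (MOO only).
    """

    w: np.ndarray
    b: np.ndarray
    gene_names: list[str]
    role: str = "soo"
    model: "GRNModel | None" = None
    sqe_value: float | None = None
    gamma: float | None = None
    attainment: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        n = len(self.gene_names)
        if self.w.shape != (n, n) or self.b.shape != (n,):
            raise ValueError("w/b shape does not match gene list")
        if not (np.all(np.isfinite(self.w)) and np.all(np.isfinite(self.b))):
            raise ValueError("non-finite estimates")

    @property
    def n_genes(self) -> int:
        return len(self.gene_names)

    def w_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.gene_names, columns=self.gene_names)

    def to_edge_list(self) -> pd.DataFrame:
        """Ranked edge list: regulator, target, weight, sign (|w| descending)."""
        n = self.n_genes
        rows = []
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                wij = self.w[i, j]
                rows.append(
                    (self.gene_names[j], self.gene_names[i], wij,
                     int(np.sign(wij)) if wij != 0 else 0)
                )
        df = pd.DataFrame(rows, columns=["regulator", "target", "weight", "sign"])
        return df.reindex(
            df.weight.abs().sort_values(ascending=False).index
        ).reset_index(drop=True)

    def save(self, prefix: str) -> None:
        """Write w (TSV), b (TSV) and provenance (JSON)."""
        import json

        write_expression_tsv(prefix + "_w.tsv", self.w, self.gene_names, self.gene_names)
        write_expression_tsv(
            prefix + "_b.tsv", self.b[:, None], self.gene_names, ["b"]
        )
        payload = {
            "role": self.role,
            "gamma": self.gamma,
            "sqe": self.sqe_value,
            "attainment": self.attainment,
            "provenance": self.provenance,
        }
        with open(prefix + ".json", "w") as fh:
            json.dump(payload, fh, indent=1, default=str)

    def summary(self, top: int = 10) -> str:
        """Readable fit report: criterion values and the strongest edges."""
        lines = [
            "Gene regulatory network fit",
            "=" * 42,
            f"genes:          {self.n_genes}",
            f"procedure:      {self.role}",
        ]
        if self.sqe_value is not None:
            lines.append(f"E_SQE:          {self.sqe_value:.6g}")
        if self.gamma is not None:
            lines.append(f"gamma attained: {self.gamma:.6g}")
        for label, att in self.attainment.items():
            lines.append(f"  F[{label}] - J:  {att:.6g}")
        edges = self.to_edge_list().head(top)
        lines.append(f"top {min(top, len(edges))} edges (|weight| desc):")
        for _, r in edges.iterrows():
            arrow = "-|" if r.sign < 0 else "->"
            lines.append(
                f"  {r.regulator} {arrow} {r.target}   w = {r.weight:+.4f}"
            )
        return "\n".join(lines)


class GRNModel:
    """Linear-ODE gene network model over an interpolated expression series.

    Parameters
    ----------
    series
        Densely interpolated single-replicate series with derivatives (see
        :func:`grninfer.preprocess.interpolate_timecourse`).
    terms
        Objective terms for multi-objective fitting; scaled with
        ``scale_strategy`` at construction.  With no terms, ``fit`` reduces
        to the single-objective least-squares estimator.
    sqe_slack
        Relative relaxation of the hard squared-error goal in MOO.
    tolerance
        Convergence tolerance of the optimisers.

    Examples
    --------
    >>> model = GRNModel(series, terms=[dsp_term])
    >>> res = model.fit(method="moo", seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        series: InterpolatedSeries,
        terms: list[ObjectiveTerm] | tuple = (),
        scale_strategy: str = "unit_max",
        sqe_slack: float = 0.05,
        tolerance: float = 1e-6,
    ) -> None:
        self.series = series
        self.terms = [scale_objective(t, scale_strategy) for t in terms]
        self.sqe_slack = float(sqe_slack)
        self.tolerance = float(tolerance)

    @classmethod
    def from_timecourse(
        cls,
        tc,
        terms: list[ObjectiveTerm] | tuple = (),
        n_interp_points: int = 200,
        max_degree: int = 6,
        **kwargs,
    ) -> "GRNModel":
        """Build a model straight from a replicated raw time course."""
        from .preprocess import average_replicates, interpolate_timecourse

        series = interpolate_timecourse(
            average_replicates(tc), n_points=n_interp_points, max_degree=max_degree
        )
        return cls(series, terms=terms, **kwargs)

    def fit(
        self, method: str = "moo", seed: int = 0, solver: str | None = None
    ) -> GRNResults:
        """Estimate (w, b).

        ``method="soo"`` ignores the objective terms; ``method="moo"``
        requires at least one term (and falls back to SOO without any).
        """
        if method == "soo" or (method == "moo" and not self.terms):
            res = soo_fit(
                self.series, tolerance=self.tolerance, init_seed=seed,
                solver=solver or "trust-region",
            )
        elif method == "moo":
            problem = GoalAttainmentProblem(
                data=self.series,
                terms=self.terms,
                sqe_slack=self.sqe_slack,
                tolerance=self.tolerance,
                init_seed=seed,
            )
            res = moo_fit(problem, solver=solver or "dual")
        else:
            raise ValueError(f"unknown method {method!r}")
        res.model = self
        return res
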
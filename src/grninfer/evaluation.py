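"""Scoring inferred networks against ground truth and benchmark runs.

Two accuracy metrics are used:

* **Undirected AUC** — every unordered gene pair is scored by the larger of
  the two directed weight magnitudes and ranked against the true (undirected)
  connectivity; the area under the ROC curve is the Mann-Whitney statistic.

* **Directed-signed AUC** — the threshold on ``|w|`` is swept; at each
  threshold the predicted signed edge set is compared against the true
  network, counting as true positives only edges with the correct target,
  regulator *and* sign.  The curve of true-positive rate against
  true-negative rate (over the true non-edges) is integrated by trapezoid.
  A predictor with the right magnitudes but systematically wrong signs
  scores close to 0, so values below 0.5 are meaningful.

Self-loops (diagonal entries) are excluded from both metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score

from .kinetics import sample_kinetics, simulate_knockout_compendium, simulate_timecourse
from .model import GRNModel, GRNResults, ensemble_combine, soo_fit
from .network import SignedNetwork, extract_subnetwork, generate_source_topology
from .objectives import (
    correlation_objective,
    delayed_spearman_objective,
    ratio_objective,
    select_tp,
)
from .preprocess import average_replicates, interpolate_timecourse

__all__ = [
    "auc_undirected",
    "auc_directed_signed",
    "threshold_network",
    "compare_auc_distributions",
    "BenchmarkConfig",
    "BenchmarkResult",
    "run_benchmark",
    "PROCEDURES",
]


class EvaluationError(ValueError):
    pass


def _weight_matrix(w) -> np.ndarray:
    if isinstance(w, GRNResults):
        return w.w
    return np.asarray(w, dtype=float)


def auc_undirected(w, truth: SignedNetwork) -> float:
    """ROC AUC over unordered pairs scored by max(|w_ij|, |w_ji|)."""
    w = _weight_matrix(w)
    n = truth.n_genes
    if w.shape != (n, n):
        raise EvaluationError("weight matrix size does not match the network")
    adj = truth.adjacency()
    iu = np.triu_indices(n, k=1)
    scores = np.maximum(np.abs(w), np.abs(w.T))[iu]
    labels = ((adj != 0) | (adj.T != 0))[iu].astype(int)
    if labels.min() == labels.max():
        raise EvaluationError("degenerate truth: need at least one edge and one non-edge")
    return float(roc_auc_score(labels, scores))


def auc_directed_signed(w, truth: SignedNetwork) -> float:
    """Area under the TPR-vs-TNR curve with sign-and-direction-exact TPs.

    Thresholds sweep the sorted |w| values over ordered pairs (i != j); at
    threshold tau the prediction is ``{j -> i : |w_ij| >= tau}`` with sign
    ``sign(w_ij)``.  TPR counts correctly signed true edges among all true
    edges; TNR counts unpredicted true non-edges among all true non-edges.
    The curve starts at (TNR=1, TPR=0) and ends at full inclusion (TNR=0).
    """
    w = _weight_matrix(w)
    n = truth.n_genes
    if w.shape != (n, n):
        raise EvaluationError("weight matrix size does not match the network")
    adj = truth.adjacency()
    off = ~np.eye(n, dtype=bool)
    scores = np.abs(w)[off]
    pred_sign = np.sign(w)[off]
    true_sign = adj[off]

    n_edges = int(np.count_nonzero(true_sign))
    n_nonedges = true_sign.size - n_edges
    if n_edges == 0 or n_nonedges == 0:
        raise EvaluationError("degenerate truth: need at least one edge and one non-edge")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    correct = (true_sign[order] != 0) & (pred_sign[order] == true_sign[order])
    nonedge = true_sign[order] == 0

    cum_tp = np.cumsum(correct)
    cum_fp_nonedge = np.cumsum(nonedge)
    # group ties: keep only the last position of each distinct threshold
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, cum_tp[last] / n_edges]
    tnr = np.r_[1.0, 1.0 - cum_fp_nonedge[last] / n_nonedges]
    if tnr[-1] != 0.0:  # full-inclusion point
        tnr = np.r_[tnr, 0.0]
        tpr = np.r_[tpr, tpr[-1]]
    # integrate TPR over decreasing TNR
    return float(np.trapezoid(tpr[::-1], tnr[::-1]))


def threshold_network(
    w,
    n_edges: int | None = None,
    n_connected_genes: int | None = None,
    gene_names: list[str] | None = None,
) -> SignedNetwork:
    """Keep the largest-|w| off-diagonal entries as a sparse signed network.

    Exactly one of ``n_edges`` / ``n_connected_genes`` must be given; the
    latter lowers the threshold until the number of non-isolated genes first
    reaches the target.
    """
    if (n_edges is None) == (n_connected_genes is None):
        raise EvaluationError("specify exactly one of n_edges / n_connected_genes")
    res = w if isinstance(w, GRNResults) else None
    w = _weight_matrix(w)
    n = w.shape[0]
    names = gene_names or (res.gene_names if res else [f"G{k:03d}" for k in range(n)])
    off = ~np.eye(n, dtype=bool)
    entries = sorted(
        ((abs(w[i, j]), i, j) for i in range(n) for j in range(n) if i != j and w[i, j] != 0),
        reverse=True,
    )
    if n_edges is not None:
        if n_edges > len(entries):
            raise EvaluationError(
                f"cannot keep {n_edges} edges: only {len(entries)} nonzero weights"
            )
        kept = entries[:n_edges]
    else:
        if n_connected_genes > n:
            raise EvaluationError("target gene count exceeds network size")
        kept = []
        connected: set[int] = set()
        for k, (_mag, i, j) in enumerate(entries):
            kept.append(entries[k])
            connected |= {i, j}
            if len(connected) >= n_connected_genes:
                break
        else:
            if len(connected) < n_connected_genes:
                raise EvaluationError(
                    f"cannot connect {n_connected_genes} genes with the "
                    f"available nonzero weights"
                )
    edges = {
        (names[j], names[i], 1 if w[i, j] > 0 else -1) for _mag, i, j in kept
    }
    return SignedNetwork(gene_names=list(names), edges=edges)


def compare_auc_distributions(a, b) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two AUC samples.

    Exact null distribution for samples of at most 10 each, normal
    approximation otherwise.  Returns ``(statistic, two-sided p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise EvaluationError("need at least 3 AUC values per group")
    method = "exact" if max(a.size, b.size) <= 10 else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# benchmark orchestration


PROCEDURES = (
    "SOO",
    "DSp",
    "MOO-dSp",
    "MOO-Tr",
    "MOO-Sr",
    "MOO-Tc",
    "MOO-Sc",
    "MOO-(Tr+Sr)",
    "MOO-T_ens",
    "MOO-S_ens",
)


@dataclass
class BenchmarkConfig:
    """Study conditions for a benchmark run (defaults = standard protocol)."""

    size: int = 20
    n_networks: int = 10
    procedures: tuple = PROCEDURES
    seed: int = 0
    source_size: int = 150
    avg_degree: float = 2.0
    activation_fraction: float = 0.6
    n_timepoints: int = 26
    t_max: float = 200.0
    replicates: int = 3
    noise_level: float = 0.05
    n_interp_points: int = 200
    max_delay: int = 20
    t_o: int = 1
    ko_coverage: float = 1.0
    ratio_convention: str = "log"
    corr_method: str = "pearson"
    sqe_slack: float = 0.05
    tolerance: float = 1e-6
    kinetic_mode: str = "hill"

    def __post_init__(self) -> None:
        unknown = set(self.procedures) - set(PROCEDURES)
        if unknown:
            raise ValueError(f"unknown procedures: {sorted(unknown)}")
        if self.n_networks < 1 or self.size < 2:
            raise ValueError("need size >= 2 and n_networks >= 1")


@dataclass
class BenchmarkResult:
    """Tidy per-(network, procedure, mode) AUC table plus config."""

    table: pd.DataFrame
    config: BenchmarkConfig
    fits: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Median and mean AUC per procedure and evaluation mode."""
        return (
            self.table.groupby(["procedure", "mode"])["auc"]
            .agg(["median", "mean", "std"])
            .reset_index()
        )

    def aucs(self, procedure: str, mode: str) -> np.ndarray:
        t = self.table
        sel = (t.procedure == procedure) & (t["mode"] == mode)
        return t.loc[sel].sort_values("network_id")["auc"].to_numpy()

    def save(self, prefix: str) -> None:
        import json
        from dataclasses import asdict

        self.table.to_csv(prefix + "_auc.tsv", sep="\t", index=False)
        with open(prefix + "_config.json", "w") as fh:
            cfg = asdict(self.config)
            cfg["procedures"] = list(cfg["procedures"])
            json.dump(cfg, fh, indent=1)

    def plot(self, mode: str = "undirected", path: str | None = None):
        """Boxplots of the AUC distribution per procedure."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        procs = [p for p in self.config.procedures]
        data = [self.aucs(p, mode) for p in procs]
        fig, ax = plt.subplots(figsize=(1.2 * len(procs) + 2, 4))
        ax.boxplot(data, tick_labels=procs)
        ax.set_ylabel(f"AUC ({mode})")
        ax.set_title(f"{self.config.size}-gene networks (n={self.config.n_networks})")
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def _fit_procedures(cfg: BenchmarkConfig, series, panels, rng) -> dict[str, GRNResults]:
    """Run every requested inference procedure on one benchmark instance."""
    need = set(cfg.procedures)
    if "MOO-T_ens" in need:
        need |= {"MOO-Tr", "MOO-Tc"}
    if "MOO-S_ens" in need:
        need |= {"MOO-Sr", "MOO-Sc"}

    terms: dict[str, object] = {}
    if need & {"DSp", "MOO-dSp"}:
        _dres, terms["DSp"] = delayed_spearman_objective(
            series, max_delay=cfg.max_delay, t_o=cfg.t_o
        )
    t_p = None
    if need & {"MOO-Tr", "MOO-Tc", "MOO-(Tr+Sr)"}:
        t_p = select_tp(panels["timecourse"], series)
        terms["Tr"] = ratio_objective(
            panels["timecourse"], at=t_p, sign_convention=cfg.ratio_convention
        )
        terms["Tc"] = correlation_objective(
            panels["timecourse"], at=t_p, method=cfg.corr_method
        )
    if need & {"MOO-Sr", "MOO-Sc", "MOO-(Tr+Sr)"}:
        terms["Sr"] = ratio_objective(
            panels["steady"], at="steady", sign_convention=cfg.ratio_convention
        )
        terms["Sc"] = correlation_objective(
            panels["steady"], at="steady", method=cfg.corr_method
        )

    def moo(term_labels: list[str]) -> GRNResults:
        model = GRNModel(
            series,
            terms=[terms[lbl] for lbl in term_labels],
            sqe_slack=cfg.sqe_slack,
            tolerance=cfg.tolerance,
        )
        return model.fit(method="moo", seed=int(rng.integers(2**31)))

    fits: dict[str, GRNResults] = {}
    for proc in cfg.procedures:
        if proc == "SOO":
            fits[proc] = soo_fit(
                series, tolerance=cfg.tolerance, init_seed=int(rng.integers(2**31))
            )
        elif proc == "DSp":
            # score the filtered delayed-correlation matrix itself
            term = terms["DSp"]
            fits[proc] = GRNResults(
                w=term.O, b=np.zeros(series.n_genes),
                gene_names=list(series.gene_names), role="matrix:DSp",
            )
        elif proc == "MOO-dSp":
            fits[proc] = moo(["DSp"])
        elif proc == "MOO-Tr":
            fits[proc] = moo(["Tr"])
        elif proc == "MOO-Sr":
            fits[proc] = moo(["Sr"])
        elif proc == "MOO-Tc":
            fits[proc] = moo(["Tc"])
        elif proc == "MOO-Sc":
            fits[proc] = moo(["Sc"])
        elif proc == "MOO-(Tr+Sr)":
            fits[proc] = moo(["Tr", "Sr"])
        elif proc == "MOO-T_ens":
            fits[proc] = ensemble_combine(
                fits.get("MOO-Tr") or moo(["Tr"]), fits.get("MOO-Tc") or moo(["Tc"])
            )
        elif proc == "MOO-S_ens":
            fits[proc] = ensemble_combine(
                fits.get("MOO-Sr") or moo(["Sr"]), fits.get("MOO-Sc") or moo(["Sc"])
            )
    return fits


def make_benchmark_instance(cfg: BenchmarkConfig, network_id: int):
    """Generate one benchmark instance: truth network, data, interpolation.

    Returns ``(truth, series, panels)`` where ``panels`` holds the knockout
    compendia actually needed by the configured procedures.
    """
    root = np.random.SeedSequence([cfg.seed, network_id])
    seeds = root.generate_state(8) % (2**31)
    source = generate_source_topology(
        cfg.source_size, cfg.avg_degree, cfg.activation_fraction, seed=int(seeds[0])
    )
    truth = extract_subnetwork(source, cfg.size, seed=int(seeds[1]))
    model = sample_kinetics(truth, seed=int(seeds[2]), mode=cfg.kinetic_mode)
    tc = simulate_timecourse(
        model,
        n_timepoints=cfg.n_timepoints,
        t_max=cfg.t_max,
        replicates=cfg.replicates,
        noise_level=cfg.noise_level,
        seed=int(seeds[3]),
    )
    series = interpolate_timecourse(
        average_replicates(tc), n_points=cfg.n_interp_points
    )

    need = set(cfg.procedures)
    if "MOO-S_ens" in need:
        need |= {"MOO-Sr", "MOO-Sc"}
    if "MOO-T_ens" in need:
        need |= {"MOO-Tr", "MOO-Tc"}
    panels = {}
    if need & {"MOO-Sr", "MOO-Sc", "MOO-(Tr+Sr)"}:
        panels["steady"] = simulate_knockout_compendium(
            model, mode="steady", coverage=cfg.ko_coverage,
            noise_level=cfg.noise_level, seed=int(seeds[4]),
        )
    if need & {"MOO-Tr", "MOO-Tc", "MOO-(Tr+Sr)"}:
        panels["timecourse"] = simulate_knockout_compendium(
            model, mode="timecourse", coverage=cfg.ko_coverage,
            noise_level=cfg.noise_level, seed=int(seeds[5]),
            n_timepoints=cfg.n_timepoints, t_max=cfg.t_max,
        )
    return truth, series, panels, int(seeds[6])


def run_benchmark(cfg: BenchmarkConfig, keep_fits: bool = False) -> BenchmarkResult:
    """Run the full pipeline over ``n_networks`` independent instances.

    Emits one row per (network, procedure, evaluation mode); fully seeded
    and reproducible from ``cfg.seed``.
    """
    rows = []
    all_fits = {}
    for k in range(cfg.n_networks):
        truth, series, panels, fit_seed = make_benchmark_instance(cfg, k)
        rng = np.random.default_rng(fit_seed)
        fits = _fit_procedures(cfg, series, panels, rng)
        if keep_fits:
            all_fits[k] = {"truth": truth, "fits": fits}
        for proc, res in fits.items():
            rows.append(
                dict(network_id=k, size=cfg.size, procedure=proc,
                     mode="undirected", auc=auc_undirected(res, truth),
                     seed=cfg.seed)
            )
            rows.append(
                dict(network_id=k, size=cfg.size, procedure=proc,
                     mode="directed-signed", auc=auc_directed_signed(res, truth),
                     seed=cfg.seed)
            )
    table = pd.DataFrame(rows)
    return BenchmarkResult(table=table, config=cfg, fits=all_fits)
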
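"""Relaxed-clock rate priors and the (ages, rates) -> branch-length map.

Two relaxed clocks are supported:

* **GBM** (geometric Brownian motion, autocorrelated): log node rates
  evolve by Brownian motion along the tree, so a child's log rate is
  normal around its parent's with variance sigma^2 * dt, where dt is the
  midpoint-to-midpoint time separation of the two branches.  The mean is
  shifted by -sigma^2 dt / 2 so that E[r_child | r_parent] = r_parent.
* **ILN** (independent log-normal): each branch rate is an iid
  log-normal draw with E[r_b] = mu_r and log-variance sigma^2.

Rates are in substitutions/site per 100 Myr.  ``expected_branch_lengths``
maps ages and rates to expected substitutions/site per branch: r_b * dt
for ILN and the arithmetic mean of the endpoint node rates times dt for
GBM.  Branches follow the tree's canonical post-order
(:meth:`TimeTree.canonical_branches`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import TimeTree, TreeError

__all__ = [
    "ClockConfig",
    "gbm_log_prior",
    "iln_log_prior",
    "expected_branch_lengths",
    "node_midpoint_separations",
]

LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class ClockConfig:
    """Per-locus clock configuration.

    ``mu_r`` is the locus mean rate (substitutions/site/100 Myr);
    ``sigma2`` the rate variance — per 100 Myr for GBM, a dimensionless
    log-variance for ILN.
    """

    model: str = "ILN"
    mu_r: float = 0.05
    sigma2: float = 0.1

    def __post_init__(self):
        if self.model not in ("ILN", "GBM"):
            raise ValueError(f"unknown clock model {self.model!r}")
        if self.mu_r <= 0:
            raise ValueError("mu_r must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")


def _lognormal_logpdf(x, mean_log, var_log):
    """Log density of LogNormal evaluated at x (var_log > 0)."""
    x = np.asarray(x, float)
    return -np.log(x) - 0.5 * (LOG_2PI + np.log(var_log)) - (np.log(x) - mean_log) ** 2 / (
        2.0 * var_log
    )


def node_midpoint_separations(tree: TimeTree) -> np.ndarray:
    """Midpoint-to-midpoint time separation between each node and its parent.

    The "position" of a non-root node is the midpoint of the branch above
    it; the root sits at its own age.  Separations are in 100-Myr units;
    entry for the root is nan.
    """
    mid = np.empty(tree.n_nodes)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        mid[v] = tree.ages[v] if p < 0 else 0.5 * (tree.ages[p] + tree.ages[v])
    sep = np.full(tree.n_nodes, np.nan)
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0:
            sep[v] = mid[p] - mid[v]
    return sep


def gbm_log_prior(node_rates: np.ndarray, tree: TimeTree, cfg: ClockConfig) -> float:
    """Log prior of per-node rates under the autocorrelated (GBM) clock.

    ``node_rates[v]`` is the rate at node v (all tree nodes, root
    included; the root rate itself is priced by the locus-rate
    hyperprior, not here).  With sigma2 == 0 the clock is strict: any
    deviation from the root rate has -inf density.
    """
    node_rates = np.asarray(node_rates, float)
    if node_rates.shape != (tree.n_nodes,):
        raise ValueError("node_rates must have one entry per tree node")
    if np.any(node_rates <= 0) or not np.all(np.isfinite(node_rates)):
        return -np.inf
    sep = node_midpoint_separations(tree)
    total = 0.0
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        var = cfg.sigma2 * sep[v]
        if var <= 0.0:
            # degenerate: point mass at the parent rate
            if not np.isclose(node_rates[v], node_rates[p]):
                return -np.inf
            continue
        mean_log = np.log(node_rates[p]) - var / 2.0
        total += float(_lognormal_logpdf(node_rates[v], mean_log, var))
    return total


def iln_log_prior(branch_rates: np.ndarray, cfg: ClockConfig) -> float:
    """Log prior of branch rates under the independent log-normal clock."""
    branch_rates = np.asarray(branch_rates, float)
    if np.any(branch_rates <= 0) or not np.all(np.isfinite(branch_rates)):
        return -np.inf
    if cfg.sigma2 == 0.0:
        return 0.0 if np.allclose(branch_rates, cfg.mu_r) else -np.inf
    mean_log = np.log(cfg.mu_r) - cfg.sigma2 / 2.0
    return float(np.sum(_lognormal_logpdf(branch_rates, mean_log, cfg.sigma2)))


def expected_branch_lengths(
    tree: TimeTree, rates: np.ndarray, cfg: ClockConfig
) -> np.ndarray:
    """Expected substitutions/site per branch, in canonical branch order.

    ILN: ``rates`` has one entry per branch (canonical order); b = r * dt.
    GBM: ``rates`` has one entry per node; b = (r_parent + r_child)/2 * dt.
    """
    order = tree.canonical_branches()
    dt = tree.branch_durations()
    if np.any(dt[order] < -1e-12):
        raise TreeError("negative branch duration: ages violate parent > child")
    dt = np.maximum(dt, 0.0)
    rates = np.asarray(rates, float)
    if cfg.model == "ILN":
        if rates.shape != (len(order),):
            raise ValueError("ILN rates must have one entry per branch")
        return rates * dt[order]
    if rates.shape != (tree.n_nodes,):
        raise ValueError("GBM rates must have one entry per node")
    b = np.empty(len(order))
    for k, v in enumerate(order):
        b[k] = 0.5 * (rates[tree.parent[v]] + rates[v]) * dt[v]
    return b
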
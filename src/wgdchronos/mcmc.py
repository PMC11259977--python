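"""Metropolis–Hastings sampler for node ages, rates and hyperparameters.

The posterior combines, on a fixed duplicated topology:

* fossil-calibration densities on calibrated nodes (the root must carry
  one, since the birth–death kernel conditions on the root age),
* the birth–death-with-sampling kernel on uncalibrated internal nodes,
* a relaxed-clock prior (GBM or ILN) on per-locus rates,
* gamma hyperpriors on per-locus mean rates and sigma^2, and
* one quadratic (normal-approximation) likelihood per locus.

Proposals: per-node sliding-window age moves respecting parent/child
order, per-branch (ILN) or per-node (GBM) multiplicative rate moves
vectorized across loci, multiplicative hyperparameter moves, and a
whole-tree "mixing" move (ages x c, rates / c) whose Jacobian keeps the
chain correct.  Step sizes are tuned toward 20–40% acceptance during
burn-in and then frozen, preserving detailed balance in the sampling
phase.  A single integer seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy.stats import linregress

from . import clocks as _clocks
from .likelihood import BranchLengthApprox
from .priors import (
    BirthDeathPrior,
    RateHyperpriors,
    bd_kernel_log_density,
    calibration_log_density,
    calibration_quantile,
    hyperprior_log_density,
)
from .treeio import MA_PER_UNIT, TimeTree

__all__ = [
    "ChainState",
    "PosteriorSamples",
    "run_chain",
    "run_duplicate_chains",
    "summarize_posterior",
    "check_convergence",
    "hpd_interval",
    "log_posterior",
]

LOG_2PI = np.log(2.0 * np.pi)


def node_name(tree: TimeTree, v: int) -> str:
    """Stable display name for an internal node."""
    if tree.labels[v]:
        return tree.labels[v]
    cl = tree.clade_leafset(v)
    return f"{min(cl)}+{len(cl)}"


@dataclass
class ChainState:
    """Snapshot of all sampled parameters (internal 100-Myr units).

    ``rates`` is (n_loci, n_branches) for ILN, (n_loci, n_nodes) for GBM
    (entry per node, root included).  ``log_posterior`` caches the value
    at this state; :func:`log_posterior` recomputes it from scratch.
    """

    ages: np.ndarray
    rates: np.ndarray
    mu: np.ndarray
    sigma2: np.ndarray
    log_posterior: float = np.nan


@dataclass
class PosteriorSamples:
    """Thinned posterior draws plus sampler metadata."""

    node_ids: list[int]
    node_labels: list[str]
    draws: dict[str, np.ndarray]
    seed: int
    settings: dict = field(default_factory=dict)
    acceptance: dict = field(default_factory=dict)
    final_state: ChainState | None = None

    @property
    def n_draws(self) -> int:
        return len(self.draws["logpost"])

    def ages_Ma(self) -> np.ndarray:
        return self.draws["ages"] * MA_PER_UNIT

    def parameter_table(self) -> pd.DataFrame:
        """All scalar parameter traces as one tidy table (ages in Ma)."""
        cols = {"logpost": self.draws["logpost"]}
        for j, lab in enumerate(self.node_labels):
            cols[f"t_{lab}"] = self.draws["ages"][:, j] * MA_PER_UNIT
        for j in range(self.draws["mu"].shape[1]):
            cols[f"mu_{j}"] = self.draws["mu"][:, j]
        for j in range(self.draws["sigma2"].shape[1]):
            cols[f"sigma2_{j}"] = self.draws["sigma2"][:, j]
        return pd.DataFrame(cols)

    def write_trace(self, path) -> None:
        df = self.parameter_table()
        df.insert(0, "iteration", np.arange(len(df)))
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Posterior evaluation
# ---------------------------------------------------------------------------

def _stack_loci(loci: list[BranchLengthApprox], expected_names: list[str]):
    if not loci:
        nb = len(expected_names)
        return np.zeros((0, nb)), np.zeros((0, nb)), np.zeros((0, nb, nb))
    for ap in loci:
        if ap.branch_names != expected_names:
            bad = next(
                (a, b) for a, b in zip(ap.branch_names, expected_names) if a != b
            )
            raise ValueError(
                f"locus {ap.locus_id}: branch ordering does not match the dating "
                f"tree (first mismatch {bad[0]!r} vs {bad[1]!r})"
            )
    return (
        np.stack([ap.bhat for ap in loci]),
        np.stack([ap.grad for ap in loci]),
        np.stack([ap.hessian for ap in loci]),
    )


class _Model:
    """Precomputed structure + vectorized posterior pieces."""

    def __init__(self, tree, loci, clock_model, hp, bd):
        if not tree.is_binary():
            raise ValueError("dating tree must be binary")
        self.tree = tree
        self.clock_model = clock_model
        self.hp, self.bd = hp, bd
        self.order = tree.canonical_branches()
        self.branch_names = [tree.branch_name(v) for v in self.order]
        self.parent = tree.parent
        self.root = tree.root
        self.internal = tree.internal_ids()
        self.n_nodes = tree.n_nodes
        self.nb = len(self.order)
        self.order_arr = np.array(self.order)
        self.par_of_branch = self.parent[self.order_arr]
        self.leaf_mask = np.array([tree.is_leaf(v) for v in range(self.n_nodes)])
        if self.root not in tree.calibrations:
            raise ValueError("the root must carry a calibration")
        self.calibrated = sorted(tree.calibrations)
        self.uncalibrated = [v for v in self.internal if v not in tree.calibrations]
        self.Bhat, self.G, self.H = _stack_loci(loci, self.branch_names)
        self.L = self.Bhat.shape[0]
        # non-root nodes and their parents, for the GBM prior
        self.nonroot = np.array([v for v in range(self.n_nodes) if v != self.root])
        self.nonroot_parent = self.parent[self.nonroot]

    # -- pieces -------------------------------------------------------------

    def durations(self, ages):
        return ages[self.par_of_branch] - ages[self.order_arr]

    def branch_lengths(self, ages, rates):
        dt = self.durations(ages)
        if self.clock_model == "ILN":
            return rates * dt[None, :]
        rsum = rates[:, self.par_of_branch] + rates[:, self.order_arr]
        return 0.5 * rsum * dt[None, :]

    def loglik(self, B):
        if self.L == 0:
            return np.zeros(0)
        d = B - self.Bhat
        return np.einsum("lk,lk->l", self.G, d) + 0.5 * np.einsum(
            "lj,ljk,lk->l", d, self.H, d
        )

    def age_logprior(self, ages):
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and ages[v] >= ages[p]:
                return -np.inf
        total = 0.0
        for v in self.calibrated:
            total += calibration_log_density(ages[v], self.tree.calibrations[v])
        if self.uncalibrated:
            t = ages[self.uncalibrated]
            troot = ages[self.root]
            if np.any(t <= 0) or np.any(t >= troot):
                return -np.inf
            total += float(np.sum(bd_kernel_log_density(t, troot, self.bd)))
        return float(total)

    def clock_logprior(self, ages, rates, mu, sigma2):
        """Per-locus clock-prior vector (length L)."""
        if self.L == 0:
            return np.zeros(0)
        if self.clock_model == "ILN":
            s2 = sigma2[:, None]
            mean_log = np.log(mu)[:, None] - s2 / 2.0
            x = np.log(rates)
            terms = -x - 0.5 * (LOG_2PI + np.log(s2)) - (x - mean_log) ** 2 / (2 * s2)
            return terms.sum(axis=1)
        # GBM: midpoint separations depend on ages
        mid = np.where(
            self.parent >= 0, 0.5 * (ages[np.maximum(self.parent, 0)] + ages), ages
        )
        sep = mid[self.nonroot_parent] - mid[self.nonroot]  # > 0 on a valid tree
        var = sigma2[:, None] * sep[None, :]
        x = np.log(rates[:, self.nonroot])
        m = np.log(rates[:, self.nonroot_parent]) - var / 2.0
        terms = -x - 0.5 * (LOG_2PI + np.log(var)) - (x - m) ** 2 / (2 * var)
        return terms.sum(axis=1)

    def hyper_logprior(self, rates, mu, sigma2):
        if self.L == 0:
            return np.zeros(0)
        if self.clock_model == "ILN":
            lr = hyperprior_log_density(mu, "locus_rate", self.hp)
        else:  # GBM: the root node rate plays the locus-rate role
            lr = hyperprior_log_density(rates[:, self.root], "locus_rate", self.hp)
        return np.asarray(lr) + np.asarray(
            hyperprior_log_density(sigma2, "sigma2", self.hp)
        )

    def logpost(self, st: ChainState) -> float:
        age_lp = self.age_logprior(st.ages)
        if not np.isfinite(age_lp):
            return -np.inf
        B = self.branch_lengths(st.ages, st.rates)
        return float(
            age_lp
            + self.loglik(B).sum()
            + self.clock_logprior(st.ages, st.rates, st.mu, st.sigma2).sum()
            + self.hyper_logprior(st.rates, st.mu, st.sigma2).sum()
        )


def log_posterior(
    tree: TimeTree,
    loci: list[BranchLengthApprox],
    state: ChainState,
    clock_model: str = "ILN",
    hyperpriors: RateHyperpriors = RateHyperpriors(),
    bd: BirthDeathPrior = BirthDeathPrior(),
) -> float:
    """Recompute the full log posterior of a chain state from scratch."""
    return _Model(tree, loci, clock_model, hyperpriors, bd).logpost(state)


# ---------------------------------------------------------------------------
# Sampler
# ---------------------------------------------------------------------------

def _initial_state(model: _Model, rng) -> ChainState:
    tree = model.tree
    ages = np.zeros(model.n_nodes)
    root_cal = tree.calibrations[model.root]
    ages[model.root] = calibration_quantile(0.5, root_cal)
    for v in tree.preorder():
        if v == model.root or tree.is_leaf(v):
            continue
        t = 0.82 * ages[tree.parent[v]]
        cal = tree.calibrations.get(v)
        if cal is not None:
            t = min(max(t, cal.t_L * 1.01), cal.t_U)
        ages[v] = min(t, 0.97 * ages[tree.parent[v]])
    # auto-repair any residual order violation
    for v in tree.preorder():
        p = tree.parent[v]
        if p >= 0 and not tree.is_leaf(v) and ages[v] >= ages[p]:
            ages[v] = 0.95 * ages[p]
    mu0 = model.hp.alpha_r / model.hp.beta_r
    s20 = model.hp.alpha_sigma / model.hp.beta_sigma
    n_rate_cols = model.nb if model.clock_model == "ILN" else model.n_nodes
    rates = np.full((model.L, n_rate_cols), mu0)
    mu = np.full(model.L, mu0)
    sigma2 = np.full(model.L, s20)
    return ChainState(ages, rates, mu, sigma2)


class _StepSizes:
    def __init__(self, model: _Model, t_root: float):
        self.age = np.full(model.n_nodes, 0.08 * t_root)
        n_rate_moves = model.nb if model.clock_model == "ILN" else model.n_nodes
        self.rate = np.full(n_rate_moves, 0.5)
        self.mu = 0.3
        self.sigma2 = 0.6
        self.mix = 0.15


def _tune(step, acc_rate, lo=0.2, hi=0.4):
    if acc_rate < lo:
        return step * np.exp(np.clip(acc_rate - 0.3, -0.3, 0.0) * 2.0)
    if acc_rate > hi:
        return step * np.exp(np.clip(acc_rate - 0.3, 0.0, 0.7) * 2.0)
    return step


def run_chain(
    tree: TimeTree,
    loci: list[BranchLengthApprox],
    clock_model: str = "ILN",
    hyperpriors: RateHyperpriors = RateHyperpriors(),
    bd: BirthDeathPrior = BirthDeathPrior(),
    n_iter: int = 20000,
    burn_in: float | int = 0.25,
    thin: int | None = None,
    seed: int = 0,
    tune_interval: int = 100,
    max_draws: int = 10000,
    store_rates: bool = False,
) -> PosteriorSamples:
    """Sample the dating posterior; see the module docstring for the model.

    ``n_iter`` counts sweeps (one sweep updates every age, every rate
    block, the hyperparameters, and proposes one mixing move).
    ``burn_in`` is a fraction of ``n_iter`` (if < 1) or a sweep count;
    ``thin`` defaults to whatever keeps at most ``max_draws`` retained
    draws.  An empty ``loci`` list samples the effective prior (the
    calibrations + tree prior only), which is the standard sampler
    correctness check.
    """
    if clock_model not in ("ILN", "GBM"):
        raise ValueError(f"unknown clock model {clock_model!r}")
    model = _Model(tree, loci, clock_model, hyperpriors, bd)
    rng = np.random.default_rng(seed)
    st = _initial_state(model, rng)
    if not np.isfinite(model.logpost(st)):
        raise RuntimeError("could not construct a valid initial state")

    n_burn = int(burn_in * n_iter) if isinstance(burn_in, float) and burn_in < 1 else int(burn_in)
    if thin is None:
        thin = max(1, (n_iter - n_burn) // max_draws)

    L, nb = model.L, model.nb
    internal = model.internal
    steps = _StepSizes(model, st.ages[model.root])

    # caches
    age_lp = model.age_logprior(st.ages)
    B = model.branch_lengths(st.ages, st.rates)
    lik = model.loglik(B)
    clock_lp = model.clock_logprior(st.ages, st.rates, st.mu, st.sigma2)
    hyper_lp = model.hyper_logprior(st.rates, st.mu, st.sigma2)

    n_rate_moves = nb if clock_model == "ILN" else model.n_nodes
    acc = {
        "age": np.zeros(model.n_nodes),
        "age_n": np.zeros(model.n_nodes),
        "rate": np.zeros(n_rate_moves),
        "rate_n": np.zeros(n_rate_moves),
        "mu": 0.0,
        "mu_n": 0.0,
        "sigma2": 0.0,
        "sigma2_n": 0.0,
        "mix": 0.0,
        "mix_n": 0.0,
    }

    children_arr = model.tree.children
    kept_ages, kept_mu, kept_s2, kept_lp, kept_rates = [], [], [], [], []

    n_rate_params = st.rates.size + (L if clock_model == "ILN" else 0)
    n_free_ages = len(internal)

    def total_lp():
        return age_lp + lik.sum() + clock_lp.sum() + hyper_lp.sum()

    for sweep in range(n_iter):
        # ---- age moves ----------------------------------------------------
        for v in internal:
            t_old = st.ages[v]
            t_new = t_old + steps.age[v] * (2.0 * rng.random() - 1.0)
            acc["age_n"][v] += 1
            lo = max((st.ages[c] for c in children_arr[v]), default=0.0)
            hi = st.ages[model.parent[v]] if model.parent[v] >= 0 else np.inf
            if not (lo < t_new < hi):
                continue
            st.ages[v] = t_new
            new_age_lp = model.age_logprior(st.ages)
            if not np.isfinite(new_age_lp):
                st.ages[v] = t_old
                continue
            newB = model.branch_lengths(st.ages, st.rates)
            new_lik = model.loglik(newB)
            if clock_model == "GBM":
                new_clock = model.clock_logprior(st.ages, st.rates, st.mu, st.sigma2)
            else:
                new_clock = clock_lp
            delta = (
                (new_age_lp - age_lp)
                + (new_lik.sum() - lik.sum())
                + (new_clock.sum() - clock_lp.sum())
            )
            if np.log(rng.random()) < delta:
                age_lp, B, lik, clock_lp = new_age_lp, newB, new_lik, new_clock
                acc["age"][v] += 1
            else:
                st.ages[v] = t_old

        # ---- rate moves (vectorized across loci) --------------------------
        if L:
            for k in range(n_rate_moves):
                f = np.exp(steps.rate[k] * (2.0 * rng.random(L) - 1.0))
                new_rates = st.rates.copy()
                new_rates[:, k] *= f
                newB = model.branch_lengths(st.ages, new_rates)
                new_lik = model.loglik(newB)
                new_clock = model.clock_logprior(st.ages, new_rates, st.mu, st.sigma2)
                new_hyper = (
                    model.hyper_logprior(new_rates, st.mu, st.sigma2)
                    if clock_model == "GBM" and k == model.root
                    else hyper_lp
                )
                # log-scale random walk: Jacobian contributes +log f per locus
                delta = (
                    (new_lik - lik)
                    + (new_clock - clock_lp)
                    + (new_hyper - hyper_lp)
                    + np.log(f)
                )
                accepted = np.log(rng.random(L)) < delta
                if np.any(accepted):
                    st.rates[accepted, k] = new_rates[accepted, k]
                    B = model.branch_lengths(st.ages, st.rates)
                    lik = np.where(accepted, new_lik, lik)
                    clock_lp = np.where(accepted, new_clock, clock_lp)
                    hyper_lp = np.where(accepted, new_hyper, hyper_lp)
                acc["rate"][k] += accepted.mean()
                acc["rate_n"][k] += 1

            # ---- hyperparameter moves -------------------------------------
            if clock_model == "ILN":
                f = np.exp(steps.mu * (2.0 * rng.random(L) - 1.0))
                new_mu = st.mu * f
                new_clock = model.clock_logprior(st.ages, st.rates, new_mu, st.sigma2)
                new_hyper = model.hyper_logprior(st.rates, new_mu, st.sigma2)
                delta = (new_clock - clock_lp) + (new_hyper - hyper_lp) + np.log(f)
                accepted = np.log(rng.random(L)) < delta
                st.mu = np.where(accepted, new_mu, st.mu)
                clock_lp = np.where(accepted, new_clock, clock_lp)
                hyper_lp = np.where(accepted, new_hyper, hyper_lp)
                acc["mu"] += accepted.mean()
                acc["mu_n"] += 1

            f = np.exp(steps.sigma2 * (2.0 * rng.random(L) - 1.0))
            new_s2 = st.sigma2 * f
            new_clock = model.clock_logprior(st.ages, st.rates, st.mu, new_s2)
            new_hyper = model.hyper_logprior(st.rates, st.mu, new_s2)
            delta = (new_clock - clock_lp) + (new_hyper - hyper_lp) + np.log(f)
            accepted = np.log(rng.random(L)) < delta
            st.sigma2 = np.where(accepted, new_s2, st.sigma2)
            clock_lp = np.where(accepted, new_clock, clock_lp)
            hyper_lp = np.where(accepted, new_hyper, hyper_lp)
            acc["sigma2"] += accepted.mean()
            acc["sigma2_n"] += 1

        # ---- mixing move (ages x c, rates / c) ----------------------------
        c = np.exp(steps.mix * (2.0 * rng.random() - 1.0))
        cand = ChainState(st.ages * c, st.rates / c, st.mu / c, st.sigma2)
        new_age_lp = model.age_logprior(cand.ages)
        acc["mix_n"] += 1
        if np.isfinite(new_age_lp):
            newB = model.branch_lengths(cand.ages, cand.rates)
            new_lik = model.loglik(newB)
            new_clock = model.clock_logprior(cand.ages, cand.rates, cand.mu, cand.sigma2)
            new_hyper = model.hyper_logprior(cand.rates, cand.mu, cand.sigma2)
            delta = (
                (new_age_lp - age_lp)
                + (new_lik.sum() - lik.sum())
                + (new_clock.sum() - clock_lp.sum())
                + (new_hyper.sum() - hyper_lp.sum())
                + (n_free_ages - n_rate_params) * np.log(c)
            )
            if np.log(rng.random()) < delta:
                st = cand
                age_lp, B, lik = new_age_lp, newB, new_lik
                clock_lp, hyper_lp = new_clock, new_hyper
                acc["mix"] += 1

        # ---- tuning during burn-in ----------------------------------------
        if sweep < n_burn and (sweep + 1) % tune_interval == 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(acc["age_n"] > 0, acc["age"] / np.maximum(acc["age_n"], 1), 0.3)
                steps.age = np.array([_tune(s, a) for s, a in zip(steps.age, r)])
                if L:
                    r = acc["rate"] / np.maximum(acc["rate_n"], 1)
                    steps.rate = np.array([_tune(s, a) for s, a in zip(steps.rate, r)])
                    if clock_model == "ILN" and acc["mu_n"]:
                        steps.mu = _tune(steps.mu, acc["mu"] / acc["mu_n"])
                    if acc["sigma2_n"]:
                        steps.sigma2 = _tune(steps.sigma2, acc["sigma2"] / acc["sigma2_n"])
                if acc["mix_n"]:
                    steps.mix = _tune(steps.mix, acc["mix"] / acc["mix_n"])
            for key in ("age", "age_n", "rate", "rate_n"):
                acc[key] = np.zeros_like(acc[key])
            for key in ("mu", "mu_n", "sigma2", "sigma2_n", "mix", "mix_n"):
                acc[key] = 0.0

        # ---- record --------------------------------------------------------
        if sweep >= n_burn and (sweep - n_burn) % thin == 0:
            kept_ages.append(st.ages[internal].copy())
            kept_mu.append(st.mu.copy())
            kept_s2.append(st.sigma2.copy())
            kept_lp.append(total_lp())
            if store_rates:
                kept_rates.append(st.rates.copy())

    st.log_posterior = float(total_lp())
    draws = {
        "ages": np.array(kept_ages),
        "mu": np.array(kept_mu).reshape(len(kept_mu), -1),
        "sigma2": np.array(kept_s2).reshape(len(kept_s2), -1),
        "logpost": np.array(kept_lp),
    }
    if store_rates:
        draws["rates"] = np.array(kept_rates)
    acc_summary = {
        "age": float(np.sum(acc["age"]) / max(np.sum(acc["age_n"]), 1)),
        "mix": float(acc["mix"] / max(acc["mix_n"], 1)),
    }
    if L:
        acc_summary["rate"] = float(np.mean(acc["rate"] / np.maximum(acc["rate_n"], 1)))
    return PosteriorSamples(
        node_ids=list(internal),
        node_labels=[node_name(tree, v) for v in internal],
        draws=draws,
        seed=seed,
        settings={
            "clock_model": clock_model,
            "n_iter": n_iter,
            "burn_in": n_burn,
            "thin": thin,
            "n_loci": L,
        },
        acceptance=acc_summary,
        final_state=st,
    )


def run_duplicate_chains(tree, loci, seeds=(1, 2), **kwargs):
    """Run two chains differing only in seed and report convergence."""
    a = run_chain(tree, loci, seed=seeds[0], **kwargs)
    b = run_chain(tree, loci, seed=seeds[1], **kwargs)
    return a, b, check_convergence(a, b)


# ---------------------------------------------------------------------------
# Summaries and diagnostics
# ---------------------------------------------------------------------------

def hpd_interval(x: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``mass`` of the draws (order-statistic
    method)."""
    x = np.sort(np.asarray(x, float))
    n = len(x)
    m = max(1, int(np.ceil(mass * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def _ess(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return float(len(x))
    with np.errstate(all="ignore"):
        e = float(az.ess(np.asarray(x)[None, :]))
    return e if np.isfinite(e) else float(len(x))


def summarize_posterior(
    samples: PosteriorSamples, mass: float = 0.95, min_draws: int = 100
) -> pd.DataFrame:
    """Per-node posterior mean, HPD bounds (Ma) and ESS."""
    if samples.n_draws < min_draws:
        raise ValueError(
            f"need at least {min_draws} post-burn-in draws, have {samples.n_draws}"
        )
    rows = []
    ages = samples.ages_Ma()
    for j, lab in enumerate(samples.node_labels):
        x = ages[:, j]
        lo, hi = hpd_interval(x, mass)
        rows.append(
            {
                "node": lab,
                "mean": float(x.mean()),
                "hpd_low": lo,
                "hpd_high": hi,
                "ess": _ess(x),
            }
        )
    return pd.DataFrame(rows)


def _split_rhat(a: np.ndarray, b: np.ndarray) -> float:
    """Classic split-R-hat from two chains (4 half-chains).

    Degenerate conventions: identical chains, or chains with zero
    within-chain variance, give exactly 1.
    """
    if np.array_equal(a, b):
        return 1.0
    n = min(len(a), len(b)) // 2
    if n < 2:
        return np.inf
    halves = np.array([a[:n], a[n : 2 * n], b[:n], b[n : 2 * n]])
    W = halves.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    Bv = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + Bv / n
    return float(np.sqrt(var_plus / W))


def check_convergence(
    run_a: PosteriorSamples,
    run_b: PosteriorSamples,
    rhat_tol: float = 1.01,
) -> pd.DataFrame:
    """Per-parameter split-R-hat and mean agreement between two runs.

    Flags parameters with R-hat above ``rhat_tol`` or with
    ``|mean_a - mean_b| > 0.5 * pooled standard error`` (SE from ESS).
    Also carries the mean-vs-mean regression (slope/intercept/r) of node
    ages as DataFrame attrs.
    """
    ta, tb = run_a.parameter_table(), run_b.parameter_table()
    if list(ta.columns) != list(tb.columns):
        raise ValueError("runs have mismatched parameter sets")
    rows = []
    for col in ta.columns:
        if col == "logpost":
            continue
        xa, xb = ta[col].to_numpy(), tb[col].to_numpy()
        rhat = _split_rhat(xa, xb)
        se = np.sqrt(xa.var(ddof=1) / _ess(xa) + xb.var(ddof=1) / _ess(xb))
        dmean = abs(xa.mean() - xb.mean())
        rows.append(
            {
                "parameter": col,
                "rhat": rhat,
                "mean_a": xa.mean(),
                "mean_b": xb.mean(),
                "flagged": bool(rhat > rhat_tol or (se > 0 and dmean > 0.5 * se)),
            }
        )
    report = pd.DataFrame(rows)
    age_cols = [c for c in ta.columns if c.startswith("t_")]
    if len(age_cols) >= 2:
        reg = linregress(tb[age_cols].mean().to_numpy(), ta[age_cols].mean().to_numpy())
        report.attrs["regression"] = {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "r": reg.rvalue,
        }
    return report
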
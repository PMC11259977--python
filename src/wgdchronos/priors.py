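"""Prior densities for node ages and rate hyperparameters.

Three ingredients make up the age prior of the dating model:

* **Fossil calibrations** with a hard minimum and a soft maximum: the
  density is uniform between the bounds and carries 97.5% of the mass
  there ("equal probability per unit time"), with zero mass below the
  hard minimum and a 2.5% tail above the soft maximum.  The tail is an
  exponential whose rate is chosen so the density is continuous at the
  soft maximum and integrates to exactly the tail mass.
* **A birth–death node-age kernel** for uncalibrated internal nodes,
  conditional on the root age, with incomplete species sampling
  (Yang–Rannala construction); defaults birth=1, death=1, sampling=0.1.
* **Gamma hyperpriors** on the per-locus mean rate ("rgene gamma") and
  on the rate-variance parameter sigma^2 of the relaxed clocks.

All ages here are in internal units of 100 Myr.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .treeio import MA_PER_UNIT, TimeTree

__all__ = [
    "Calibration",
    "BirthDeathPrior",
    "RateHyperpriors",
    "calibration_log_density",
    "calibration_cdf",
    "calibration_quantile",
    "birth_death_log_prior",
    "bd_kernel_log_density",
    "bd_kernel_cdf",
    "bd_kernel_quantile",
    "hyperprior_log_density",
    "read_calibration_table",
    "write_calibration_table",
    "attach_calibrations",
]

#: |birth - death| below which the critical (lambda = mu) closed form is used
BD_EQUAL_TOL = 1e-8


class ConfigurationError(ValueError):
    """Invalid prior configuration."""


# ---------------------------------------------------------------------------
# Fossil calibrations: hard minimum, uniform body, soft-maximum tail
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """Hard-minimum / soft-maximum age calibration (ages in 100 Myr).

    ``p_body`` of the mass is uniform on [t_L, t_U]; ``p_tail`` sits in an
    exponential tail above t_U whose rate theta = p_body / (p_tail (t_U - t_L))
    makes the density continuous at t_U.  Mass below t_L is exactly zero.
    """

    node_ref: str
    t_L: float
    t_U: float
    p_body: float = 0.975
    p_tail: float = 0.025

    def __post_init__(self):
        if not (0.0 <= self.t_L < self.t_U):
            raise ConfigurationError(
                f"calibration {self.node_ref!r}: need 0 <= t_L < t_U, "
                f"got ({self.t_L}, {self.t_U})"
            )
        if not np.isclose(self.p_body + self.p_tail, 1.0):
            raise ConfigurationError("p_body + p_tail must equal 1")

    @property
    def body_density(self) -> float:
        return self.p_body / (self.t_U - self.t_L)

    @property
    def tail_rate(self) -> float:
        return self.p_body / (self.p_tail * (self.t_U - self.t_L))


def calibration_log_density(t, cal: Calibration):
    """Log prior density of a calibrated node age (vectorized over ``t``)."""
    t = np.asarray(t, float)
    logd = np.full(t.shape, -np.inf)
    body = (t >= cal.t_L) & (t <= cal.t_U)
    logd[body] = np.log(cal.body_density)
    tail = t > cal.t_U
    logd[tail] = np.log(cal.body_density) - cal.tail_rate * (t[tail] - cal.t_U)
    return logd if logd.shape else float(logd)


def calibration_cdf(t, cal: Calibration):
    """Prior CDF: 0 at t_L, ``p_body`` at t_U, 1 at infinity."""
    t = np.asarray(t, float)
    c = np.zeros(t.shape)
    body = (t >= cal.t_L) & (t <= cal.t_U)
    c[body] = cal.p_body * (t[body] - cal.t_L) / (cal.t_U - cal.t_L)
    tail = t > cal.t_U
    c[tail] = cal.p_body + cal.p_tail * (1.0 - np.exp(-cal.tail_rate * (t[tail] - cal.t_U)))
    return c if c.shape else float(c)


def calibration_quantile(u, cal: Calibration):
    """Inverse CDF (closed form), for prior simulation."""
    u = np.asarray(u, float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("quantile argument outside [0, 1]")
    t = np.empty(u.shape)
    body = u <= cal.p_body
    t[body] = cal.t_L + (cal.t_U - cal.t_L) * u[body] / cal.p_body
    tail = ~body
    t[tail] = cal.t_U - np.log1p(-(u[tail] - cal.p_body) / cal.p_tail) / cal.tail_rate
    return t if t.shape else float(t)


# ---------------------------------------------------------------------------
# Birth–death node-age kernel with species sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BirthDeathPrior:
    """Birth–death process with sampling fraction, conditioning node ages."""

    birth: float = 1.0
    death: float = 1.0
    sampling: float = 0.1

    def __post_init__(self):
        if self.birth <= 0 or self.death <= 0:
            raise ConfigurationError("birth and death rates must be positive")
        if not (0.0 < self.sampling <= 1.0):
            raise ConfigurationError("sampling fraction must be in (0, 1]")


def _bd_v(t, bd: BirthDeathPrior):
    """Unnormalized kernel CDF v(t); v(t)/v(t_root) is the node-age CDF."""
    lam, mu, rho = bd.birth, bd.death, bd.sampling
    t = np.asarray(t, float)
    if abs(lam - mu) < BD_EQUAL_TOL:
        return rho * lam * t / (1.0 + rho * lam * t)
    e = np.exp((mu - lam) * t)
    p0 = rho * (lam - mu) / (rho * lam + (lam * (1 - rho) - mu) * e)
    return 1.0 - p0 * e / rho


def bd_kernel_log_density(t, t_root: float, bd: BirthDeathPrior):
    """Log density of one uncalibrated node age on (0, t_root)."""
    lam, mu, rho = bd.birth, bd.death, bd.sampling
    t = np.asarray(t, float)
    logd = np.full(t.shape, -np.inf)
    ok = (t > 0) & (t < t_root)
    tt = t[ok]
    if abs(lam - mu) < BD_EQUAL_TOL:
        g = (1.0 + rho * lam * t_root) / (t_root * (1.0 + rho * lam * tt) ** 2)
        logd[ok] = np.log(g)
    else:
        e = np.exp((mu - lam) * tt)
        p0 = rho * (lam - mu) / (rho * lam + (lam * (1 - rho) - mu) * e)
        p1 = p0**2 * e / rho
        v1 = _bd_v(t_root, bd)
        logd[ok] = np.log(lam * p1 / v1)
    return logd if logd.shape else float(logd)


def bd_kernel_cdf(t, t_root: float, bd: BirthDeathPrior):
    t = np.asarray(t, float)
    c = np.clip(_bd_v(np.clip(t, 0.0, t_root), bd) / _bd_v(t_root, bd), 0.0, 1.0)
    return c if c.shape else float(c)


def bd_kernel_quantile(u, t_root: float, bd: BirthDeathPrior):
    """Closed-form inverse of the kernel CDF, for simulation."""
    lam, mu, rho = bd.birth, bd.death, bd.sampling
    u = np.asarray(u, float)
    v = u * _bd_v(t_root, bd)
    if abs(lam - mu) < BD_EQUAL_TOL:
        t = v / (rho * lam * (1.0 - v))
    else:
        a, b = rho * lam, lam * (1 - rho) - mu
        y = a * (1.0 - v) / ((lam - mu) - b * (1.0 - v))
        t = np.log(y) / (mu - lam)
    return t if np.asarray(t).shape else float(t)


def birth_death_log_prior(ages, t_root: float, bd: BirthDeathPrior) -> float:
    """Joint log prior of uncalibrated internal-node ages: the product of
    iid kernel densities conditional on the root age."""
    ages = np.asarray(ages, float)
    if ages.size == 0:
        return 0.0
    if np.any((ages <= 0) | (ages >= t_root)):
        return -np.inf
    return float(np.sum(bd_kernel_log_density(ages, t_root, bd)))


# ---------------------------------------------------------------------------
# Rate hyperpriors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateHyperpriors:
    """Gamma hyperpriors: per-locus mean rate ~ Gamma(alpha_r, beta_r)
    (shape/rate; default mean 0.05 substitutions/site/100 Myr) and the
    clock variance sigma^2 ~ Gamma(alpha_sigma, beta_sigma) (default
    mean 0.1)."""

    alpha_r: float = 2.0
    beta_r: float = 40.0
    alpha_sigma: float = 1.0
    beta_sigma: float = 10.0

    def __post_init__(self):
        for name in ("alpha_r", "beta_r", "alpha_sigma", "beta_sigma"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")


def hyperprior_log_density(value, which: str, hp: RateHyperpriors):
    """Log gamma density of a hyperparameter value.

    ``which`` selects the prior: ``"locus_rate"`` (mean rate mu_r of one
    locus) or ``"sigma2"`` (clock variance).  Non-positive values have
    zero density.
    """
    if which == "locus_rate":
        a, b = hp.alpha_r, hp.beta_r
    elif which == "sigma2":
        a, b = hp.alpha_sigma, hp.beta_sigma
    else:
        raise ValueError(f"unknown hyperparameter {which!r}")
    value = np.asarray(value, float)
    logd = np.full(value.shape, -np.inf)
    ok = value > 0
    logd[ok] = gamma_dist.logpdf(value[ok], a, scale=1.0 / b)
    return logd if logd.shape else float(logd)


# ---------------------------------------------------------------------------
# Calibration tables
# ---------------------------------------------------------------------------

def read_calibration_table(path) -> list[tuple[str, str, str, float, float]]:
    """Read a tab-delimited calibration table.

    Columns: ``clade_label  taxonA  taxonB  min_Ma  max_Ma``.  For a
    calibration on a leaf-pair MRCA, taxonA/taxonB name two leaves; a
    row may instead put ``.`` in both taxon columns to address the node
    by its Newick label.  Returns rows with ages still in Ma.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ValueError(f"calibration row needs 5 columns: {line!r}")
            label, ta, tb, lo, hi = parts
            rows.append((label, ta, tb, float(lo), float(hi)))
    return rows


def write_calibration_table(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("# clade_label\ttaxonA\ttaxonB\tmin_Ma\tmax_Ma\n")
        for label, ta, tb, lo, hi in rows:
            fh.write(f"{label}\t{ta}\t{tb}\t{lo:.4f}\t{hi:.4f}\n")


def attach_calibrations(tree: TimeTree, rows) -> TimeTree:
    """Attach :class:`Calibration` objects to tree nodes (ages Ma -> 100 Myr).

    Each row addresses a node either by a leaf pair (MRCA) or, with ``.``
    taxa, by its internal node label.
    """
    for label, ta, tb, lo_ma, hi_ma in rows:
        if ta == "." and tb == ".":
            node = tree.find_node(label)
        else:
            node = tree.mrca([ta, tb])
        tree.calibrations[node] = Calibration(label, lo_ma / MA_PER_UNIT, hi_ma / MA_PER_UNIT)
    return tree
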
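"""Amino-acid likelihoods and the normal-approximation machinery.

Dating runs never re-evaluate the sequence likelihood.  Instead, for each
locus the branch lengths of the (fixed) duplicated topology are estimated
by maximum likelihood under an empirical amino-acid model, and the
log-likelihood surface is replaced by its second-order Taylor expansion
around the MLE:

    l(b) - l(bhat)  ~  g' (b - bhat) + 1/2 (b - bhat)' H (b - bhat)

with gradient ``g`` (zero at an interior MLE) and Hessian ``H``.  The MCMC
then only ever evaluates this quadratic, which is what makes dating with
dozens of loci cheap.

This module implements Felsenstein pruning (with optional discrete-gamma
rate heterogeneity), analytic per-site score vectors via a post-order +
pre-order pass, the MLE/Hessian estimator, the quadratic approximation,
and a plain-text file dialect for the per-locus (bhat, g, H) triples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.optimize import minimize
from scipy.stats import gamma as gamma_dist

from .treeio import MISSING_CHARS, LocusAlignment, TimeTree

__all__ = [
    "AA_ALPHABET",
    "SubstitutionModel",
    "BranchLengthApprox",
    "OptimizationError",
    "pruning_loglik",
    "estimate_brlens_and_hessian",
    "approx_loglik",
    "write_bv",
    "read_bv",
]

#: PAML residue order
AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
N_STATES = 20
MISSING_STATE = 20

#: lower box bound keeping MLEs interior so the quadratic expansion is valid
BRLEN_FLOOR = 1e-6
BRLEN_CEIL = 50.0


class OptimizationError(RuntimeError):
    """Branch-length optimization failed; carries the best point found."""

    def __init__(self, message, best_b=None, grad_norm=None):
        super().__init__(message)
        self.best_b = best_b
        self.grad_norm = grad_norm


# ---------------------------------------------------------------------------
# Substitution models
# ---------------------------------------------------------------------------

def _load_paml_dat(name: str) -> tuple[np.ndarray, np.ndarray]:
    text = resources.files("wgdchronos.data").joinpath(f"{name}.dat").read_text()
    numbers = [float(x) for x in text.split()]
    if len(numbers) != 190 + 20:
        raise ValueError(f"model file {name}.dat malformed")
    S = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            S[i, j] = S[j, i] = numbers[k]
            k += 1
    freqs = np.array(numbers[190:])
    return S, freqs / freqs.sum()


@dataclass
class SubstitutionModel:
    """Reversible 20-state model, scaled to 1 expected substitution/site.

    ``gamma_shape``/``n_cat`` switch on discrete-gamma rate heterogeneity
    (median-of-category discretization, category rates normalized to
    mean 1).
    """

    name: str
    exchangeability: np.ndarray
    freqs: np.ndarray
    gamma_shape: float | None = None
    n_cat: int = 4
    # eigen machinery, filled in __post_init__
    _U: np.ndarray = field(init=False, repr=False)
    _W: np.ndarray = field(init=False, repr=False)
    _eval: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        S, pi = np.asarray(self.exchangeability, float), np.asarray(self.freqs, float)
        if not np.allclose(S, S.T):
            raise ValueError("exchangeability matrix must be symmetric")
        if not np.isclose(pi.sum(), 1.0):
            raise ValueError("frequencies must sum to 1")
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -np.sum(pi * np.diag(Q))
        Q /= scale
        self.rate_matrix = Q
        d = np.sqrt(pi)
        B = (Q * d[:, None]) / d[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eval = w
        self._U = V / d[:, None]
        self._W = V.T * d[None, :]
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValueError("gamma shape must be positive")

    @classmethod
    def poisson(cls, gamma_shape: float | None = None, n_cat: int = 4):
        S = np.ones((N_STATES, N_STATES)) - np.eye(N_STATES)
        return cls("Poisson", S, np.full(N_STATES, 1.0 / N_STATES), gamma_shape, n_cat)

    @classmethod
    def from_name(cls, name: str, gamma_shape: float | None = None, n_cat: int = 4):
        if name.lower() == "poisson":
            return cls.poisson(gamma_shape, n_cat)
        if name.upper() not in ("WAG", "LG", "JTT"):
            raise ValueError(f"unknown substitution model {name!r}")
        S, pi = _load_paml_dat(name.lower())
        return cls(name.upper(), S, pi, gamma_shape, n_cat)

    def category_rates(self) -> np.ndarray:
        """Discrete-gamma category rates (mean normalized to 1)."""
        if self.gamma_shape is None:
            return np.array([1.0])
        a, k = self.gamma_shape, self.n_cat
        r = gamma_dist.ppf((2 * np.arange(k) + 1) / (2.0 * k), a, scale=1.0 / a)
        return r / r.mean()

    def transition_matrices(self, t: float) -> np.ndarray:
        """P(r_c * t) for each rate category: array (k, 20, 20)."""
        rates = self.category_rates()
        et = np.exp(self._eval[None, :] * rates[:, None] * max(t, 0.0))
        P = np.einsum("ij,kj,jl->kil", self._U, et, self._W)
        return np.clip(P, 0.0, None)

    def dtransition_matrices(self, t: float) -> np.ndarray:
        """d/dt of the category transition matrices (chain rule incl. r_c)."""
        rates = self.category_rates()
        lam = self._eval[None, :] * rates[:, None]
        et = lam * np.exp(lam * max(t, 0.0))
        return np.einsum("ij,kj,jl->kil", self._U, et, self._W)


def encode_alignment(aln: LocusAlignment, labels: list[str]) -> np.ndarray:
    """Integer codes (n_seq, n_sites); gaps/unknowns -> MISSING_STATE."""
    lut = np.full(128, -1, dtype=np.int8)
    for i, c in enumerate(AA_ALPHABET):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    for c in MISSING_CHARS + "*.":
        lut[ord(c)] = MISSING_STATE
    lut[ord("B")] = lut[ord("Z")] = lut[ord("J")] = lut[ord("U")] = lut[ord("O")] = (
        MISSING_STATE
    )
    out = np.empty((len(labels), aln.length), dtype=np.int8)
    for row, lab in enumerate(labels):
        seq = aln.sequences[lab]
        codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8) & 0x7F]
        if np.any(codes < 0):
            bad = seq[int(np.argmax(codes < 0))]
            raise ValueError(f"invalid residue {bad!r} in sequence {lab!r}")
        out[row] = codes
    return out


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class PruningEngine:
    """Felsenstein pruning on a fixed topology with pattern compression.

    Branch ``k`` is the edge above node ``order[k]`` where ``order`` is the
    tree's canonical post-order; this is the ordering used everywhere
    (BV files, MCMC, clocks).
    """

    def __init__(self, aln: LocusAlignment, tree: TimeTree, model: SubstitutionModel):
        self.tree = tree
        self.model = model
        self.order = tree.canonical_branches()
        self.branch_index = {v: k for k, v in enumerate(self.order)}
        leaf_ids = tree.leaf_ids
        missing = [tree.labels[i] for i in leaf_ids if tree.labels[i] not in aln.sequences]
        extra = sorted(set(aln.sequences) - {tree.labels[i] for i in leaf_ids})
        if missing or extra:
            raise ValueError(
                f"leaf/alignment label mismatch: tree-only {sorted(missing)}, "
                f"alignment-only {extra}"
            )
        codes = encode_alignment(aln, [tree.labels[i] for i in leaf_ids])
        patterns, self.weights = np.unique(codes, axis=1, return_counts=True)
        self.n_sites = aln.length
        self.n_patterns = patterns.shape[1]
        self.leaf_partial = {}
        k = len(model.category_rates())
        eye = np.vstack([np.eye(N_STATES), np.ones(N_STATES)])
        for row, nid in enumerate(leaf_ids):
            part = eye[patterns[row]].T  # (20, n_patterns)
            self.leaf_partial[nid] = np.broadcast_to(part, (k, N_STATES, self.n_patterns))

    @property
    def n_branches(self) -> int:
        return len(self.order)

    def _passes(self, b: np.ndarray, want_score: bool):
        tree, model = self.tree, self.model
        k = len(model.category_rates())
        P = {}
        for idx, v in enumerate(self.order):
            P[v] = model.transition_matrices(b[idx])
        down: dict[int, np.ndarray] = {}
        msg: dict[int, np.ndarray] = {}
        scale = {}  # per-pattern log-scaler accumulated in the subtree
        for v in tree.postorder():
            if tree.is_leaf(v):
                down[v] = self.leaf_partial[v]
                scale[v] = np.zeros(self.n_patterns)
            else:
                prod = np.ones((k, N_STATES, self.n_patterns))
                sc = np.zeros(self.n_patterns)
                for c in tree.children[v]:
                    msg[c] = np.matmul(P[c], down[c])
                    prod = prod * msg[c]
                    sc = sc + scale[c]
                m = prod.max(axis=(0, 1))
                m = np.where(m > 0, m, 1.0)
                down[v] = prod / m
                scale[v] = sc + np.log(m)
        pi = model.freqs
        Lroot = np.einsum("j,kjp->kp", pi, down[tree.root])  # (k, n_patterns)
        Lmean = Lroot.mean(axis=0)
        site_ll = np.log(np.maximum(Lmean, 1e-300)) + scale[tree.root]
        loglik = float(np.dot(self.weights, site_ll))
        if not want_score:
            return loglik, site_ll, None
        # pre-order (outside) pass
        pre = {tree.root: np.broadcast_to(pi[None, :, None], (k, N_STATES, self.n_patterns))}
        pre_scale = {tree.root: np.zeros(self.n_patterns)}
        score = np.empty((self.n_branches, self.n_patterns))
        for v in tree.preorder():
            if tree.is_leaf(v):
                continue
            for c in tree.children[v]:
                out = pre[v]
                sc = pre_scale[v]
                for s in tree.children[v]:
                    if s != c:
                        out = out * msg[s]
                        sc = sc + scale[s]
                m = out.max(axis=(0, 1))
                m = np.where(m > 0, m, 1.0)
                out = out / m
                sc = sc + np.log(m)
                dP = self.model.dtransition_matrices(b[self.branch_index[c]])
                num = np.einsum("kip,kij,kjp->p", out, dP, down[c]) / k
                # d loglik / d b_c per pattern: numerator and L share scalers
                score[self.branch_index[c]] = (
                    num * np.exp(sc + scale[c] - site_ll)
                )
                pre[c] = np.einsum("kip,kij->kjp", out, P[c])
                pre_scale[c] = sc
        return loglik, site_ll, score

    def loglik(self, b: np.ndarray) -> float:
        return self._passes(np.asarray(b, float), False)[0]

    def loglik_and_grad(self, b: np.ndarray) -> tuple[float, np.ndarray]:
        ll, _, score = self._passes(np.asarray(b, float), True)
        return ll, score @ self.weights

    def site_scores(self, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-pattern score vectors and pattern weights (for the
        empirical-Fisher curvature)."""
        _, _, score = self._passes(np.asarray(b, float), True)
        return score, self.weights


def pruning_loglik(
    aln: LocusAlignment, tree: TimeTree, b: np.ndarray, model: SubstitutionModel
) -> float:
    """Exact log-likelihood of the alignment on the fixed topology.

    ``b`` holds substitutions/site per branch in the tree's canonical
    post-order.  Missing residues contribute partial likelihood 1 over
    all states; with gamma heterogeneity, site likelihoods average over
    the discrete categories.
    """
    b = np.asarray(b, float)
    if np.any(b < 0):
        raise ValueError("branch lengths must be nonnegative")
    return PruningEngine(aln, tree, model).loglik(b)


# ---------------------------------------------------------------------------
# MLE branch lengths, gradient and Hessian
# ---------------------------------------------------------------------------

@dataclass
class BranchLengthApprox:
    """Per-locus second-order summary of the likelihood surface."""

    locus_id: str
    branch_names: list[str]
    bhat: np.ndarray
    grad: np.ndarray
    hessian: np.ndarray

    def __post_init__(self):
        n = len(self.branch_names)
        self.bhat = np.asarray(self.bhat, float)
        self.grad = np.asarray(self.grad, float)
        self.hessian = np.asarray(self.hessian, float)
        if self.bhat.shape != (n,) or self.grad.shape != (n,) or self.hessian.shape != (n, n):
            raise ValueError(f"locus {self.locus_id}: dimension mismatch with {n} branches")
        asym = np.abs(self.hessian - self.hessian.T).max() if n else 0.0
        if asym > 1e-8:
            warnings.warn(
                f"locus {self.locus_id}: Hessian asymmetry {asym:.3g}; symmetrizing"
            )
        self.hessian = (self.hessian + self.hessian.T) / 2.0

    @property
    def n_branches(self) -> int:
        return len(self.branch_names)


def approx_loglik(b: np.ndarray, approx: BranchLengthApprox) -> float:
    """Quadratic log-likelihood difference l(b) - l(bhat)."""
    b = np.asarray(b, float)
    if b.shape != approx.bhat.shape:
        raise ValueError(
            f"branch vector of length {b.size} does not match "
            f"{approx.n_branches} branches of locus {approx.locus_id}"
        )
    d = b - approx.bhat
    return float(approx.grad @ d + 0.5 * d @ approx.hessian @ d)


def estimate_brlens_and_hessian(
    aln: LocusAlignment,
    tree: TimeTree,
    model: SubstitutionModel,
    hessian_method: str = "fd",
    floor: float = BRLEN_FLOOR,
    gtol_per_site: float = 1e-3,
    starts: tuple[float, ...] = (0.1, 0.5),
) -> BranchLengthApprox:
    """MLE branch lengths with gradient and Hessian at the optimum.

    Multi-start L-BFGS-B with analytic gradients and box bound
    ``b >= floor`` (keeping the MLE interior).  The Hessian comes from
    central finite differences of the analytic gradient
    (``hessian_method="fd"``, step ``max(1e-4, 1e-2 * bhat_i)``) or from
    the negative outer product of per-site scores (``"outer"``, the
    empirical Fisher information — much faster, asymptotically
    equivalent).  Raises :class:`OptimizationError` if no start
    converges to ``|g|_inf <= gtol_per_site * n_sites``.
    """
    engine = PruningEngine(aln, tree, model)
    nb = engine.n_branches

    def negobj(b):
        ll, g = engine.loglik_and_grad(b)
        return -ll, -g

    best = None
    for s in starts:
        res = minimize(
            negobj,
            np.full(nb, s),
            jac=True,
            method="L-BFGS-B",
            bounds=[(floor, BRLEN_CEIL)] * nb,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        if best is None or res.fun < best.fun:
            best = res
    bhat = np.asarray(best.x)
    ll, grad = engine.loglik_and_grad(bhat)
    gnorm = float(np.abs(grad).max()) if nb else 0.0
    interior = (bhat > floor * (1 + 1e-6)) & (bhat < BRLEN_CEIL * (1 - 1e-6))
    if gnorm > gtol_per_site * engine.n_sites and np.all(interior):
        raise OptimizationError(
            f"branch-length optimization did not converge (|g|_inf={gnorm:.3g})",
            best_b=bhat,
            grad_norm=gnorm,
        )
    if hessian_method == "outer":
        score, w = engine.site_scores(bhat)
        H = -(score * w[None, :]) @ score.T
    elif hessian_method == "fd":
        H = np.empty((nb, nb))
        for j in range(nb):
            h = max(1e-4, 1e-2 * bhat[j])
            bp, bm = bhat.copy(), bhat.copy()
            bp[j] += h
            bm[j] = max(bm[j] - h, floor / 10)
            _, gp = engine.loglik_and_grad(bp)
            _, gm = engine.loglik_and_grad(bm)
            H[:, j] = (gp - gm) / (bp[j] - bm[j])
        H = (H + H.T) / 2.0
    else:
        raise ValueError(f"unknown hessian_method {hessian_method!r}")
    names = [tree.branch_name(v) for v in engine.order]
    return BranchLengthApprox(aln.locus_id, names, bhat, grad, H)


# ---------------------------------------------------------------------------
# BV file dialect
# ---------------------------------------------------------------------------

BV_HEADER = "# wgdchronos BV v1"


def write_bv(approxes: list[BranchLengthApprox], path) -> None:
    """Write branch-length approximations as versioned plain text.

    Layout per locus: ``locus`` id, branch count, one line of canonical
    branch names, then the bhat line, the gradient line, and the Hessian
    block (n rows).  Numbers carry 12+ significant digits so read/write
    round-trips exactly at that precision.
    """

    def line(v):
        return " ".join(f"{x:.12e}" for x in v)

    with open(path, "w") as fh:
        fh.write(BV_HEADER + "\n")
        for ap in approxes:
            fh.write(f"locus {ap.locus_id}\n")
            fh.write(f"branches {ap.n_branches}\n")
            fh.write(" ".join(ap.branch_names) + "\n")
            fh.write(line(ap.bhat) + "\n")
            fh.write(line(ap.grad) + "\n")
            for row in ap.hessian:
                fh.write(line(row) + "\n")
            fh.write("\n")


def read_bv(path, expected_branch_names: list[str] | None = None) -> list[BranchLengthApprox]:
    """Read a BV file; optionally validate branch naming/ordering against
    a dating tree's canonical branches (error names the first mismatch)."""
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    if not lines or lines[0] != BV_HEADER:
        raise ValueError(f"{path}: not a wgdchronos BV v1 file")
    out: list[BranchLengthApprox] = []
    i = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith("locus "):
            raise ValueError(f"{path}: expected 'locus' at line {i + 1}")
        locus_id = lines[i][6:].strip()
        if not lines[i + 1].startswith("branches "):
            raise ValueError(f"{path}: expected 'branches' at line {i + 2}")
        n = int(lines[i + 1].split()[1])
        names = lines[i + 2].split()
        if len(names) != n:
            raise ValueError(f"{path}: locus {locus_id}: {len(names)} names for {n} branches")
        try:
            bhat = np.array([float(x) for x in lines[i + 3].split()])
            grad = np.array([float(x) for x in lines[i + 4].split()])
            H = np.array(
                [[float(x) for x in lines[i + 5 + r].split()] for r in range(n)]
            )
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}: locus {locus_id}: malformed numeric block") from exc
        if bhat.size != n or grad.size != n or H.shape != (n, n):
            raise ValueError(
                f"{path}: locus {locus_id}: block shapes do not match {n} branches"
            )
        out.append(BranchLengthApprox(locus_id, names, bhat, grad, H))
        i += 5 + n
    if expected_branch_names is not None:
        for ap in out:
            if ap.branch_names != list(expected_branch_names):
                bad = next(
                    (a, b)
                    for a, b in zip(ap.branch_names, expected_branch_names)
                    if a != b
                )
                raise ValueError(
                    f"locus {ap.locus_id}: branch ordering mismatch with dating tree "
                    f"(first mismatch: file {bad[0]!r} vs tree {bad[1]!r})"
                )
    return out
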
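"""Synthetic studies with the statistical structure the dating model assumes.

The generator emulates the design of a concatenated-ohnologue WGD dating
study: 12 ray-finned-fish taxa of which the 6 teleosts contribute two
ohnologue copies each (18 expected sequences per locus), ~30 loci with
occasional missing genes, per-locus rate heterogeneity, and node ages on
a Devonian-to-Neogene scale.  Chronograms come from the same calibration
+ birth–death prior the sampler uses, rates from the configured relaxed
clock, and loci either as amino-acid alignments evolved down the tree or
directly as branch-length approximations with curvature-consistent noise.

A delayed-rediploidization simulator produces ohnologue pairs whose
per-site divergence ages are pushed toward the rediploidization time by
gene conversion during the tetrasomic phase — the generative counterpart
of the question whether a dated WGD node tracks the duplication itself
or only the end of tetrasomy.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clocks as _clocks
from .likelihood import (
    AA_ALPHABET,
    BranchLengthApprox,
    N_STATES,
    PruningEngine,
    SubstitutionModel,
)
from .priors import (
    BirthDeathPrior,
    Calibration,
    RateHyperpriors,
    attach_calibrations,
    bd_kernel_cdf,
    bd_kernel_quantile,
    calibration_quantile,
    write_calibration_table,
)
from .treeio import (
    MA_PER_UNIT,
    LocusAlignment,
    TaxonRoster,
    TimeTree,
    build_duplicated_topology,
    parse_newick,
    write_fasta_alignment,
    write_newick,
)

__all__ = [
    "StudyDesign",
    "WGDSimParams",
    "default_design",
    "simulate_chronogram",
    "simulate_locus",
    "simulate_alignment",
    "simulate_wgd_rediploidization",
    "make_fixture",
]

#: 12-taxon ray-finned-fish backbone: bichirs (Cladistia), sturgeon+paddlefish
#: (Chondrostei), gar+bowfin (Holostei) as non-duplicated outgroups; six
#: teleosts forming the duplicated clade.
DEFAULT_SPECIES_NEWICK = (
    "((Polypterus,Erpetoichthys)Cladistia,"
    "((Acipenser,Polyodon)Chondrostei,"
    "((Lepisosteus,Amia)Holostei,"
    "(Scleropages,(Anguilla,(Danio,(Esox,(Gasterosteus,Oryzias)"
    "Acanthomorpha)Euteleostei)Clupeocephala)Elopocephalai)Teleostei"
    ")Neopterygii)Actinopteri)Actinopterygii;"
)

TELEOSTS = ("Scleropages", "Anguilla", "Danio", "Esox", "Gasterosteus", "Oryzias")
OUTGROUPS = ("Polypterus", "Erpetoichthys", "Acipenser", "Polyodon", "Lepisosteus", "Amia")

#: default soft-bound calibrations (Ma): root + one backbone node + both
#: mirrored crown-teleost nodes ('.' taxa address nodes by label)
DEFAULT_CALIBRATIONS = [
    ("Actinopterygii", ".", ".", 360.0, 400.0),
    ("Neopterygii", ".", ".", 300.0, 340.0),
    ("Teleostei_1", ".", ".", 230.0, 260.0),
    ("Teleostei_2", ".", ".", 230.0, 260.0),
]


@dataclass
class StudyDesign:
    """Everything needed to generate one synthetic study (ages in 100 Myr).

    Defaults emulate the reference design: 12 taxa (6 duplicated), 30
    loci with >= 100 columns each, exactly 3 missing genes spread over
    distinct loci (so the default fixture has 30*18 - 3 = 537 sequences
    and 27 complete loci), a WGD in the Permian on a ~380-Ma-root scale,
    ILN rate variation across loci drawn from the gamma hyperpriors.
    """

    species_newick: str = DEFAULT_SPECIES_NEWICK
    duplicated_taxa: tuple[str, ...] = TELEOSTS
    outgroup_taxa: tuple[str, ...] = OUTGROUPS
    copy_suffixes: tuple[str, str] = ("_1", "_2")
    wgd_age: float = 2.77
    n_loci: int = 30
    length_shape: float = 4.0
    length_scale: float = 122.0  # gamma(4, 122) + 100 -> mean ~588 columns
    min_length: int = 100
    n_missing_genes: int = 3
    clock_model: str = "ILN"
    hyperpriors: RateHyperpriors = field(default_factory=RateHyperpriors)
    bd: BirthDeathPrior = field(default_factory=BirthDeathPrior)
    substitution_model: str = "Poisson"
    calibrations: list = field(default_factory=lambda: list(DEFAULT_CALIBRATIONS))

    def roster(self) -> TaxonRoster:
        return TaxonRoster(self.duplicated_taxa, self.outgroup_taxa, self.copy_suffixes)

    def species_tree(self) -> TimeTree:
        return parse_newick(self.species_newick)

    def duplicated_tree(self) -> TimeTree:
        tree = build_duplicated_topology(
            self.species_tree(), self.duplicated_taxa, self.copy_suffixes
        )
        return attach_calibrations(tree, self.calibrations)


def default_design(**overrides) -> StudyDesign:
    return dataclasses.replace(StudyDesign(), **overrides)


# ---------------------------------------------------------------------------
# Chronogram simulation
# ---------------------------------------------------------------------------

def _free_components(tree: TimeTree, free: set[int]) -> list[list[int]]:
    """Connected components of free internal nodes under parent-child edges."""
    comps, seen = [], set()
    for v in sorted(free):
        if v in seen:
            continue
        comp, stack = [], [v]
        seen.add(v)
        while stack:
            u = stack.pop()
            comp.append(u)
            nbrs = [tree.parent[u]] + list(tree.children[u])
            for w in nbrs:
                if w in free and w not in seen:
                    seen.add(w)
                    stack.append(w)
        comps.append(sorted(comp))
    return comps


def simulate_chronogram(
    design: StudyDesign, seed_or_rng=0, t_root: float | None = None, max_tries: int = 20000
) -> TimeTree:
    """Draw a duplicated-topology chronogram from the study's age prior.

    Ages are drawn from exactly the prior the sampler uses: calibrated
    nodes (root included) from their calibration densities, the WGD node
    fixed at ``design.wgd_age``, and the remaining internal nodes iid
    from the birth–death kernel conditional on the root age, restricted
    to the parent > child order constraints.  The restriction is sampled
    exactly: within each connected component of free nodes, draws are
    truncated to the enclosing fixed-node ages and rejected until the
    component's internal order holds.  A single free node therefore
    follows the plain kernel density.
    """
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    tree = design.duplicated_tree()
    wgd = tree.find_node("WGD")
    root = tree.root
    internal = tree.internal_ids()
    calibrated = [v for v in internal if v in tree.calibrations and v != root]
    free = {v for v in internal if v not in tree.calibrations and v != wgd}
    comps = _free_components(tree, free)

    def fixed_upper(v, ages):
        u = tree.parent[v]
        while u in free:
            u = tree.parent[u]
        return ages[u]

    def fixed_lower(v, ages):
        lo = 0.0
        stack = list(tree.children[v])
        while stack:
            u = stack.pop()
            if tree.is_leaf(u):
                continue
            if u in free:
                stack.extend(tree.children[u])
            else:
                lo = max(lo, ages[u])
        return lo

    for _ in range(max_tries):
        ages = np.zeros(tree.n_nodes)
        ages[root] = (
            t_root
            if t_root is not None
            else calibration_quantile(rng.random(), tree.calibrations[root])
        )
        for v in calibrated:
            ages[v] = calibration_quantile(rng.random(), tree.calibrations[v])
        ages[wgd] = design.wgd_age
        # the fixed skeleton itself must respect the topology
        fixed = [root, wgd] + calibrated
        if not all(
            _skeleton_ok(tree, ages, v, set(fixed) | {root}) for v in fixed
        ):
            continue
        ok = True
        for comp in comps:
            pairs = [
                (tree.parent[v], v) for v in comp if tree.parent[v] in comp
            ]
            for _ in range(5000):
                for v in comp:
                    lo, hi = fixed_lower(v, ages), fixed_upper(v, ages)
                    u_lo = bd_kernel_cdf(lo, ages[root], design.bd) if lo > 0 else 0.0
                    u_hi = bd_kernel_cdf(hi, ages[root], design.bd)
                    u = u_lo + rng.random() * (u_hi - u_lo)
                    ages[v] = bd_kernel_quantile(u, ages[root], design.bd)
                if all(ages[p] > ages[c] for p, c in pairs):
                    break
            else:
                ok = False
                break
        if ok:
            out = tree.copy()
            out.set_ages(ages)
            return out
    raise RuntimeError(
        "could not draw a chronogram consistent with the calibrations and WGD age"
    )


def _skeleton_ok(tree: TimeTree, ages, v, fixed: set) -> bool:
    """Check v against its nearest fixed ancestor (free nodes skipped)."""
    if tree.parent[v] < 0:
        return True
    u = tree.parent[v]
    while u not in fixed and tree.parent[u] >= 0:
        u = tree.parent[u]
    return u not in fixed or ages[v] < ages[u]


# ---------------------------------------------------------------------------
# Sequence / locus simulation
# ---------------------------------------------------------------------------

def _draw_rates(tree: TimeTree, cfg: _clocks.ClockConfig, rng) -> np.ndarray:
    """Branch rates (ILN, canonical branch order) or node rates (GBM)."""
    if cfg.model == "ILN":
        nb = tree.n_nodes - 1
        if cfg.sigma2 == 0:
            return np.full(nb, cfg.mu_r)
        mean_log = np.log(cfg.mu_r) - cfg.sigma2 / 2.0
        return np.exp(rng.normal(mean_log, np.sqrt(cfg.sigma2), nb))
    rates = np.empty(tree.n_nodes)
    rates[tree.root] = cfg.mu_r
    sep = _clocks.node_midpoint_separations(tree)
    for v in tree.preorder():
        p = tree.parent[v]
        if p < 0:
            continue
        var = cfg.sigma2 * sep[v]
        rates[v] = (
            rates[p]
            if var <= 0
            else np.exp(rng.normal(np.log(rates[p]) - var / 2.0, np.sqrt(var)))
        )
    return rates


def simulate_alignment(
    tree: TimeTree,
    b: np.ndarray,
    n_sites: int,
    model: SubstitutionModel,
    rng,
    labels: list[str] | None = None,
) -> LocusAlignment:
    """Evolve an alignment site-wise down the tree (branch lengths ``b``
    in canonical order, substitutions/site).  ``labels`` restricts the
    output to a subset of leaves (missing genes)."""
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    order = tree.canonical_branches()
    branch_index = {v: i for i, v in enumerate(order)}
    k = len(model.category_rates())
    cat = rng.integers(0, k, n_sites) if k > 1 else np.zeros(n_sites, int)
    states = {tree.root: rng.choice(N_STATES, n_sites, p=model.freqs)}
    for v in tree.preorder():
        if v == tree.root:
            continue
        P = model.transition_matrices(b[branch_index[v]])  # (k, 20, 20)
        parent_states = states[tree.parent[v]]
        # cumulative inverse-transform per site
        C = np.cumsum(P, axis=2)
        u = rng.random(n_sites)
        rows = C[cat, parent_states, :]
        states[v] = (u[:, None] < rows).argmax(axis=1)
    alpha = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
    seqs = {}
    for nid in tree.leaf_ids:
        lab = tree.labels[nid]
        if labels is not None and lab not in labels:
            continue
        seqs[lab] = alpha[states[nid]].tobytes().decode()
    return LocusAlignment("sim", seqs)


def simulate_locus(
    tree: TimeTree,
    cfg: _clocks.ClockConfig,
    n_sites: int,
    mode: str = "alignment",
    seed_or_rng=0,
    model: SubstitutionModel | None = None,
    noise_scale: float = 1.0,
    present_labels: list[str] | None = None,
    locus_id: str = "sim",
    return_truth: bool = False,
):
    """Simulate one locus on an aged tree under the configured clock.

    ``mode="alignment"`` evolves sequences and returns a
    :class:`LocusAlignment`.  ``mode="brlen_approx"`` returns a
    :class:`BranchLengthApprox` directly: the true branch lengths b are
    perturbed with curvature-consistent noise, bhat = b + eps with
    eps ~ N(0, -H^{-1}), where H is the empirical-Fisher curvature of the
    pruning likelihood at b measured on an alignment of ``n_sites``
    simulated at b (a small ridge keeps H invertible when missing genes
    leave branches uninformed); g = 0.  ``noise_scale`` scales eps
    (0 returns bhat = b exactly).
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    model = model or SubstitutionModel.poisson()
    rates = _draw_rates(tree, cfg, rng)
    b = _clocks.expected_branch_lengths(tree, rates, cfg)
    truth = {"rates": rates, "b": b}
    if mode == "alignment":
        aln = simulate_alignment(tree, b, n_sites, model, rng, labels=present_labels)
        aln.locus_id = locus_id
        return (aln, truth) if return_truth else aln
    if mode != "brlen_approx":
        raise ValueError(f"unknown mode {mode!r}")
    aln = simulate_alignment(tree, b, n_sites, model, rng)
    if present_labels is not None:
        # absent genes become all-missing rows: same topology, no information
        aln = LocusAlignment(
            locus_id,
            {
                lab: (s if lab in present_labels else "?" * len(s))
                for lab, s in aln.sequences.items()
            },
        )
    engine = PruningEngine(aln, tree, model)
    score, w = engine.site_scores(np.maximum(b, 1e-8))
    H = -(score * w[None, :]) @ score.T
    ridge = 1e-3 * max(np.mean(np.diag(-H)), 1.0)
    H -= ridge * np.eye(len(b))
    cov = np.linalg.inv(-H)
    eps = np.linalg.cholesky(cov) @ rng.standard_normal(len(b))
    # bhat may go slightly negative on near-zero branches; the quadratic
    # likelihood is defined there and censoring would bias the noise model
    bhat = b + noise_scale * eps
    names = [tree.branch_name(v) for v in tree.canonical_branches()]
    ap = BranchLengthApprox(locus_id, names, bhat, np.zeros(len(b)), H)
    return (ap, truth) if return_truth else ap


# ---------------------------------------------------------------------------
# Delayed rediploidization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WGDSimParams:
    """Tetrasomic-phase simulation parameters (times in 100 Myr).

    Between the WGD at ``t_wgd`` and rediploidization at ``t_r`` the two
    copies are homogenized by gene-conversion events arriving per site at
    rate ``conversion_rate`` (events/site/100 Myr); after ``t_r`` they
    diverge freely at substitution rate ``subst_rate``.
    """

    t_wgd: float
    t_r: float
    conversion_rate: float
    subst_rate: float = 0.05

    def __post_init__(self):
        if not (0.0 <= self.t_r <= self.t_wgd):
            raise ValueError("need 0 <= t_r <= t_wgd")
        if self.conversion_rate < 0:
            raise ValueError("conversion rate must be nonnegative")


def simulate_wgd_rediploidization(
    params: WGDSimParams, n_sites: int, seed_or_rng=0
) -> tuple[np.ndarray, LocusAlignment]:
    """Per-site ohnologue divergence ages plus the diverged pair.

    A site's effective divergence age is the age of its most recent
    conversion event, t_r plus a truncated-exponential residual — or
    t_wgd if no conversion hit the site during the tetrasomic phase.
    Both copies then evolve independently from a common ancestral
    residue for that long, under the Poisson model at ``subst_rate``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed_or_rng) if isinstance(seed_or_rng, (int, np.integer)) else seed_or_rng
    c, delta = params.conversion_rate, params.t_wgd - params.t_r
    u = rng.random(n_sites)
    if c == 0 or delta == 0:
        ages = np.full(n_sites, params.t_wgd)
    else:
        p_none = np.exp(-c * delta)
        resid = -np.log1p(-rng.random(n_sites) * (1.0 - p_none)) / c
        ages = np.where(u < p_none, params.t_wgd, params.t_r + resid)
    # Poisson-model divergence: each copy evolves distance r * age
    beta = N_STATES / (N_STATES - 1.0)
    anc = rng.integers(0, N_STATES, n_sites)
    seqs = {}
    for name in ("copy_1", "copy_2"):
        stay = rng.random(n_sites) < np.exp(-beta * params.subst_rate * ages)
        new = rng.integers(0, N_STATES, n_sites)
        states = np.where(stay, anc, new)
        alpha = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)
        seqs[name] = alpha[states].tobytes().decode()
    return ages, LocusAlignment("redip", seqs)


# ---------------------------------------------------------------------------
# On-disk fixtures
# ---------------------------------------------------------------------------

def _prune_tree_to_labels(tree: TimeTree, labels: set) -> TimeTree:
    from .treeio import _from_nested, _prune_nested, _to_nested

    nested = _prune_nested(_to_nested(tree), labels)
    return _from_nested(nested)


def make_fixture(design: StudyDesign, out_dir, seed: int = 0) -> dict:
    """Write a complete synthetic study to ``out_dir``.

    Produces FASTA loci, per-locus gene trees, the species and duplicated
    trees, the true chronogram, the calibration table, per-locus clock
    configurations, and truth tables for recovery tests.  Regenerating
    with the same seed is byte-identical.  Returns a manifest dict with
    paths and the truth DataFrames.
    """
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    (out / "loci").mkdir(parents=True, exist_ok=True)
    (out / "gene_trees").mkdir(exist_ok=True)
    chron = simulate_chronogram(design, rng)
    roster = design.roster()
    labels = roster.expected_labels
    model = SubstitutionModel.from_name(design.substitution_model)

    # choose missing genes: distinct loci, one gene each, never the last outgroup
    missing: dict[int, str] = {}
    if design.n_missing_genes:
        loci_hit = rng.choice(design.n_loci, design.n_missing_genes, replace=False)
        for li in sorted(loci_hit):
            missing[int(li)] = labels[int(rng.integers(0, len(labels)))]

    locus_rows, node_rows = [], []
    hp = design.hyperpriors
    for li in range(design.n_loci):
        n_sites = design.min_length + int(
            rng.gamma(design.length_shape, design.length_scale)
        )
        mu = rng.gamma(hp.alpha_r, 1.0 / hp.beta_r)
        s2 = rng.gamma(hp.alpha_sigma, 1.0 / hp.beta_sigma)
        cfg = _clocks.ClockConfig(design.clock_model, mu, s2)
        present = [l for l in labels if missing.get(li) != l]
        lid = f"locus_{li:02d}"
        aln = simulate_locus(
            chron,
            cfg,
            n_sites,
            mode="alignment",
            seed_or_rng=rng,
            model=model,
            present_labels=present,
            locus_id=lid,
        )
        write_fasta_alignment(aln, out / "loci" / f"{lid}.fasta")
        gt = _prune_tree_to_labels(chron, set(present))
        with open(out / "gene_trees" / f"{lid}.nwk", "w") as fh:
            fh.write(write_newick(gt) + "\n")
        locus_rows.append(
            {
                "locus": lid,
                "n_sites": n_sites,
                "mu_r": mu,
                "sigma2": s2,
                "n_sequences": len(present),
            }
        )

    for v in chron.internal_ids():
        from .mcmc import node_name

        node_rows.append(
            {"node": node_name(chron, v), "true_age_Ma": chron.ages[v] * MA_PER_UNIT}
        )

    with open(out / "species_tree.nwk", "w") as fh:
        fh.write(design.species_newick + "\n")
    with open(out / "duplicated_tree.nwk", "w") as fh:
        fh.write(write_newick(design.duplicated_tree()) + "\n")
    with open(out / "chronogram_true.nwk", "w") as fh:
        fh.write(write_newick(chron, unit="Ma") + "\n")
    write_calibration_table(design.calibrations, out / "calibrations.tsv")
    truth_nodes = pd.DataFrame(node_rows)
    truth_loci = pd.DataFrame(locus_rows)
    truth_nodes.to_csv(out / "truth_nodes.csv", index=False)
    truth_loci.to_csv(out / "truth_loci.csv", index=False)
    return {
        "dir": out,
        "chronogram": chron,
        "roster": roster,
        "truth_nodes": truth_nodes,
        "truth_loci": truth_loci,
        "missing": missing,
    }
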
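"""Downstream analytics and the pipeline driver.

Covers the quantities a WGD dating study reports beyond raw posteriors:
exact interval arithmetic for WGD-to-radiation lags (how long after the
duplication did the crown radiate?), the infinite-sites regression of
HPD width on posterior mean age (how much uncertainty per Myr of
divergence remains as data grow), a paired comparison of clock models,
and ``run_pipeline`` which drives a complete study from inputs on disk
to summary tables with a hashed manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from decimal import Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import linregress, ttest_rel

from . import mcmc as _mcmc
from .likelihood import SubstitutionModel, estimate_brlens_and_hessian, write_bv
from .priors import BirthDeathPrior, RateHyperpriors, attach_calibrations, read_calibration_table
from .treeio import (
    MA_PER_UNIT,
    TaxonRoster,
    build_duplicated_topology,
    filter_and_concatenate,
    parse_newick,
    read_fasta_alignment,
    screen_orthogroup,
)

__all__ = [
    "AgeInterval",
    "IntervalStats",
    "PrecisionPoint",
    "RegressionResult",
    "ClockComparison",
    "interval_stats",
    "infinite_sites_regression",
    "compare_clock_models",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Interval arithmetic (exact at the printed 2-decimal precision)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeInterval:
    """A printed age interval in Ma (older bound first)."""

    older: float
    younger: float
    label: str = ""

    def __post_init__(self):
        if self.older < self.younger:
            raise ValueError(f"interval {self.label!r}: older < younger")


@dataclass(frozen=True)
class IntervalStats:
    width: float
    min_gap: float | None = None
    max_gap: float | None = None


def _dec(x: float) -> Decimal:
    return Decimal(f"{x:.2f}")


def interval_stats(a: AgeInterval, b: AgeInterval | None = None) -> IntervalStats:
    """Width of ``a`` and, given ``b``, the offset range between them.

    The offset range is (a.younger - b.older, a.older - b.younger): the
    smallest and largest possible time gap by which ``a`` precedes ``b``.
    Arithmetic is exact decimal at 2 dp (the precision such bounds are
    printed with), so e.g. 286.18 - 267.20 is exactly 18.98.
    """
    width = float(_dec(a.older) - _dec(a.younger))
    if b is None:
        return IntervalStats(width)
    return IntervalStats(
        width,
        min_gap=float(_dec(a.younger) - _dec(b.older)),
        max_gap=float(_dec(a.older) - _dec(b.younger)),
    )


# ---------------------------------------------------------------------------
# Infinite-sites regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionPoint:
    """One node in an infinite-sites plot (units of 100 Myr)."""

    node: str
    mean: float
    width: float
    n_loci: int = 0

    def __post_init__(self):
        if self.width < 0:
            raise ValueError("HPD width must be nonnegative")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    rse: float
    n: int


def infinite_sites_regression(
    points: list[PrecisionPoint],
    include_root: bool = True,
    root_label: str | None = None,
) -> RegressionResult:
    """OLS of 95%-HPD width on posterior mean age (both in 100 Myr).

    The slope is the uncertainty added per unit of divergence time; as
    sequence data grow it approaches the infinite-sites limit set by the
    calibrations.  ``include_root=False`` drops the root point (by
    ``root_label``, else the oldest point), the usual robustness check
    since the root often sits alone at the old end.
    """
    pts = list(points)
    if not include_root:
        if root_label is not None:
            pts = [p for p in pts if p.node != root_label]
        else:
            oldest = max(pts, key=lambda p: p.mean)
            pts = [p for p in pts if p is not oldest]
    if len(pts) < 3:
        raise ValueError("need at least 3 points for the regression")
    x = np.array([p.mean for p in pts])
    y = np.array([p.width for p in pts])
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all posterior means equal")
    res = linregress(x, y)
    resid = y - (res.intercept + res.slope * x)
    rse = float(np.sqrt(np.sum(resid**2) / (len(pts) - 2))) if len(pts) > 2 else 0.0
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        rse=rse,
        n=len(pts),
    )


# ---------------------------------------------------------------------------
# Clock-model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClockComparison:
    t_stat: float
    p_value: float
    slope: float
    intercept: float
    r: float
    n: int
    degenerate: bool = False
    note: str = ""


def compare_clock_models(means_a, means_b) -> ClockComparison:
    """Paired two-tailed t-test plus regression of per-node posterior means.

    ``means_a``/``means_b`` map node label -> posterior mean age (any
    mapping or pandas Series); only shared nodes enter.  Identical means
    give t = 0, P = 1; equal but nonzero differences everywhere are
    degenerate (P undefined).
    """
    a, b = pd.Series(dict(means_a)), pd.Series(dict(means_b))
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 2:
        raise ValueError("need at least 2 shared nodes for a paired comparison")
    x, y = a[shared].to_numpy(float), b[shared].to_numpy(float)
    reg = linregress(y, x)
    d = x - y
    if np.ptp(d) == 0:
        if d[0] == 0:
            return ClockComparison(0.0, 1.0, reg.slope, reg.intercept, reg.rvalue, len(shared))
        return ClockComparison(
            np.nan,
            np.nan,
            reg.slope,
            reg.intercept,
            reg.rvalue,
            len(shared),
            degenerate=True,
            note="degenerate: all differences equal",
        )
    t = ttest_rel(x, y)
    return ClockComparison(
        float(t.statistic), float(t.pvalue), reg.slope, reg.intercept, reg.rvalue, len(shared)
    )


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "clock_models": ["ILN"],
    "substitution_model": "Poisson",
    "hessian_method": "outer",
    "min_len": 100,
    "subsets": [1, 6, 12, 18, 30],
    "include_prior_only": True,
    "mcmc": {"n_iter": 4000, "burn_in": 1500, "thin": 1, "seeds": [1, 2]},
    "seed": 0,
    "wgd_label": "WGD",
    "crown_labels": ["Teleostei_1", "Teleostei_2"],
    "copy_suffixes": ["_1", "_2"],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name: str, fingerprint: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(
                    f"pipeline stage {name!r} failed on {fingerprint}"
                ) from exc

    return _Ctx()


def run_pipeline(config) -> dict:
    """Run a complete dating study from a config dict or YAML path.

    Expects a study directory in the layout written by
    :func:`wgdchronos.synthetic.make_fixture` (``loci/*.fasta``,
    ``gene_trees/*.nwk``, ``species_tree.nwk``, ``calibrations.tsv``)
    plus ``study_dir``, ``out_dir``, ``duplicated_clade`` (taxon list)
    and ``outgroup_taxa`` in the config.  Stages: conformance screen,
    length filter + concatenation summary, per-locus branch-length
    approximation (BV), dating under each configured clock with duplicate
    chains and a convergence report, nested-subset runs (plus an optional
    no-data run) for the infinite-sites analysis, and the WGD-to-crown
    interval report.  Every artifact is hashed into ``manifest.json``;
    config + seed fully determine every output byte.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **config}
    cfg["mcmc"] = {**DEFAULT_CONFIG["mcmc"], **config.get("mcmc", {})}
    study = Path(cfg["study_dir"])
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    results: dict[str, object] = {"config": cfg}

    roster = TaxonRoster(
        tuple(cfg["duplicated_clade"]),
        tuple(cfg["outgroup_taxa"]),
        tuple(cfg["copy_suffixes"]),
    )

    with _stage("load", str(study)):
        species = parse_newick((study / "species_tree.nwk").read_text())
        expected = build_duplicated_topology(
            species, roster.duplicated_taxa, roster.copy_suffixes
        )
        cal_rows = read_calibration_table(study / "calibrations.tsv")
        attach_calibrations(expected, cal_rows)
        locus_paths = sorted((study / "loci").glob("*.fasta"))
        if not locus_paths:
            raise FileNotFoundError("no loci found under loci/*.fasta")

    with _stage("screen", str(study / "gene_trees")):
        rows, kept = [], []
        for p in locus_paths:
            lid = p.stem
            gt_path = study / "gene_trees" / f"{lid}.nwk"
            gt = parse_newick(gt_path.read_text(), strict_binary=False)
            verdict = screen_orthogroup(gt, expected, roster.copy_suffixes)
            rows.append({"locus": lid, "passed": verdict.passed, "reason": verdict.reason})
            if verdict.passed:
                kept.append(p)
        screen_df = pd.DataFrame(rows)
        screen_df.to_csv(out / "screen_report.csv", index=False)
        artifacts["screen_report"] = out / "screen_report.csv"
        results["screen"] = screen_df

    with _stage("concat", f"{len(kept)} screened loci"):
        loci_alns = [read_fasta_alignment(p) for p in kept]
        ohno, summary = filter_and_concatenate(loci_alns, roster, cfg["min_len"])
        concat_df = pd.DataFrame([dataclasses.asdict(summary)])
        concat_df.to_csv(out / "concat_summary.csv", index=False)
        artifacts["concat_summary"] = out / "concat_summary.csv"
        results["concat"] = summary
        results["ohnologue_set"] = ohno

    with _stage("bv", f"{len(ohno.loci)} loci"):
        model = SubstitutionModel.from_name(cfg["substitution_model"])
        approxes = []
        for aln in ohno.loci:
            full = {
                lab: aln.sequences.get(lab, "?" * aln.length)
                for lab in roster.expected_labels
            }
            from .treeio import LocusAlignment

            ap = estimate_brlens_and_hessian(
                LocusAlignment(aln.locus_id, full),
                expected,
                model,
                hessian_method=cfg["hessian_method"],
            )
            approxes.append(ap)
        write_bv(approxes, out / "loci.bv")
        artifacts["bv"] = out / "loci.bv"
        results["bv"] = approxes

    mc = cfg["mcmc"]
    hp = RateHyperpriors()
    bd = BirthDeathPrior()
    summaries = {}
    with _stage("date", f"clocks {cfg['clock_models']}"):
        for clock in cfg["clock_models"]:
            run_a, run_b, report = _mcmc.run_duplicate_chains(
                expected,
                approxes,
                seeds=tuple(mc["seeds"]),
                clock_model=clock,
                hyperpriors=hp,
                bd=bd,
                n_iter=mc["n_iter"],
                burn_in=mc["burn_in"],
                thin=mc["thin"],
            )
            summ = _mcmc.summarize_posterior(run_a)
            summ.to_csv(out / f"summary_{clock}.csv", index=False)
            report.to_csv(out / f"convergence_{clock}.csv", index=False)
            artifacts[f"summary_{clock}"] = out / f"summary_{clock}.csv"
            artifacts[f"convergence_{clock}"] = out / f"convergence_{clock}.csv"
            run_a.write_trace(out / f"trace_{clock}.tsv")
            artifacts[f"trace_{clock}"] = out / f"trace_{clock}.tsv"
            summaries[clock] = summ
            results[f"samples_{clock}"] = run_a
            results[f"convergence_{clock}"] = report
    results["summaries"] = summaries

    if len(cfg["clock_models"]) == 2:
        a, b = (summaries[c].set_index("node")["mean"] for c in cfg["clock_models"])
        comp = compare_clock_models(a.to_dict(), b.to_dict())
        pd.DataFrame([dataclasses.asdict(comp)]).to_csv(
            out / "clock_comparison.csv", index=False
        )
        artifacts["clock_comparison"] = out / "clock_comparison.csv"
        results["clock_comparison"] = comp

    with _stage("infinite_sites", f"subsets {cfg['subsets']}"):
        rng = np.random.default_rng(cfg["seed"])
        perm = rng.permutation(len(approxes))
        clock0 = cfg["clock_models"][0]
        sizes = [n for n in cfg["subsets"] if n <= len(approxes)]
        runs = {}
        if cfg["include_prior_only"]:
            runs[0] = _mcmc.run_chain(
                expected,
                [],
                clock_model=clock0,
                hyperpriors=hp,
                bd=bd,
                n_iter=mc["n_iter"],
                burn_in=mc["burn_in"],
                thin=mc["thin"],
                seed=mc["seeds"][0],
            )
        for n in sizes:
            subset = [approxes[i] for i in perm[:n]]  # sequentially nested
            runs[n] = _mcmc.run_chain(
                expected,
                subset,
                clock_model=clock0,
                hyperpriors=hp,
                bd=bd,
                n_iter=mc["n_iter"],
                burn_in=mc["burn_in"],
                thin=mc["thin"],
                seed=mc["seeds"][0],
            )
        prec_rows, reg_rows = [], []
        for n, run in sorted(runs.items()):
            summ = _mcmc.summarize_posterior(run)
            pts = [
                PrecisionPoint(
                    r["node"],
                    r["mean"] / MA_PER_UNIT,
                    (r["hpd_high"] - r["hpd_low"]) / MA_PER_UNIT,
                    n,
                )
                for _, r in summ.iterrows()
            ]
            for p in pts:
                prec_rows.append(dataclasses.asdict(p))
            root_label = _mcmc.node_name(expected, expected.root)
            if len(pts) >= 4:
                for include_root in (True, False):
                    reg = infinite_sites_regression(pts, include_root, root_label)
                    reg_rows.append(
                        {"n_loci": n, "include_root": include_root,
                         **dataclasses.asdict(reg)}
                    )
        prec_df = pd.DataFrame(prec_rows)
        reg_df = pd.DataFrame(reg_rows)
        prec_df.to_csv(out / "precision_points.csv", index=False)
        reg_df.to_csv(out / "infinite_sites.csv", index=False)
        artifacts["precision_points"] = out / "precision_points.csv"
        artifacts["infinite_sites"] = out / "infinite_sites.csv"
        results["precision_points"] = prec_df
        results["infinite_sites"] = reg_df
        results["subset_runs"] = runs

    with _stage("intervals", cfg["wgd_label"]):
        summ = summaries[cfg["clock_models"][0]].set_index("node")
        wgd_row = summ.loc[cfg["wgd_label"]]
        wgd = AgeInterval(
            round(wgd_row["hpd_high"], 2), round(wgd_row["hpd_low"], 2), cfg["wgd_label"]
        )
        int_rows = [{"label": cfg["wgd_label"], "older": wgd.older, "younger": wgd.younger,
                     "width": interval_stats(wgd).width}]
        crowns = [c for c in cfg["crown_labels"] if c in summ.index]
        if crowns:
            # mirrored crown nodes reported separately and as their average
            for c in crowns:
                row = summ.loc[c]
                ci = AgeInterval(round(row["hpd_high"], 2), round(row["hpd_low"], 2), c)
                st = interval_stats(wgd, ci)
                int_rows.append(
                    {"label": c, "older": ci.older, "younger": ci.younger,
                     "width": interval_stats(ci).width,
                     "offset_min": st.min_gap, "offset_max": st.max_gap}
                )
            avg = AgeInterval(
                round(float(np.mean([summ.loc[c]["hpd_high"] for c in crowns])), 2),
                round(float(np.mean([summ.loc[c]["hpd_low"] for c in crowns])), 2),
                "crown_average",
            )
            st = interval_stats(wgd, avg)
            int_rows.append(
                {"label": "crown_average", "older": avg.older, "younger": avg.younger,
                 "width": interval_stats(avg).width,
                 "offset_min": st.min_gap, "offset_max": st.max_gap}
            )
        int_df = pd.DataFrame(int_rows)
        int_df.to_csv(out / "interval_report.csv", index=False)
        artifacts["interval_report"] = out / "interval_report.csv"
        results["intervals"] = int_df

    manifest = {
        "seed": cfg["seed"],
        "files": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in artifacts.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
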
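"""Synthetic-study generator: chronograms, loci, rediploidization, fixtures."""

import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import kstest

from wgdchronos import priors as P
from wgdchronos import synthetic as S
from wgdchronos import treeio as T
from wgdchronos.clocks import ClockConfig


class TestChronogram:
    def test_ages_respect_topology(self, design):
        for seed in range(12):
            chron = S.simulate_chronogram(design, seed)
            for v in range(chron.n_nodes):
                p = chron.parent[v]
                if p >= 0 and not chron.is_leaf(v):
                    assert chron.ages[v] < chron.ages[p]

    def test_wgd_age_and_calibrated_nodes(self, design, chronogram):
        assert chronogram.ages[chronogram.find_node("WGD")] == design.wgd_age
        root_cal = chronogram.calibrations[chronogram.root]
        assert chronogram.ages[chronogram.root] >= root_cal.t_L

    def test_same_seed_identical(self, design):
        a = S.simulate_chronogram(design, 5)
        b = S.simulate_chronogram(design, 5)
        np.testing.assert_array_equal(a.ages, b.ages)

    def test_free_node_follows_kernel(self, design):
        # Holostei is free with a fixed parent (calibrated Neopterygii):
        # its conditional law is the kernel truncated at the parent age, so
        # the probability-integral transform must be uniform
        rng = np.random.default_rng(99)
        tree = design.duplicated_tree()
        hol, neo = None, None
        pit = []
        for _ in range(3000):
            chron = S.simulate_chronogram(design, rng)
            t_hol = chron.ages[chron.find_node("Holostei")]
            t_neo = chron.ages[chron.find_node("Neopterygii")]
            t_root = chron.ages[chron.root]
            pit.append(
                P.bd_kernel_cdf(t_hol, t_root, design.bd)
                / P.bd_kernel_cdf(t_neo, t_root, design.bd)
            )
        assert kstest(pit, "uniform").statistic < 0.02


class TestSimulateLocus:
    def test_zero_branch_lengths_identical_sequences(self, chronogram, rng):
        from wgdchronos.likelihood import SubstitutionModel

        aln = S.simulate_alignment(
            chronogram,
            np.zeros(chronogram.n_nodes - 1),
            50,
            SubstitutionModel.poisson(),
            rng,
        )
        seqs = set(aln.sequences.values())
        assert len(seqs) == 1

    def test_poisson_identity_fraction(self):
        # two leaves at total distance d: P(identical) = 1/20 + (19/20) e^{-20d/19}
        tree = T.parse_newick("(A:1,B:1);")
        tree.set_ages_from_edge_lengths()
        cfg = ClockConfig("ILN", mu_r=0.05, sigma2=0.0)
        aln = S.simulate_locus(tree, cfg, 100_000, seed_or_rng=8)
        a, b = aln.sequences["A"], aln.sequences["B"]
        frac = np.mean([x == y for x, y in zip(a, b)])
        d = 2 * 0.05 * 1.0
        expected = 1 / 20 + (19 / 20) * np.exp(-20 * d / 19)
        assert frac == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 1e5))

    def test_brlen_approx_zero_noise_exact(self, chronogram):
        cfg = ClockConfig("ILN", 0.05, 0.1)
        ap, truth = S.simulate_locus(
            chronogram, cfg, 200, mode="brlen_approx", seed_or_rng=3,
            noise_scale=0.0, return_truth=True,
        )
        np.testing.assert_allclose(ap.bhat, truth["b"])
        assert np.all(ap.grad == 0)

    def test_brlen_approx_names_match_tree(self, chronogram):
        ap = S.simulate_locus(
            chronogram, ClockConfig("ILN", 0.05, 0.1), 200,
            mode="brlen_approx", seed_or_rng=3,
        )
        expected = [chronogram.branch_name(v) for v in chronogram.canonical_branches()]
        assert ap.branch_names == expected

    def test_invalid_sites(self, chronogram):
        with pytest.raises(ValueError, match="n_sites"):
            S.simulate_locus(chronogram, ClockConfig(), 0)


class TestRediploidization:
    def test_no_conversion_dates_the_wgd(self):
        params = S.WGDSimParams(t_wgd=2.8, t_r=2.0, conversion_rate=0.0)
        ages, _ = S.simulate_wgd_rediploidization(params, 1000, 1)
        assert np.all(ages == 2.8)

    def test_fast_conversion_dates_rediploidization(self):
        params = S.WGDSimParams(t_wgd=2.8, t_r=2.0, conversion_rate=1e4)
        ages, _ = S.simulate_wgd_rediploidization(params, 1000, 1)
        assert np.all(ages >= 2.0)
        assert np.quantile(ages, 0.99) < 2.01

    def test_mean_age_matches_brute_force_oracle(self):
        # oracle: simulate explicit conversion events in the tetrasomic
        # window and take the most recent one, per site
        params = S.WGDSimParams(t_wgd=2.8, t_r=2.0, conversion_rate=1.0)
        n = 100_000
        ages, _ = S.simulate_wgd_rediploidization(params, n, 7)
        rng = np.random.default_rng(17)
        delta = params.t_wgd - params.t_r
        oracle = np.empty(n)
        n_events = rng.poisson(params.conversion_rate * delta, n)
        for i, k in enumerate(n_events):
            if k == 0:
                oracle[i] = params.t_wgd
            else:
                oracle[i] = params.t_r + rng.random(k).min() * delta
        se = np.sqrt(oracle.var() / n + ages.var() / n)
        assert ages.mean() == pytest.approx(oracle.mean(), abs=4 * se)

    def test_sequences_diverge_from_site_ages(self):
        params = S.WGDSimParams(t_wgd=2.8, t_r=2.0, conversion_rate=1.0, subst_rate=0.05)
        ages, aln = S.simulate_wgd_rediploidization(params, 100_000, 5)
        a, b = aln.sequences["copy_1"], aln.sequences["copy_2"]
        frac = np.mean([x == y for x, y in zip(a, b)])
        d = 2 * params.subst_rate * ages
        expected = np.mean(1 / 20 + (19 / 20) * np.exp(-20 * d / 19))
        assert frac == pytest.approx(expected, abs=0.01)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            S.WGDSimParams(t_wgd=2.0, t_r=2.8, conversion_rate=1.0)


class TestFixture:
    @pytest.fixture(scope="class")
    def fixture_dir(self, tmp_path_factory, design):
        out = tmp_path_factory.mktemp("study")
        manifest = S.make_fixture(design, out, seed=1)
        return out, manifest

    def test_reference_design_statistics(self, fixture_dir, design):
        out, manifest = fixture_dir
        loci = [
            T.read_fasta_alignment(p) for p in sorted((out / "loci").glob("*.fasta"))
        ]
        assert len(loci) == 30
        _, summary = T.filter_and_concatenate(loci, design.roster())
        assert summary.n_sequences_total == 537  # 30 * 18 - 3
        assert summary.n_complete_loci == 27
        assert all(l.length >= 100 for l in loci)
        # brute-force recount
        assert summary.n_columns_total == sum(l.length for l in loci)

    def test_gene_trees_pass_screen(self, fixture_dir, design):
        out, _ = fixture_dir
        expected = design.duplicated_tree()
        for p in sorted((out / "gene_trees").glob("*.nwk"))[:5]:
            gt = T.parse_newick(p.read_text(), strict_binary=False)
            assert T.screen_orthogroup(gt, expected).passed

    def test_truth_tables(self, fixture_dir):
        out, manifest = fixture_dir
        nodes = manifest["truth_nodes"]
        assert set(nodes.columns) == {"node", "true_age_Ma"}
        assert (nodes["true_age_Ma"] > 0).all()
        assert "WGD" in set(nodes["node"])
        loci = manifest["truth_loci"]
        assert (loci["mu_r"] > 0).all() and (loci["sigma2"] > 0).all()

    def test_regeneration_byte_identical(self, tmp_path, design):
        small = S.default_design(n_loci=4)
        S.make_fixture(small, tmp_path / "a", seed=3)
        S.make_fixture(small, tmp_path / "b", seed=3)

        def digest(root):
            out = {}
            for p in sorted(Path(root).rglob("*")):
                if p.is_file():
                    out[p.relative_to(root)] = hashlib.sha256(p.read_bytes()).hexdigest()
            return out

        assert digest(tmp_path / "a") == digest(tmp_path / "b")
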
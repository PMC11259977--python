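"""Pruning likelihood, MLE branch lengths + Hessian, approximate likelihood, BV I/O."""

import numpy as np
import pytest
from scipy.linalg import expm

from wgdchronos import likelihood as L
from wgdchronos import treeio as T


def random_alignment(labels, n_sites, rng):
    return T.LocusAlignment(
        "t", {lab: "".join(rng.choice(list(L.AA_ALPHABET), n_sites)) for lab in labels}
    )


def enumeration_loglik(aln, tree, b, model):
    """Brute-force likelihood: explicit recursion with expm transition
    matrices, averaging over gamma categories — independent of the
    pruning engine."""
    order = tree.canonical_branches()
    rates = model.category_rates()
    pi = model.freqs
    codes = {
        lab: [L.AA_ALPHABET.index(c) if c in L.AA_ALPHABET else None for c in seq]
        for lab, seq in aln.sequences.items()
    }
    P = {
        (k, v): expm(model.rate_matrix * b[i] * r)
        for k, r in enumerate(rates)
        for i, v in enumerate(order)
    }
    total = 0.0
    for s in range(aln.length):
        site = 0.0
        for k in range(len(rates)):
            def down(v):
                if tree.is_leaf(v):
                    vec = np.ones(20)
                    c = codes[tree.labels[v]][s]
                    if c is not None:
                        vec = np.zeros(20)
                        vec[c] = 1.0
                    return vec
                out = np.ones(20)
                for ch in tree.children[v]:
                    out = out * (P[(k, ch)] @ down(ch))
                return out
            site += pi @ down(tree.root)
        total += np.log(site / len(rates))
    return total


class TestPruning:
    def test_identical_sequences_zero_lengths(self):
        tree = T.parse_newick("(A,B);")
        aln = T.LocusAlignment("x", {"A": "ACDEF", "B": "ACDEF"})
        got = L.pruning_loglik(aln, tree, np.zeros(2), L.SubstitutionModel.poisson())
        assert got == pytest.approx(5 * np.log(1 / 20), rel=1e-12)

    def test_two_sequence_closed_form(self):
        # one differing site at total distance d under Poisson
        tree = T.parse_newick("(A,B);")
        aln = T.LocusAlignment("x", {"A": "A", "B": "R"})
        model = L.SubstitutionModel.poisson()
        d = 0.3
        got = L.pruning_loglik(aln, tree, np.array([0.1, 0.2]), model)
        # transition-matrix exponentiation oracle at total distance d
        P = expm(model.rate_matrix * d)
        assert got == pytest.approx(np.log(P[0, 1] / 20), rel=1e-10)

    @pytest.mark.parametrize(
        "nwk,model_name,gamma",
        [
            ("((A,B),C);", "poisson", None),
            ("((A,B),(C,D));", "LG", None),
            ("((A,B),(C,D));", "poisson", 0.5),
            ("(((A,B),C),(D,E));", "WAG", 1.2),
            ("((A,B),(C,(D,E)));", "JTT", None),
        ],
    )
    def test_matches_enumeration_oracle(self, nwk, model_name, gamma, rng):
        tree = T.parse_newick(nwk)
        model = L.SubstitutionModel.from_name(model_name, gamma_shape=gamma)
        aln = random_alignment(tree.leaf_labels, 4, rng)
        b = rng.uniform(0.02, 0.7, tree.n_nodes - 1)
        got = L.pruning_loglik(aln, tree, b, model)
        want = enumeration_loglik(aln, tree, b, model)
        assert got == pytest.approx(want, abs=1e-9)

    def test_missing_data_marginalized(self, rng):
        # a fully missing sequence must not change the likelihood of the rest
        tree3 = T.parse_newick("((A,B),C);")
        model = L.SubstitutionModel.from_name("LG")
        aln3 = T.LocusAlignment("x", {"A": "ACDE", "B": "AC-E", "C": "????"})
        b = np.array([0.1, 0.2, 0.15, 0.3])
        got = L.pruning_loglik(aln3, tree3, b, model)
        want = enumeration_loglik(aln3, tree3, b, model)
        assert got == pytest.approx(want, abs=1e-9)

    def test_reroot_invariance(self, rng):
        # reversible model: likelihood identical for any rooting of the
        # same unrooted tree with the same edge lengths
        model = L.SubstitutionModel.from_name("LG")
        aln = random_alignment(list("ABCD"), 6, rng)
        t1 = T.parse_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.15);")
        # same unrooted tree re-rooted on the A edge, path lengths preserved
        t2 = T.parse_newick("((B:0.2,(C:0.3,D:0.4):0.2):0.1,A:0.0);")
        def ll(t):
            order = t.canonical_branches()
            b = np.array([t.edge_lengths[v] for v in order])
            return L.pruning_loglik(aln, t, b, model)
        assert ll(t1) == pytest.approx(ll(t2), abs=1e-9)

    def test_label_mismatch_reported(self, rng):
        tree = T.parse_newick("((A,B),C);")
        aln = random_alignment(["A", "B", "X"], 3, rng)
        with pytest.raises(ValueError, match="label mismatch"):
            L.pruning_loglik(aln, tree, np.ones(4) * 0.1, L.SubstitutionModel.poisson())

    def test_analytic_gradient_matches_fd(self, rng):
        tree = T.parse_newick("((A,B),(C,D));")
        model = L.SubstitutionModel.from_name("LG", gamma_shape=0.8)
        aln = random_alignment(tree.leaf_labels, 30, rng)
        b = rng.uniform(0.05, 0.5, 6)
        eng = L.PruningEngine(aln, tree, model)
        _, g = eng.loglik_and_grad(b)
        h = 1e-6
        for j in range(6):
            e = np.zeros(6)
            e[j] = h
            fd = (eng.loglik(b + e) - eng.loglik(b - e)) / (2 * h)
            assert g[j] == pytest.approx(fd, abs=1e-5)


class TestEstimate:
    def test_two_sequence_distance_closed_form(self, rng):
        # k differences in n sites: 20-state Jukes-Cantor-type inversion
        n, k = 400, 60
        sA = "".join(rng.choice(list(L.AA_ALPHABET), n))
        sB = list(sA)
        for p in rng.choice(n, k, replace=False):
            sB[p] = rng.choice([c for c in L.AA_ALPHABET if c != sB[p]])
        aln = T.LocusAlignment("x", {"A": sA, "B": "".join(sB)})
        tree = T.parse_newick("(A,B);")
        ap = L.estimate_brlens_and_hessian(
            aln, tree, L.SubstitutionModel.poisson(), hessian_method="outer"
        )
        closed = -(19 / 20) * np.log(1 - (20 / 19) * (k / n))
        assert ap.bhat.sum() == pytest.approx(closed, rel=1e-5)

    @pytest.fixture(scope="class")
    def six_leaf_fit(self):
        from wgdchronos.synthetic import simulate_alignment

        rng = np.random.default_rng(11)
        tree = T.parse_newick("(((A,B),C),((D,E),F));")
        model = L.SubstitutionModel.poisson()
        b_true = rng.uniform(0.05, 0.4, tree.n_nodes - 1)
        aln = simulate_alignment(tree, b_true, 5000, model, rng)
        ap = L.estimate_brlens_and_hessian(aln, tree, model, hessian_method="fd")
        return tree, model, b_true, aln, ap

    def test_simulation_consistency(self, six_leaf_fit):
        _, _, b_true, _, ap = six_leaf_fit
        se = np.sqrt(np.diag(np.linalg.inv(-ap.hessian)))
        assert np.all(np.abs(ap.bhat - b_true) < 3 * se)

    def test_hessian_negative_semidefinite(self, six_leaf_fit):
        _, _, _, _, ap = six_leaf_fit
        eig = np.linalg.eigvalsh(ap.hessian)
        assert eig.max() < 1e-6 * abs(eig.min())

    def test_outer_product_close_to_fd(self, six_leaf_fit):
        tree, model, _, aln, ap_fd = six_leaf_fit
        ap_outer = L.estimate_brlens_and_hessian(aln, tree, model, hessian_method="outer")
        # empirical Fisher ~ observed information at this sample size
        scale = np.abs(np.diag(ap_fd.hessian))
        assert np.all(
            np.abs(np.diag(ap_outer.hessian) - np.diag(ap_fd.hessian)) < 0.25 * scale
        )

    def test_gradient_small_at_interior_mle(self, six_leaf_fit):
        _, _, _, aln, ap = six_leaf_fit
        assert np.abs(ap.grad).max() < 1e-3 * aln.length


class TestApproxLoglik:
    @pytest.fixture(scope="class")
    def approx(self):
        rng = np.random.default_rng(2)
        names = [f"b{i}" for i in range(4)]
        H = -np.eye(4) * 50.0
        H[0, 1] = H[1, 0] = 5.0
        return L.BranchLengthApprox(
            "x", names, rng.uniform(0.1, 0.3, 4), np.zeros(4), H
        )

    def test_zero_at_expansion_point(self, approx):
        assert L.approx_loglik(approx.bhat, approx) == 0.0

    def test_symmetric_when_gradient_zero(self, approx, rng):
        d = rng.normal(0, 0.05, 4)
        assert L.approx_loglik(approx.bhat + d, approx) == pytest.approx(
            L.approx_loglik(approx.bhat - d, approx)
        )

    def test_dimension_mismatch(self, approx):
        with pytest.raises(ValueError, match="does not match"):
            L.approx_loglik(np.ones(3), approx)

    def test_tracks_exact_loglik_near_mle(self):
        from wgdchronos.synthetic import simulate_alignment

        rng = np.random.default_rng(4)
        tree = T.parse_newick("(((A,B),C),((D,E),F));")
        model = L.SubstitutionModel.poisson()
        nb = tree.n_nodes - 1
        b_true = rng.uniform(0.08, 0.35, nb)
        aln = simulate_alignment(tree, b_true, 2000, model, rng)
        ap = L.estimate_brlens_and_hessian(aln, tree, model, hessian_method="fd")
        eng = L.PruningEngine(aln, tree, model)
        ll_hat = eng.loglik(ap.bhat)
        # perturb only along informative eigendirections: the split of the
        # root edge between its two child branches is flat for a
        # reversible model (only the sum is identified), so H is singular
        # there and "2 SE" is undefined in that direction
        eig, V = np.linalg.eigh(-ap.hessian)
        keep = eig > 1e-3 * eig.max()
        for _ in range(10):
            z = rng.standard_normal(keep.sum())
            z *= rng.uniform(0, 2) / np.linalg.norm(z)  # within 2 SE
            b = np.maximum(ap.bhat + V[:, keep] @ (z / np.sqrt(eig[keep])), 1e-6)
            exact_diff = eng.loglik(b) - ll_hat
            assert abs(L.approx_loglik(b, ap) - exact_diff) < 0.5


class TestBVIO:
    def _make(self, rng, lid, n=5):
        names = [f"x{i}+1" for i in range(n)]
        A = rng.normal(0, 1, (n, n))
        H = -(A @ A.T) - n * np.eye(n)
        return L.BranchLengthApprox(
            lid, names, rng.uniform(0.01, 0.5, n), rng.normal(0, 1e-4, n), H
        )

    def test_round_trip(self, tmp_path, rng):
        aps = [self._make(rng, "l1"), self._make(rng, "l2")]
        path = tmp_path / "loci.bv"
        L.write_bv(aps, path)
        back = L.read_bv(path)
        for a, b in zip(aps, back):
            assert a.locus_id == b.locus_id
            assert a.branch_names == b.branch_names
            np.testing.assert_allclose(a.bhat, b.bhat, rtol=1e-12)
            np.testing.assert_allclose(a.grad, b.grad, rtol=1e-12)
            np.testing.assert_allclose(a.hessian, b.hessian, rtol=1e-12)
        # write(read(x)) is stable text
        path2 = tmp_path / "again.bv"
        L.write_bv(back, path2)
        assert path.read_text() == path2.read_text()

    def test_malformed_hessian_block(self, tmp_path, rng):
        path = tmp_path / "bad.bv"
        L.write_bv([self._make(rng, "l1")], path)
        lines = path.read_text().splitlines()
        del lines[-3]  # drop one Hessian row
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError):
            L.read_bv(path)

    def test_asymmetric_hessian_warns_and_symmetrizes(self, rng):
        names = ["a+1", "b+1"]
        H = np.array([[-3.0, 0.5], [0.2, -3.0]])
        with pytest.warns(UserWarning, match="asymmetry"):
            ap = L.BranchLengthApprox("x", names, [0.1, 0.2], [0.0, 0.0], H)
        assert np.allclose(ap.hessian, ap.hessian.T)
        assert ap.hessian[0, 1] == pytest.approx(0.35)

    def test_ordering_mismatch_names_branch(self, tmp_path, rng):
        ap = self._make(rng, "l1")
        path = tmp_path / "x.bv"
        L.write_bv([ap], path)
        wrong = list(ap.branch_names)
        wrong[2] = "other+9"
        with pytest.raises(ValueError, match="x2"):
            L.read_bv(path, expected_branch_names=wrong)

    def test_header_required(self, tmp_path):
        path = tmp_path / "x.bv"
        path.write_text("not a bv file\n")
        with pytest.raises(ValueError, match="BV v1"):
            L.read_bv(path)
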
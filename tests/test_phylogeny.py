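"""GTR+I+G likelihood, NJ, fitting, NNI search, bootstrap, simulation."""

import numpy as np
import pytest

from mitoprofile.align import Alignment, concatenate
from mitoprofile.model import MitoError
from mitoprofile.phylogeny import (
    PhyloModel,
    bootstrap,
    fit,
    jc_distance,
    loglik,
    nj,
    nj_tree,
    nni_search,
    search,
    simulate,
    JC_SATURATION_CAP,
)
from mitoprofile.tree import from_newick, random_bifurcating
from mitoprofile.validation import brute_force_loglik


@pytest.fixture(scope="module")
def small_model():
    return PhyloModel(
        freqs=np.array([0.31, 0.19, 0.16, 0.34]),
        exch=np.array([1.4, 5.0, 1.1, 0.9, 6.0, 1.0]),
        p_inv=0.15,
        alpha=0.6,
    )


class TestModel:
    def test_rate_matrix_rows_sum_to_zero(self, small_model):
        q = small_model.q_matrix()
        assert np.allclose(q.sum(axis=1), 0.0)

    def test_mean_rate_normalized_over_mixture(self, small_model):
        q = small_model.q_matrix()
        mu = -(small_model.freqs * np.diag(q)).sum()
        rates = small_model.category_rates()
        mixture_mean = small_model.p_inv * 0 + (1 - small_model.p_inv) * rates.mean()
        assert mu * mixture_mean == pytest.approx(1.0, abs=1e-10)

    def test_gt_exchangeability_fixed_to_one(self):
        m = PhyloModel(exch=np.array([2.0, 4.0, 2.0, 2.0, 4.0, 2.0]))
        assert m.exch[5] == 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(MitoError):
            PhyloModel(p_inv=1.0)
        with pytest.raises(MitoError):
            PhyloModel(alpha=-1)
        with pytest.raises(MitoError):
            PhyloModel(freqs=np.array([0.5, 0.5, 0.5, 0.5]))


class TestConcatenate:
    def test_supermatrix_lengths_and_partitions(self):
        a = Alignment({"x": "ACGT", "y": "ACGA"})
        b = Alignment({"x": "GG", "y": "GT"})
        sup = concatenate({"g1": a, "g2": b})
        assert sup.length == 6
        assert sup.partitions == {"g1": (0, 4), "g2": (4, 6)}

    def test_missing_taxon_gap_filled(self):
        a = Alignment({"x": "ACGT", "y": "ACGA"})
        b = Alignment({"x": "GG"})
        sup = concatenate({"g1": a, "g2": b})
        assert sup["y"] == "ACGA--"

    def test_empty_taxon_intersection_rejected(self):
        with pytest.raises(MitoError, match="share no taxa"):
            concatenate({"g1": Alignment({"x": "AC"}), "g2": Alignment({"y": "AC"})})


class TestJcDistance:
    def test_identical_sequences(self):
        assert jc_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_at_p_010(self):
        a = "A" * 900 + "C" * 100
        b = "A" * 1000
        assert jc_distance(a, b) == pytest.approx(0.10732563, abs=1e-6)

    def test_saturation_capped(self):
        assert jc_distance("AAAA", "CCCC") == JC_SATURATION_CAP

    def test_pairwise_deletion_of_gaps(self):
        assert jc_distance("AC-T", "ACNT") == 0.0

    def test_no_comparable_sites_is_error(self):
        with pytest.raises(MitoError):
            jc_distance("--", "AC")


class TestNeighborJoining:
    def test_additive_distances_recover_topology(self):
        # distances generated on ((A,B),(C,D)) with known branch lengths
        tree = from_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.3):0.07);")
        taxa = ["A", "B", "C", "D"]
        paths = {"A": 0.1, "B": 0.2, "C": 0.15, "D": 0.3}

        def dist(u, v):
            extra = 0.12 if {u, v} in ({"A", "B"}, {"C", "D"}) else 0.0
            base = paths[u] + paths[v]
            return base if extra else base + 0.12

        d = np.zeros((4, 4))
        for i, u in enumerate(taxa):
            for j, v in enumerate(taxa):
                if i != j:
                    d[i, j] = dist(u, v)
        out = nj(d, taxa)
        assert out.splits() == tree.splits()

    def test_three_taxa_unique_topology(self):
        d = np.array([[0, 0.2, 0.3], [0.2, 0, 0.25], [0.3, 0.25, 0]])
        t = nj(d, ["a", "b", "c"])
        assert sorted(t.taxa()) == ["a", "b", "c"] and t.splits() == set()

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(0)
        tree = random_bifurcating(list("ABCDEF"), rng)
        aln = simulate(tree, PhyloModel(), 2000, rng)
        t1 = nj_tree(aln)
        perm = Alignment({k: aln[k] for k in reversed(aln.taxa)})
        t2 = nj_tree(perm)
        assert t1.splits() == t2.splits()

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1.0, 2], [1, 0, 2], [2, 2.5, 0]])
        with pytest.raises(MitoError):
            nj(d, ["a", "b", "c"])


class TestLoglik:
    def test_matches_brute_force_enumeration(self, small_model):
        rng = np.random.default_rng(4)
        tree = from_newick("((A:0.12,B:0.31):0.14,C:0.23,D:0.08);")
        aln = simulate(tree, small_model, 12, rng)
        assert loglik(tree, aln, small_model) == pytest.approx(
            brute_force_loglik(tree, aln, small_model), abs=1e-8
        )

    def test_invariant_under_rerooting(self, small_model):
        rng = np.random.default_rng(5)
        tree = from_newick("((A:0.1,B:0.3):0.2,(C:0.15,D:0.25):0.1,E:0.4);")
        aln = simulate(tree, small_model, 200, rng)
        ll = loglik(tree, aln, small_model)
        rerooted = from_newick("((C:0.15,D:0.25):0.1,(A:0.1,B:0.3):0.2,E:0.4);")
        assert loglik(rerooted, aln, small_model) == pytest.approx(ll, abs=1e-9)
        swapped = from_newick("((B:0.3,A:0.1):0.2,E:0.4,(D:0.25,C:0.15):0.1);")
        assert loglik(swapped, aln, small_model) == pytest.approx(ll, abs=1e-9)

    def test_large_alpha_limit_is_single_rate(self, small_model):
        rng = np.random.default_rng(6)
        tree = from_newick("((A:0.1,B:0.3):0.2,C:0.15,D:0.25);")
        aln = simulate(tree, small_model, 50, rng)
        big = PhyloModel(freqs=small_model.freqs, exch=small_model.exch, p_inv=0.0, alpha=1e8)
        single = PhyloModel(freqs=small_model.freqs, exch=small_model.exch, p_inv=0.0, alpha=1.0, k=1)
        assert loglik(tree, aln, big) == pytest.approx(loglik(tree, aln, single), abs=1e-6)

    def test_taxon_mismatch_rejected(self, small_model):
        tree = from_newick("((A:0.1,B:0.3):0.2,C:0.15,D:0.25);")
        aln = Alignment({"A": "ACGT", "B": "ACGT", "C": "ACGT", "X": "ACGT"})
        with pytest.raises(MitoError, match="taxa"):
            loglik(tree, aln, small_model)


class TestFit:
    def test_alpha_recovery_and_pinv_zero_truth(self):
        tree = from_newick("((A:0.12,B:0.18):0.07,(C:0.1,D:0.22):0.05,E:0.15);")
        truth = PhyloModel(
            freqs=np.array([0.3, 0.18, 0.17, 0.35]),
            exch=np.array([1.5, 8.0, 2.0, 1.0, 10.0, 1.0]),
            p_inv=0.0,
            alpha=0.5,
        )
        aln = simulate(tree, truth, 5000, np.random.default_rng(1))
        result = fit(tree, aln, max_rounds=4)
        assert 0.35 <= result.model.alpha <= 0.70
        assert result.model.p_inv < 0.05

    def test_refit_at_optimum_is_fixed_point(self, small_model):
        rng = np.random.default_rng(9)
        tree = from_newick("((A:0.1,B:0.3):0.2,C:0.15,D:0.25);")
        aln = simulate(tree, small_model, 800, rng)
        first = fit(tree, aln, max_rounds=8)
        second = fit(first.tree, aln, first.model, max_rounds=2)
        assert second.loglik - first.loglik < 0.05
        assert second.loglik >= first.loglik - 1e-9  # never decreases


class TestSearchAndBootstrap:
    def test_six_taxon_recovery_with_support(self):
        rng = np.random.default_rng(12)
        truth = from_newick(
            "((A:0.1,B:0.12):0.06,((C:0.09,D:0.11):0.05,(E:0.1,F:0.08):0.07):0.04);"
        )
        model = PhyloModel(freqs=np.array([0.3, 0.2, 0.17, 0.33]),
                           exch=np.array([1.5, 6.0, 1.5, 1.0, 8.0, 1.0]),
                           p_inv=0.1, alpha=0.7)
        aln = simulate(truth, model, 2000, rng)
        result = search(aln, fit_rounds=2)
        assert result.tree.splits() == truth.splits()
        bt = bootstrap(aln, result.model, b=20, seed=5, tree=result.tree)
        supports = [n.support for n in bt.postorder() if n.support is not None]
        assert supports and all(0 <= s <= 100 for s in supports)
        assert np.mean(supports) >= 80

    def test_bootstrap_deterministic_for_seed(self):
        rng = np.random.default_rng(13)
        truth = from_newick("((A:0.1,B:0.12):0.08,(C:0.09,D:0.11):0.06,E:0.1);")
        aln = simulate(truth, PhyloModel(alpha=1.0), 500, rng)
        model = PhyloModel()
        t1 = bootstrap(aln, model, b=10, seed=42)
        t2 = bootstrap(aln, model, b=10, seed=42)
        s1 = sorted(n.support for n in t1.postorder() if n.support is not None)
        s2 = sorted(n.support for n in t2.postorder() if n.support is not None)
        assert s1 == s2

    def test_identical_sequences_flagged_star_like(self):
        aln = Alignment({t: "ACGTACGTACGTACGTACGT" * 5 for t in "ABCDE"})
        with pytest.raises(MitoError, match="star"):
            bootstrap(aln, PhyloModel(), b=2, seed=1)

    def test_bootstrap_requires_positive_b(self):
        aln = Alignment({t: "ACGT" for t in "ABCD"})
        with pytest.raises(MitoError, match="B >= 1"):
            bootstrap(aln, PhyloModel(), b=0, seed=1)

    def test_nni_never_decreases_loglik(self, small_model):
        rng = np.random.default_rng(14)
        truth = from_newick("((A:0.1,B:0.12):0.08,(C:0.09,D:0.11):0.06,E:0.1);")
        aln = simulate(truth, small_model, 400, rng)
        start = nj_tree(aln)
        ll0 = loglik(start, aln, small_model)
        _, ll1 = nni_search(start, aln, small_model)
        assert ll1 >= ll0 - 1e-9


class TestSimulate:
    def test_zero_branch_lengths_give_identical_sequences(self, small_model):
        tree = from_newick("((A:0,B:0):0,C:0,D:0);")
        aln = simulate(tree, small_model, 100, np.random.default_rng(2))
        assert len({aln[t] for t in aln.taxa}) == 1

    def test_stationary_frequencies_recovered(self, small_model):
        tree = from_newick("(A:0.05,B:0.05);")
        aln = simulate(tree, small_model, 50_000, np.random.default_rng(3))
        seq = aln["A"]
        for base, pi in zip("ACGT", small_model.freqs):
            assert abs(seq.count(base) / len(seq) - pi) < 0.02

    def test_jc_distance_recovered_under_jc_truth(self):
        tree = from_newick("(A:0.05,B:0.05);")
        aln = simulate(tree, PhyloModel(), 50_000, np.random.default_rng(4))
        assert abs(jc_distance(aln["A"], aln["B"]) - 0.1) < 0.01
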
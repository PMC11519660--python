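"""K2P distances, nucleotide diversity, NG86 Ka/Ks, saturation, NJ."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.composition_stats import AA_OF, STOP_CODONS
from mitocomp.molevol import (
    AlignmentError,
    SaturationError,
    count_pq,
    distance_matrix,
    k2p_distance,
    kaks_summary,
    ng86_kaks,
    ng86_site_counts,
    nj_tree,
    saturation_test,
    sliding_pi,
)
from mitocomp.molevol import _path_counts, _syn_fraction
from mitocomp.synthetic import evolve_pair


class TestCountPQ:
    def test_identical(self):
        assert count_pq("AAAA", "AAAA") == (0.0, 0.0, 4)

    def test_single_transition(self):
        assert count_pq("AG", "GG") == (0.5, 0.0, 2)

    def test_pure_transversions(self):
        assert count_pq("AT", "TA") == (0.0, 1.0, 2)

    def test_pairwise_deletion(self):
        P, Q, n = count_pq("A-GN", "AAGC")
        assert n == 2 and P == 0.0 and Q == 0.0

    def test_all_gapped_rejected(self):
        with pytest.raises(AlignmentError):
            count_pq("--", "AA")


class TestK2P:
    def test_zero(self):
        assert k2p_distance(0.0, 0.0) == 0.0

    def test_closed_form_value(self):
        # -0.5 ln(0.75) - 0.25 ln(0.9), evaluated independently
        assert k2p_distance(0.1, 0.05) == pytest.approx(0.170181, abs=1e-6)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance(0.5, 0.0)

    @given(
        st.floats(0.0, 0.35), st.floats(0.0, 0.35),
        st.floats(0.001, 0.05), st.floats(0.001, 0.05),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_monotone_in_p_and_q(self, p, q, dp, dq):
        if 2 * (p + dp) + (q + dq) >= 0.999 or 2 * (q + dq) >= 0.999:
            return
        assert k2p_distance(p + dp, q) >= k2p_distance(p, q)
        assert k2p_distance(p, q + dq) >= k2p_distance(p, q)

    def test_k2p_at_least_p_distance(self):
        for p, q in [(0.05, 0.02), (0.1, 0.1), (0.2, 0.05)]:
            assert k2p_distance(p, q) >= p + q


class TestDistanceMatrix:
    def test_identical_pair_is_zero(self):
        m = distance_matrix({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert (m.to_numpy() == 0).all()

    def test_symmetric_with_zero_diagonal(self):
        aln = {"a": "ACGTACGTAC", "b": "ACGAACGTAC", "c": "TCGTACGAAC"}
        m = distance_matrix(aln)
        assert np.allclose(m, m.T) and np.allclose(np.diag(m), 0)

    def test_recovers_simulated_divergence(self):
        """Mean K2P estimate over replicates falls within 3 standard
        errors of the simulated divergence."""
        rng = np.random.default_rng(42)
        base = "".join(np.array(list("ACGT"))[rng.integers(4, size=10_000)])
        est = []
        for s in range(60):
            mut = evolve_pair(base, 0.08, kappa=4.0, seed=1000 + s)
            P, Q, _ = count_pq(base, mut)
            est.append(k2p_distance(P, Q))
        se = np.std(est, ddof=1) / math.sqrt(len(est))
        assert abs(np.mean(est) - 0.08) < 3 * se

    def test_saturated_cell_is_nan_not_fatal(self):
        # maximally divergent pair: every site a transition
        aln = {"a": "A" * 50, "b": "G" * 50, "c": "A" * 50}
        with pytest.warns(UserWarning):
            m = distance_matrix(aln)
        assert math.isnan(m.loc["a", "b"]) and m.loc["a", "c"] == 0.0


class TestSlidingPi:
    def test_identical_sequences_zero(self):
        out = sliding_pi({"a": "ACGT" * 50, "b": "ACGT" * 50}, 100, 20)
        assert all(w.pi == 0.0 for w in out)

    def test_single_difference_hand_value(self):
        a = "A" * 100
        b = "A" * 99 + "T"
        out = sliding_pi({"a": a, "b": b}, 100, 10)
        assert out[0].pi == pytest.approx(0.01)

    def test_four_sequences_all_distinct_at_one_site(self):
        seqs = {x: "A" * 99 + x for x in "ACGT"}
        out = sliding_pi(seqs, 100, 100)
        # every one of the 6 pairs differs at exactly that site
        assert out[0].pi == pytest.approx(0.01)

    def test_whole_alignment_window_equals_global_pi(self):
        rng = np.random.default_rng(3)
        seqs = {
            f"s{i}": "".join(np.array(list("ACGT"))[rng.integers(4, size=300)])
            for i in range(4)
        }
        [whole] = sliding_pi(seqs, 300, 999)
        pairs = list(itertools.combinations(seqs.values(), 2))
        manual = np.mean(
            [sum(x != y for x, y in zip(a, b)) / 300 for a, b in pairs]
        )
        assert whole.pi == pytest.approx(manual)

    def test_gap_only_window_is_undefined(self):
        out = sliding_pi({"a": "----" + "ACGT", "b": "AAAA" + "ACGT"}, 4, 4)
        assert out[0].pi is None and out[1].pi == 0.0


def _brute_force_pathways(c1, c2):
    """Independent oracle: enumerate substitution orderings directly."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if AA_OF[nxt] == AA_OF[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    return results


class TestNG86:
    def test_identical_cds(self):
        ev = ng86_kaks("ATGCTACTA", "ATGCTACTA")
        assert ev.Ka == 0.0 and ev.Ks == 0.0 and not ev.omega_defined

    def test_single_synonymous_change(self):
        a = "ATG" + "CTA" * 29
        b = "ATG" + "CTG" + "CTA" * 28  # Leu -> Leu at a third position
        ev = ng86_kaks(a, b)
        assert ev.Ka == 0.0 and ev.Ks > 0.0

    def test_site_counts_sum_to_three_per_codon(self):
        rng = np.random.default_rng(5)
        sense = sorted(set(AA_OF) - STOP_CODONS)
        cds = "".join(rng.choice(sense, size=40))
        S, N = ng86_site_counts(cds)
        assert S + N == pytest.approx(3 * 40)

    def test_internal_stop_rejected(self):
        with pytest.raises(AlignmentError):
            ng86_kaks("ATGTAACTA", "ATGTAACTA")

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            ng86_kaks("ATGCTA", "ATGCTACTA")

    def test_pathway_counts_match_enumeration_oracle(self):
        """Pathway-averaged difference counts equal brute-force
        enumeration over substitution orderings for random codon pairs."""
        rng = np.random.default_rng(11)
        sense = sorted(set(AA_OF) - STOP_CODONS)
        checked = 0
        while checked < 300:
            c1, c2 = rng.choice(sense, size=2)
            oracle = _brute_force_pathways(c1, c2)
            if not oracle:
                continue
            sd, nd = _path_counts(c1, c2)
            assert sd == pytest.approx(np.mean([o[0] for o in oracle]))
            assert nd == pytest.approx(np.mean([o[1] for o in oracle]))
            checked += 1

    def test_syn_fraction_known_codon(self):
        # CTA (Leu): third position fully synonymous under the mito code,
        # first position T->C also Leu (TTA); 3 of 9 changes silent... check
        s, n = _syn_fraction("CTA")
        assert s + n == pytest.approx(3.0)
        assert s == pytest.approx(1.0 + 1.0 / 3.0)


class TestKaksSummary:
    def test_two_genomes_single_pair_sd_zero(self):
        g = {
            "s1": {"ND1": "ATGCTACTA", "ND2": "ATGAAACCC"},
            "s2": {"ND1": "ATGCTGCTA", "ND2": "ATGAAGCCC"},
        }
        df = kaks_summary(g)
        assert (df["sd_Ka"] == 0).all() and (df["n_pairs"] == 1).all()

    def test_undefined_omega_counted(self):
        g = {"s1": {"ND1": "ATGCTACTA"}, "s2": {"ND1": "ATGCTACTA"}}
        df = kaks_summary(g)
        assert df.loc["ND1", "n_omega_excluded"] == 1


class TestSaturation:
    def test_identical_alignment_iss_zero(self):
        aln = {f"s{i}": "ACGTACGTAC" * 20 for i in range(4)}
        res = saturation_test(aln, reps=20, seed=1)
        assert res.Iss == 0.0
        assert res.Iss < res.Iss_c_sim

    def test_random_alignment_saturated(self):
        rng = np.random.default_rng(7)
        aln = {
            f"s{i}": "".join(np.array(list("ACGT"))[rng.integers(4, size=1000)])
            for i in range(8)
        }
        res = saturation_test(aln, reps=30, seed=2)
        assert res.Iss >= res.Iss_c_sim

    def test_low_divergence_not_saturated(self):
        rng = np.random.default_rng(9)
        base = "".join(np.array(list("ACGT"))[rng.integers(4, size=1000)])
        aln = {f"s{i}": evolve_pair(base, 0.05, seed=i) for i in range(6)}
        res = saturation_test(aln, reps=30, seed=3)
        assert res.Iss < res.Iss_c_sim

    def test_too_few_reps_rejected(self):
        aln = {f"s{i}": "ACGT" * 10 for i in range(4)}
        with pytest.raises(AlignmentError):
            saturation_test(aln, reps=5)

    def test_sv_curve_sorted_by_distance(self):
        rng = np.random.default_rng(13)
        base = "".join(np.array(list("ACGT"))[rng.integers(4, size=500)])
        aln = {f"s{i}": evolve_pair(base, 0.02 * (i + 1), seed=20 + i) for i in range(4)}
        res = saturation_test(aln, reps=10, seed=4)
        ds = [d for d, _, _ in res.sv_curve if not math.isnan(d)]
        assert ds == sorted(ds)


class TestNJ:
    def test_additive_four_taxon_exact_recovery(self):
        import io

        from skbio import TreeNode

        labels = ["A", "B", "C", "D"]
        # tree ((A:1,B:2):3,(C:4,D:5)) => additive distances
        dist = {("A", "B"): 3, ("A", "C"): 8, ("A", "D"): 9,
                ("B", "C"): 9, ("B", "D"): 10, ("C", "D"): 9}
        m = np.zeros((4, 4))
        for (i, j) in itertools.combinations(range(4), 2):
            m[i, j] = m[j, i] = dist[(labels[i], labels[j])]
        tree = TreeNode.read(io.StringIO(nj_tree(m, labels)))
        for a, b in itertools.combinations(labels, 2):
            assert tree.find(a).distance(tree.find(b)) == pytest.approx(dist[(a, b)])

    def test_three_taxa(self):
        m = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        nwk = nj_tree(m, ["x", "y", "z"])
        assert nwk.endswith(";") and all(t in nwk for t in ("x", "y", "z"))

    def test_equidistant_taxa_star_like(self):
        import io

        from skbio import TreeNode

        n = 4
        m = np.full((n, n), 2.0)
        np.fill_diagonal(m, 0.0)
        tree = TreeNode.read(io.StringIO(nj_tree(m, list("abcd"))))
        tip_depths = {t.name: t.distance(tree.root()) for t in tree.tips()}
        pairs = [tree.find(a).distance(tree.find(b))
                 for a, b in itertools.combinations("abcd", 2)]
        assert all(p == pytest.approx(2.0) for p in pairs)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(AlignmentError):
            nj_tree(m, list("abc"))
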
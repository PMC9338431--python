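"""GY94 rate matrices, pruning likelihoods and likelihood ratio tests."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

from numtforge.phylo import parse_newick
from numtforge.selection_models import (
    CodonModelSpec,
    CodonMSA,
    CodonStates,
    ModelParams,
    build_rate_matrix,
    fit,
    fit_lengths,
    log_likelihood,
    lrt,
)
from numtforge.seqio_codes import STANDARD_CODE, VERTEBRATE_MITO_CODE
from numtforge.synthetic_data import simulate_codon_alignment

MITO = VERTEBRATE_MITO_CODE


def equal_freqs(code):
    n = len(code.sense_codons)
    return np.full(n, 1.0 / n)


class TestRateMatrix:
    def test_rows_sum_to_zero_and_mean_rate_one(self):
        pi = equal_freqs(MITO)
        q = build_rate_matrix(2.0, 0.3, pi, MITO)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert -(pi * np.diag(q)).sum() == pytest.approx(1.0)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        st = CodonStates(MITO)
        q = build_rate_matrix(2.0, 0.0, equal_freqs(MITO), MITO)
        for i, j, syn in zip(st.pi_idx, st.pj_idx, st.is_synonymous):
            if not syn:
                assert q[i, j] == 0.0

    def test_detailed_balance(self, rng):
        st = CodonStates(STANDARD_CODE)
        pi = rng.dirichlet(np.ones(st.n) * 5)
        q = build_rate_matrix(3.0, 0.7, pi, STANDARD_CODE)
        flux = pi[:, None] * q
        idx = rng.integers(0, st.n, size=(100, 2))
        for i, j in idx:
            assert flux[i, j] == pytest.approx(flux[j, i], abs=1e-12)

    def test_neutral_symmetric_case_all_neighbours_equal(self):
        st = CodonStates(MITO)
        q = build_rate_matrix(1.0, 1.0, equal_freqs(MITO), MITO)
        off = q[st.pi_idx, st.pj_idx]
        assert np.allclose(off, off[0])

    def test_multi_nucleotide_changes_forbidden(self):
        st = CodonStates(MITO)
        q = build_rate_matrix(2.0, 0.5, equal_freqs(MITO), MITO)
        single = set(zip(st.pi_idx.tolist(), st.pj_idx.tolist()))
        nz = np.argwhere(q != 0.0)
        for i, j in nz:
            if i != j:
                assert (int(i), int(j)) in single


def brute_force_loglik(tree, msa, params, pi, code):
    """Sum over all internal-state assignments; independent of pruning."""
    st = CodonStates(code)
    q_bg = build_rate_matrix(params.kappa, params.omega_background[0], pi, code)
    mat = msa.state_matrix(code)
    leaves = tree.leaves()
    order = {n: i for i, n in enumerate(msa.names)}
    internal = [n for n in tree.postorder() if not n.is_leaf]
    P = {id(n): expm(q_bg * n.length) for n in tree.branches()}
    total = 0.0
    for site in range(mat.shape[1]):
        leaf_state = {id(l): mat[order[l.name], site] for l in leaves}
        s = 0.0
        for assign in itertools.product(range(st.n), repeat=len(internal)):
            states = dict(leaf_state)
            for node, a in zip(internal, assign):
                states[id(node)] = a
            prob = pi[states[id(tree)]]
            for n in tree.branches():
                prob *= P[id(n)][states[id(n.parent)], states[id(n)]]
            s += prob
        total += np.log(s)
    return total


class TestLikelihood:
    def test_two_taxa_matches_matrix_exponential(self):
        tree = parse_newick("(a:0.1,b:0.2);")
        spec = CodonModelSpec("one_ratio", code=MITO, freq_scheme="equal")
        params = ModelParams(2.0, [1.0], [0.5], [0.5])
        msa = simulate_codon_alignment(tree, spec, params, 40, seed=1)
        ll = log_likelihood(tree, msa, spec, params)
        pi = equal_freqs(MITO)
        q = build_rate_matrix(2.0, 0.5, pi, MITO)
        P = expm(q * 0.3)  # reversibility collapses the two branches
        mat = msa.state_matrix(MITO)
        direct = sum(np.log(pi[i] * P[i, j]) for i, j in zip(mat[0], mat[1]))
        assert ll == pytest.approx(direct, abs=1e-8)

    def test_pruning_matches_brute_force_on_three_leaves(self):
        # 3 leaves, 1 internal node + root: brute force over 60^2 assignments
        tree = parse_newick("((a:0.08,b:0.15):0.1,c:0.3);")
        spec = CodonModelSpec("one_ratio", code=MITO, freq_scheme="equal")
        params = ModelParams(1.5, [1.0], [0.4], [0.4])
        msa = simulate_codon_alignment(tree, spec, params, 10, seed=2)
        ll = log_likelihood(tree, msa, spec, params)
        bf = brute_force_loglik(tree, msa, params, equal_freqs(MITO), MITO)
        assert ll == pytest.approx(bf, abs=1e-8)

    def test_duplicated_columns_double_loglik(self):
        tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.2,d:0.2);")
        spec = CodonModelSpec("one_ratio", code=MITO, freq_scheme="equal")
        params = ModelParams(2.0, [1.0], [0.5], [0.5])
        msa = simulate_codon_alignment(tree, spec, params, 30, seed=3)
        doubled = CodonMSA(msa.names, [s + s for s in msa.seqs])
        ll = log_likelihood(tree, msa, spec, params)
        ll2 = log_likelihood(tree, doubled, spec, params)
        assert ll2 == pytest.approx(2 * ll, rel=1e-12)

    def test_untranslatable_codons_treated_as_missing(self):
        tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.2,d:0.2);")
        spec = CodonModelSpec("one_ratio", code=MITO, freq_scheme="equal")
        params = ModelParams(2.0, [1.0], [0.5], [0.5])
        msa = simulate_codon_alignment(tree, spec, params, 20, seed=4)
        with_n = CodonMSA(msa.names, [("NNN" + s) for s in msa.seqs])
        ll = log_likelihood(tree, msa, spec, params)
        ll_n = log_likelihood(tree, with_n, spec, params)
        assert ll_n == pytest.approx(ll, abs=1e-9)  # all-missing column adds 0

    def test_partitioned_model_requires_numt_branches(self):
        tree = parse_newick("((a:0.1,b:0.1):0.1,c:0.2,d:0.2);")
        spec = CodonModelSpec("two_ratio", code=MITO, freq_scheme="equal")
        params = ModelParams(2.0, [1.0], [0.2], [0.8])
        msa = simulate_codon_alignment(
            tree, CodonModelSpec("one_ratio", code=MITO, freq_scheme="equal"),
            ModelParams(2.0, [1.0], [0.2], [0.2]), 10, seed=5,
        )
        with pytest.raises(ValueError, match="numt"):
            log_likelihood(tree, msa, spec, params)

    def test_reroot_invariance(self):
        # reversible chain: likelihood identical for a different rooting of
        # the same unrooted tree
        spec = CodonModelSpec("one_ratio", code=MITO, freq_scheme="equal")
        params = ModelParams(2.0, [1.0], [0.5], [0.5])
        t1 = parse_newick("((a:0.1,b:0.2):0.15,c:0.3,d:0.25);")
        t2 = parse_newick("((c:0.3,d:0.25):0.15,a:0.1,b:0.2);")
        msa = simulate_codon_alignment(t1, spec, params, 50, seed=6)
        assert log_likelihood(t1, msa, spec, params) == pytest.approx(
            log_likelihood(t2, msa, spec, params), abs=1e-8
        )


NUMT_TREE = (
    "(((n1#numt:0.08,n2#numt:0.08)#numt:0.06,n3#numt:0.12)#numt:0.12,"
    "(m1:0.3,m2:0.25):0.1,m3:0.35);"
)


class TestFit:
    def test_constrained_two_ratio_reproduces_one_ratio(self):
        tree = parse_newick(NUMT_TREE)
        spec1 = CodonModelSpec("one_ratio", code=MITO, freq_scheme="equal")
        params = ModelParams(2.0, [1.0], [0.25], [0.25])
        msa = simulate_codon_alignment(tree, spec1, params, 150, seed=7)
        f1 = fit(tree, msa, spec1, n_restarts=2, seed=0)
        spec2 = CodonModelSpec("two_ratio", code=MITO, freq_scheme="equal")
        f2 = fit(tree, msa, spec2, n_restarts=2, seed=0,
                 extra_starts=[(f1.params, fit_lengths(f1))])
        # nesting: the richer model can only do better
        assert f2.log_likelihood >= f1.log_likelihood - 1e-6
        # evaluating two_ratio at the one_ratio solution gives the same logL
        constrained = ModelParams(
            f1.params.kappa, [1.0],
            f1.params.omega_background, f1.params.omega_background,
        )
        tree_hat = f1.tree
        ll = log_likelihood(tree_hat, msa, spec2, constrained)
        assert ll == pytest.approx(f1.log_likelihood, abs=1e-6)

    def test_two_ratio_parameter_recovery_single_replicate(self):
        tree = parse_newick(NUMT_TREE)
        spec = CodonModelSpec("two_ratio", code=MITO, freq_scheme="equal")
        params = ModelParams(2.0, [1.0], [0.2], [0.2])
        msa = simulate_codon_alignment(tree, spec, params, 500, seed=8)
        fr = fit(tree, msa, spec, n_restarts=3, seed=0)
        assert fr.params.omega_background[0] == pytest.approx(0.2, abs=0.05)
        assert fr.params.omega_numt[0] == pytest.approx(0.2, abs=0.05)


class TestLRT:
    @pytest.mark.parametrize(
        "null_l,alt_l,df,expected",
        [
            # printed branch-model comparison: indistinguishable fits
            (-1811.746326, -1811.746294, 1, 0.99),
            # clade model with vs without the neutral constraint
            (-1803.236605, -1802.187057, 1, 0.15),
        ],
    )
    def test_reported_p_values_reproduce(self, null_l, alt_l, df, expected):
        r = lrt(null_l, alt_l, df=df)
        assert round(r.p_value, 2) == expected

    def test_strongly_significant_comparisons(self):
        assert lrt(-1828.804375, -1811.746294, df=1).p_value < 0.001
        assert lrt(-1811.746294, -1802.187057, df=3).p_value < 0.001

    def test_identical_logl(self):
        r = lrt(-100.0, -100.0, df=1)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_nesting_violation_raises(self):
        with pytest.raises(ValueError, match="nesting"):
            lrt(-100.0, -102.0, df=1)

    def test_df_from_specs(self):
        kinds = {k: CodonModelSpec(k).n_free_model_params for k in
                 ("one_ratio", "two_ratio", "two_ratio_fixed", "M1a", "M2a",
                  "cladeC", "cladeC_fixed")}
        assert kinds["two_ratio"] - kinds["one_ratio"] == 1
        assert kinds["two_ratio"] - kinds["two_ratio_fixed"] == 1
        assert kinds["cladeC"] - kinds["two_ratio"] == 3
        assert kinds["cladeC"] - kinds["M1a"] == 3
        assert kinds["cladeC"] - kinds["cladeC_fixed"] == 1

    def test_statistic_matches_chi2_tail(self):
        r = lrt(-500.0, -497.0, df=2)
        assert r.statistic == pytest.approx(6.0)
        assert r.p_value == pytest.approx(float(chi2.sf(6.0, 2)))
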
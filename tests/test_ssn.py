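"""Reference statistics, differential PCC, edge test, SSN construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import oracles
from ldnb.ssn import (
    build_ssn,
    compute_reference_stats,
    delta_pcc,
    edge_significance,
    perturbed_pcc,
    volcano_sf,
)


def _frame(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"m{i+1}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j+1}" for j in range(values.shape[1])],
    )


class TestReferenceStats:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3, 4], [2, 4, 6, 8], 1.0),
            ([1, 2, 3, 4], [4, 3, 2, 1], -1.0),
        ],
    )
    def test_perfect_linear_dependence(self, x, y, expected):
        ab = _frame([x, y])
        rs = compute_reference_stats(ab, list(ab.columns))
        assert rs.pcc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_formula_on_fixture(self, small_cohort, reference_ids):
        """Every entry of the reference PCC matrix equals an independent
        direct evaluation of the correlation sum formula."""
        rs = compute_reference_stats(small_cohort.abundance, reference_ids)
        rows = [
            small_cohort.abundance.loc[m, reference_ids].tolist()
            for m in rs.molecule_ids
        ]
        expected = oracles.pcc_matrix(rows)
        for i in range(len(rows)):
            for j in range(len(rows)):
                want = 1.0 if i == j else expected[i][j]
                assert rs.pcc[i, j] == pytest.approx(want, abs=1e-12)

    def test_constant_molecules_dropped(self):
        ab = _frame([[1, 2, 3, 4], [5, 5, 5, 5], [2, 1, 4, 3]])
        rs = compute_reference_stats(ab, list(ab.columns))
        assert rs.dropped == ("m2",)
        assert rs.molecule_ids == ("m1", "m3")
        assert (rs.sd > 0).all()

    def test_too_few_reference_samples(self):
        ab = _frame([[1, 2], [2, 1]])
        with pytest.raises(ValueError, match="at least 3"):
            compute_reference_stats(ab, list(ab.columns))

    def test_unknown_sample_id(self):
        ab = _frame([[1, 2, 3], [2, 1, 3]])
        with pytest.raises(KeyError, match="nope"):
            compute_reference_stats(ab, ["s1", "s2", "nope"])


class TestPerturbedPcc:
    def test_hand_computable_four_sample_pcc(self):
        """n=3 references plus one new sample equals the 4-sample PCC."""
        ab = _frame([[1, 2, 3, 5], [2, 1, 3, 4]])
        got = perturbed_pcc(ab, ["s1", "s2", "s3"], "s4")
        want = oracles.pearson([1, 2, 3, 5], [2, 1, 3, 4])
        assert got[0, 1] == pytest.approx(want, abs=1e-12)

    def test_duplicate_of_reference_sample(self, small_cohort, reference_ids):
        """Appending a copy of a reference sample equals the PCC of the
        duplicated multiset, against direct recomputation."""
        ab = small_cohort.abundance
        dup = ab["s2"].rename("dup")
        got = perturbed_pcc(ab, reference_ids, dup)
        for i, a in enumerate(("m1", "m2", "m3")):
            for j in range(i + 1, 4):
                b = f"m{j+1}"
                xs = ab.loc[a, reference_ids].tolist() + [ab.loc[a, "s2"]]
                ys = ab.loc[b, reference_ids].tolist() + [ab.loc[b, "s2"]]
                assert got[i, j] == pytest.approx(
                    oracles.pearson(xs, ys), abs=1e-12
                )

    def test_missing_molecules_in_new_sample(self, small_cohort, reference_ids):
        partial = small_cohort.abundance["s5"].drop(["m3", "m7"])
        with pytest.raises(KeyError, match="m3"):
            perturbed_pcc(small_cohort.abundance, reference_ids, partial)

    @given(
        hnp.arrays(
            np.float64,
            shape=st.tuples(
                st.integers(2, 6), st.integers(5, 12)
            ),
            elements=st.floats(-50, 50, allow_nan=False),
        ),
        st.integers(0, 10_000),
    )
    def test_equals_direct_recomputation_on_random_matrices(self, values, seed):
        """Property: the perturbed PCC of any new sample equals a direct
        evaluation of the correlation formula on the concatenated data."""
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0, 1e-3, values.shape)  # avoid constants
        ab = _frame(values[:, :-1])
        new = pd.Series(values[:, -1], index=ab.index, name="new")
        got = perturbed_pcc(ab, list(ab.columns), new)
        m = values.shape[0]
        for i in range(m):
            for j in range(i + 1, m):
                want = oracles.pearson(values[i].tolist(), values[j].tolist())
                assert got[i, j] == pytest.approx(want, abs=1e-9)


class TestDeltaPcc:
    def test_identity_and_arithmetic(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.all(delta_pcc(a, a) == 0)
        assert delta_pcc(np.array(0.50), np.array(0.62)) == pytest.approx(0.12)

    def test_antisymmetry(self, rng):
        a = rng.uniform(-1, 1, (4, 4))
        b = rng.uniform(-1, 1, (4, 4))
        np.testing.assert_allclose(delta_pcc(a, b), -delta_pcc(b, a))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            delta_pcc(np.zeros((2, 2)), np.zeros((3, 3)))


class TestEdgeSignificance:
    def test_null_point(self):
        z, p = edge_significance(0.0, 0.3, 10)
        assert z == 0.0
        assert p == 1.0

    def test_closed_form_example_normal_tail(self):
        """pcc_n=0, n=100, spcc=0.03: z = 0.03*99 = 2.97 and the
        standard-normal two-sided tail is ~0.0030."""
        z, p = edge_significance(0.03, 0.0, 100, tail="normal")
        assert z == pytest.approx(2.97, abs=1e-12)
        assert p == pytest.approx(0.00298, abs=5e-5)

    def test_volcano_tail_matches_quadrature(self):
        for zval in [0.3, 1.0, 2.2, 4.5]:
            z, p = edge_significance(zval / 9, 0.0, 10)
            assert z == pytest.approx(zval)
            assert p == pytest.approx(oracles.volcano_two_sided(zval), rel=1e-5)

    def test_degenerate_reference_correlation_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            edge_significance(0.1, 1.0, 10)

    def test_volcano_sf_basic_properties(self):
        t = np.linspace(0, 10, 101)
        sf = volcano_sf(t)
        assert sf[0] == 1.0
        assert np.all(np.diff(sf) <= 0)
        assert volcano_sf(50.0) < 1e-20

    def test_null_calibration(self):
        """Monte-Carlo: under a Gaussian null (n=50 references) the edge
        test rejects close to its nominal 5% level."""
        from ldnb.experiments import null_rejection_rate

        rate = null_rejection_rate(
            n_reference=50, n_trials=4000, alpha=0.05, seed=123
        )
        assert 0.035 <= rate <= 0.065


class TestBuildSsn:
    def test_alpha_zero_gives_empty_network(self, small_cohort, reference_ids):
        net = build_ssn(small_cohort.abundance, reference_ids, "s5", alpha=0.0)
        assert net.n_edges == 0

    def test_network_is_symmetric_and_self_edge_free(
        self, small_cohort, reference_ids
    ):
        net = build_ssn(small_cohort.abundance, reference_ids, "s5")
        assert not net.adjacency.diagonal().any()
        assert (net.adjacency == net.adjacency.T).all()
        for e in net.edges():
            assert e.p < net.alpha
            assert e.spcc == pytest.approx(e.pcc_n1 - e.pcc_n, abs=1e-12)

    def test_shrinking_alpha_never_adds_edges(self, small_cohort, reference_ids):
        alphas = [0.2, 0.1, 0.05, 0.01]
        nets = [
            build_ssn(small_cohort.abundance, reference_ids, "s5", alpha=a)
            for a in alphas
        ]
        for wide, narrow in zip(nets, nets[1:]):
            assert not (narrow.adjacency & ~wide.adjacency).any()

    def test_edges_match_oracle_on_fixture(self, small_cohort, reference_ids):
        net = build_ssn(small_cohort.abundance, reference_ids, "s5")
        ab = small_cohort.abundance
        rows = [ab.loc[m, reference_ids].tolist() for m in net.molecule_ids]
        new = [ab.loc[m, "s5"] for m in net.molecule_ids]
        want_edges, want_spcc = oracles.ssn_edges(rows, new, alpha=0.05)
        got_edges = {
            (i, j)
            for i in range(len(rows))
            for j in range(len(rows))
            if net.adjacency[i, j]
        }
        assert got_edges == want_edges
        for (i, j), v in want_spcc.items():
            assert net.spcc[i, j] == pytest.approx(v, abs=1e-12)

    def test_null_sample_edge_count_near_alpha(self):
        """A new sample drawn from the reference distribution itself
        yields about alpha * n_pairs edges (within 3 binomial SDs)."""
        rng = np.random.default_rng(7)
        m, n = 60, 50
        ab = _frame(rng.standard_normal((m, n + 1)))
        refs = list(ab.columns[:-1])
        net = build_ssn(ab, refs, ab.columns[-1], alpha=0.05)
        n_pairs = m * (m - 1) // 2
        expect = 0.05 * n_pairs
        sd = np.sqrt(n_pairs * 0.05 * 0.95)
        assert abs(net.n_edges - expect) <= 3 * sd

    def test_planted_module_pairs_enriched(self, strong_cohort):
        """In a strong-effect stage-A sample the planted module's pairs
        are significantly over-represented among SSN edges."""
        from scipy.stats import fisher_exact

        refs = strong_cohort.group_samples["control"]
        sample = strong_cohort.group_samples["stageA"][0]
        net = build_ssn(strong_cohort.abundance, refs, sample)
        module_idx = [
            i for i, m in enumerate(net.molecule_ids)
            if m in strong_cohort.truth_module
        ]
        in_module = np.zeros(len(net.molecule_ids), dtype=bool)
        in_module[module_idx] = True
        tri = np.triu_indices(len(net.molecule_ids), k=1)
        is_edge = net.adjacency[tri]
        both = in_module[tri[0]] & in_module[tri[1]]
        table = [
            [int((is_edge & both).sum()), int((is_edge & ~both).sum())],
            [int((~is_edge & both).sum()), int((~is_edge & ~both).sum())],
        ]
        _, p = fisher_exact(table, alternative="greater")
        assert p < 0.01

    def test_leave_one_out_reduces_reference(self, small_cohort, reference_ids):
        net_in = build_ssn(small_cohort.abundance, reference_ids, "s2")
        net_loo = build_ssn(
            small_cohort.abundance, reference_ids, "s2", leave_one_out=True
        )
        # with s2 held out, PCC_n is computed on 3 samples, so it differs
        assert not np.allclose(net_in.pcc_n, net_loo.pcc_n)

    def test_permutation_tail_runs_and_bounds_p(self, small_cohort, reference_ids):
        net = build_ssn(
            small_cohort.abundance, reference_ids, "s5", tail="permutation",
            n_permutations=99, rng=np.random.default_rng(0),
        )
        tri = np.triu_indices(len(net.molecule_ids), k=1)
        p = net.p[tri]
        ok = p <= 1.0
        assert (p[ok] >= 1 / 100).all()

    def test_reference_edge_filter_restricts_universe(
        self, small_cohort, reference_ids
    ):
        full = build_ssn(small_cohort.abundance, reference_ids, "s5", alpha=0.3)
        filt = build_ssn(
            small_cohort.abundance, reference_ids, "s5", alpha=0.3,
            reference_edge_filter="pcc_pvalue",
        )
        assert not (filt.adjacency & ~full.adjacency).any()
        assert filt.n_edges <= full.n_edges
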
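import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import parcelcorr as pc
from parcelcorr.correspondence import bh_fdr, correlate_battery, \
    pearson_corr, spin_pvalue
from parcelcorr.spin import SpinNullEnsemble


def _map(parc, values, **kw):
    return pc.ParcelMap(parc, np.asarray(values, float), **kw)


@pytest.fixture(scope="module")
def parc4():
    return pc.SphericalParcellation(
        tuple(f"lh.p{i}" for i in range(4)), ("left",) * 4,
        np.array([[0, 0, 1.0], [0, 1.0, 0], [1.0, 0, 0],
                  [0, 0, -1.0]]))


class TestPearson:
    def test_self_correlation_is_one(self, parc4):
        m = _map(parc4, [1, 2, 3, 5])
        assert pearson_corr(m, m) == pytest.approx(1.0)

    def test_sign_flip_gives_minus_one(self, parc4):
        m = _map(parc4, [1, 2, 3, 5])
        neg = _map(parc4, [-1, -2, -3, -5])
        assert pearson_corr(m, neg) == pytest.approx(-1.0)

    def test_hand_computed_example(self, parc4):
        # a=[1,2,3,4], b=[2,1,4,3]: centered cross-products sum to 3,
        # both sums of squares are 5, r = 3/5
        a = _map(parc4, [1, 2, 3, 4])
        b = _map(parc4, [2, 1, 4, 3])
        assert pearson_corr(a, b) == pytest.approx(0.6, rel=1e-12)

    def test_missing_parcels_dropped_then_too_few_errors(self, parc4):
        a = _map(parc4, [1, np.nan, 3, 4])
        b = _map(parc4, [2, 1, np.nan, 3])
        with pytest.raises(ValueError, match="non-missing"):
            pearson_corr(a, b)

    def test_zero_variance_errors(self, parc4):
        a = _map(parc4, [1, 1, 1, 1])
        b = _map(parc4, [2, 1, 4, 3])
        with pytest.raises(ValueError, match="variance"):
            pearson_corr(a, b)


class TestSpinPvalue:
    def test_identity_ensemble_gives_p_one(self, parc4):
        ens = SpinNullEnsemble(5, np.tile(np.arange(4), (5, 1)),
                               parcellation=parc4, seed=0)
        a = _map(parc4, [1, 2, 3, 4])
        b = _map(parc4, [2, 1, 4, 3])
        assert spin_pvalue(a, b, ens) == 1.0

    def test_p_formula_with_exactly_four_exceedances(self, dkt62):
        # 99 assignments of which exactly 4 are the identity: correlating a
        # map with itself, only those 4 reach |r_null| >= |r_obs| = 1, so
        # p = (1+4)/(99+1) = 0.05
        rng = np.random.default_rng(12)
        assignment = np.array([rng.permutation(62) for _ in range(99)])
        assignment[[7, 20, 40, 80]] = np.arange(62)
        ens = SpinNullEnsemble(99, assignment, parcellation=dkt62, seed=0)
        m = pc.make_autocorrelated_map(dkt62, 0.3, seed=13)
        assert spin_pvalue(m, m, ens) == pytest.approx(0.05)

    def test_p_never_below_one_over_nperm_plus_one(self, dkt62):
        ens = pc.make_spin_ensemble(dkt62, 99, seed=3)
        m = pc.make_autocorrelated_map(dkt62, 0.5, seed=4)
        p = spin_pvalue(m, m, ens)
        assert 1 / 100 <= p <= 1.0

    def test_parcellation_mismatch_errors(self, parc4, dkt62):
        ens = pc.make_spin_ensemble(dkt62, 10, seed=1)
        a = _map(parc4, [1, 2, 3, 4])
        with pytest.raises(ValueError, match="parcellation"):
            spin_pvalue(a, a, ens)

    def test_spin_exchangeable_under_map_relabeling(self, dkt62):
        # spinning map a against fixed b and vice versa gives statistically
        # indistinguishable p-values on isotropic synthetic maps
        ens = pc.make_spin_ensemble(dkt62, 300, seed=5)
        pa, pb = [], []
        rng = np.random.default_rng(6)
        for _ in range(40):
            a = pc.make_autocorrelated_map(dkt62, 0.5,
                                           seed=int(rng.integers(2**31)))
            b = pc.make_autocorrelated_map(dkt62, 0.5,
                                           seed=int(rng.integers(2**31)))
            pa.append(spin_pvalue(a, b, ens))
            pb.append(spin_pvalue(b, a, ens))
        from scipy.stats import ks_2samp
        assert ks_2samp(pa, pb).pvalue > 0.01


class TestBattery:
    def test_battery_returns_one_result_per_map_with_q_ge_p(self, dkt62):
        ens = pc.make_spin_ensemble(dkt62, 100, seed=8)
        target = pc.make_autocorrelated_map(dkt62, 0.5, seed=9)
        battery = [pc.make_autocorrelated_map(dkt62, 0.5, seed=10 + i,
                                              name=f"pet{i}")
                   for i in range(19)]
        results = correlate_battery(target, battery, ens)
        assert len(results) == 19
        assert all(r.q >= r.p_spin - 1e-12 for r in results)
        assert all(abs(r.r) <= 1 for r in results)

    def test_battery_of_one_map_q_equals_p(self, dkt62):
        ens = pc.make_spin_ensemble(dkt62, 100, seed=8)
        target = pc.make_autocorrelated_map(dkt62, 0.5, seed=9)
        other = pc.make_autocorrelated_map(dkt62, 0.5, seed=10)
        res = correlate_battery(target, [other], ens)
        assert len(res) == 1 and res[0].q == pytest.approx(res[0].p_spin)

    def test_duplicated_target_dominates(self, dkt62):
        ens = pc.make_spin_ensemble(dkt62, 100, seed=8)
        target = pc.make_autocorrelated_map(dkt62, 0.5, seed=9,
                                            name="target")
        battery = [pc.make_autocorrelated_map(dkt62, 0.5, seed=10 + i,
                                              name=f"m{i}") for i in range(4)]
        battery.append(pc.ParcelMap(dkt62, target.values.copy(), name="dup"))
        results = correlate_battery(target, battery, ens)
        dup = next(r for r in results if r.map_b_id == "dup")
        assert dup.r == pytest.approx(1.0)
        assert dup.p_spin == min(r.p_spin for r in results)

    def test_empty_battery_errors(self, dkt62):
        ens = pc.make_spin_ensemble(dkt62, 10, seed=8)
        target = pc.make_autocorrelated_map(dkt62, 0.5, seed=9)
        with pytest.raises(ValueError, match="empty"):
            correlate_battery(target, [], ens)

    def test_battery_order_does_not_change_q(self, dkt62):
        ens = pc.make_spin_ensemble(dkt62, 100, seed=8)
        target = pc.make_autocorrelated_map(dkt62, 0.5, seed=9)
        battery = [pc.make_autocorrelated_map(dkt62, 0.5, seed=10 + i,
                                              name=f"m{i}") for i in range(6)]
        q1 = {r.map_b_id: r.q for r in correlate_battery(target, battery, ens)}
        q2 = {r.map_b_id: r.q
              for r in correlate_battery(target, battery[::-1], ens)}
        assert q1 == q2


def bh_bruteforce(p):
    """Step-up BH by direct definition: q_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04], rtol=1e-12)

    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.5]), [0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=30))
    def test_matches_bruteforce_definition_and_dominates_p(self, p):
        q = bh_fdr(p)
        np.testing.assert_allclose(q, bh_bruteforce(p), rtol=1e-12, atol=1e-15)
        assert (q >= np.asarray(p) - 1e-15).all() and (q <= 1 + 1e-15).all()
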
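"""Partition-function occupancy models: enumeration, weights, limits."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clusterbind.designs import BindingSite, ClusterDesign
from clusterbind.statmech import (
    BindingConfiguration,
    EnumerationSizeError,
    StatMechModel,
    energy_to_kd,
    enumerate_states,
    kd_to_energy,
    mean_occupancy,
    occupancy_curve,
    partition_function,
    saturation_occupancy,
    state_probabilities,
    state_weight,
)


def brute_force(design, kds, c, mode, eps):
    """Independent subset-loop oracle for Z and <N>."""
    sites = design.specific_sites()
    n = len(sites)
    z = 0.0
    num = 0.0
    for r in range(n + 1):
        for combo in itertools.combinations(range(n), r):
            clashes = sum(
                1
                for i, j in itertools.combinations(combo, 2)
                if set(range(sites[i].start, sites[i].end))
                & set(range(sites[j].start, sites[j].end))
            )
            if mode == "exclusive" and clashes:
                continue
            w = 1.0
            for i in combo:
                w *= c / kds[i]
            if mode == "permissive":
                w *= math.exp(-eps * clashes)
            z += w
            num += r * w
    return z, num / z


def chain_design(n, stride, length=9):
    return ClusterDesign(
        "chain",
        [BindingSite(f"s{i}", i * stride, length) for i in range(n)],
    )


class TestEnumeration:
    def test_two_overlapping_sites_state_counts(self, two_overlapping_sites):
        assert len(enumerate_states(two_overlapping_sites, "exclusive")) == 3
        assert len(enumerate_states(two_overlapping_sites, "permissive")) == 4
        assert len(enumerate_states(two_overlapping_sites, "independent")) == 4

    def test_four_site_chain_exclusive_count(self):
        # only consecutive pairs overlap (stride 6 < 9, 2*6 >= 9)
        design = chain_design(4, 6)
        states = enumerate_states(design, "exclusive")
        assert len(states) == 8  # Fibonacci-like independent-set count

    def test_empty_configuration_always_present(self, two_overlapping_sites):
        for mode in ("independent", "exclusive", "permissive"):
            states = enumerate_states(two_overlapping_sites, mode)
            assert BindingConfiguration(bound=(), clash_pairs=0) in states

    def test_exclusive_states_have_no_clashes(self):
        design = chain_design(5, 6)
        assert all(
            s.clash_pairs == 0 for s in enumerate_states(design, "exclusive")
        )

    def test_enumeration_cap(self):
        design = ClusterDesign(
            "big",
            [BindingSite(f"s{i}", i * 14) for i in range(17)],
            target_length=17 * 14 + 9,
        )
        with pytest.raises(EnumerationSizeError):
            enumerate_states(design, "permissive")


class TestWeightsAndZ:
    def test_state_weight_basics(self, two_overlapping_sites):
        model = StatMechModel([10.0, 10.0], "permissive", eps_clash=math.log(2))
        empty = BindingConfiguration(bound=())
        one = BindingConfiguration(bound=(0,))
        both = BindingConfiguration(bound=(0, 1), clash_pairs=1)
        assert state_weight(empty, 123.0, model) == 1.0
        assert state_weight(one, 10.0, model) == pytest.approx(1.0)
        assert state_weight(both, 10.0, model) == pytest.approx(0.5)

    def test_partition_function_values(self, two_overlapping_sites):
        single = ClusterDesign("one", [BindingSite("a", 0)])
        m1 = StatMechModel([10.0], "independent")
        assert partition_function(single, 10.0, m1) == pytest.approx(2.0)
        m2 = StatMechModel([10.0, 10.0], "permissive", eps_clash=math.log(2))
        assert partition_function(two_overlapping_sites, 10.0, m2) == pytest.approx(3.5)
        assert partition_function(two_overlapping_sites, 0.0, m2) == pytest.approx(1.0)

    def test_mean_occupancy_values(self, two_overlapping_sites):
        single = ClusterDesign("one", [BindingSite("a", 0)])
        assert mean_occupancy(
            single, 10.0, StatMechModel([10.0], "independent")
        ) == pytest.approx(0.5)
        pair = ClusterDesign(
            "far", [BindingSite("a", 0), BindingSite("b", 20)]
        )
        assert mean_occupancy(
            pair, 10.0, StatMechModel([10.0, 10.0], "independent")
        ) == pytest.approx(1.0)
        m = StatMechModel([10.0, 10.0], "permissive", eps_clash=math.log(2))
        assert mean_occupancy(two_overlapping_sites, 10.0, m) == pytest.approx(6 / 7)

    def test_closed_form_two_site_permissive(self, two_overlapping_sites):
        """Z and state probabilities match Z = 1 + x1 + x2 + x1 x2 e^-eps."""
        kds = np.array([7.0, 31.0])
        eps = 1.3
        m = StatMechModel(kds, "permissive", eps_clash=eps)
        for c in (0.0, 0.3, 7.0, 450.0):
            x1, x2 = (c / kds[0], c / kds[1])
            z_expected = 1 + x1 + x2 + x1 * x2 * math.exp(-eps)
            assert partition_function(two_overlapping_sites, c, m) == pytest.approx(
                z_expected, rel=1e-12, abs=1e-12
            )
            probs = state_probabilities(two_overlapping_sites, c, m)
            expected = np.array([1, x1, x2, x1 * x2 * math.exp(-eps)]) / z_expected
            by_state = {
                tuple(b): p for b, p in zip(probs["bound_sites"], probs["P"])
            }
            got = np.array(
                [by_state[()], by_state[(0,)], by_state[(1,)], by_state[(0, 1)]]
            )
            np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    @pytest.mark.parametrize("mode", ["independent", "exclusive", "permissive"])
    def test_brute_force_oracle(self, mode):
        """Enumeration agrees with an independently coded subset loop."""
        design = chain_design(5, 6)
        kds = [5.0, 50.0, 13.0, 200.0, 8.0]
        eps = 1.7
        model = StatMechModel(kds, mode, eps_clash=eps if mode == "permissive" else 0.0)
        for c in (0.0, 1.0, 42.0, 3000.0):
            z_bf, n_bf = brute_force(design, kds, c, mode, eps)
            assert partition_function(design, c, model) == pytest.approx(z_bf, rel=1e-12)
            assert mean_occupancy(design, c, model) == pytest.approx(n_bf, rel=1e-12)


class TestProbabilitiesAndLimits:
    def test_probabilities_normalize(self, two_overlapping_sites):
        m = StatMechModel([10.0, 30.0], "permissive", eps_clash=2.0)
        for c in (0.0, 1.0, 100.0, 1e5):
            probs = state_probabilities(two_overlapping_sites, c, m)
            assert probs["P"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_concentration_all_empty(self, two_overlapping_sites):
        m = StatMechModel([10.0, 30.0], "permissive", eps_clash=2.0)
        probs = state_probabilities(two_overlapping_sites, 0.0, m)
        empty = probs[probs["n_bound"] == 0]["P"].iloc[0]
        assert empty == 1.0

    def test_doubly_bound_dominates_at_high_c(self, two_overlapping_sites):
        m = StatMechModel([10.0, 10.0], "permissive", eps_clash=5.0)
        probs = state_probabilities(two_overlapping_sites, 1e9, m)
        p_double = probs[probs["n_bound"] == 2]["P"].iloc[0]
        assert p_double > 0.99

    def test_independence_limit(self):
        """Permissive with eps = 0 reproduces the independent-site sum."""
        design = chain_design(4, 6)
        kds = np.array([5.0, 50.0, 13.0, 200.0])
        c = np.geomspace(0.01, 1e4, 30)
        perm = StatMechModel(kds, "permissive", eps_clash=0.0)
        expected = (c[None, :] / (c[None, :] + kds[:, None])).sum(axis=0)
        np.testing.assert_allclose(
            mean_occupancy(design, c, perm), expected, atol=1e-10
        )

    def test_exclusive_limit(self, two_overlapping_sites):
        """Permissive with eps = 30 k_BT matches exclusive to 1e-8."""
        kds = np.array([10.0, 10.0])
        c = np.geomspace(0.1, 1e4, 40)  # 1e-2 Kd .. 1e3 Kd
        perm = StatMechModel(kds, "permissive", eps_clash=30.0)
        excl = StatMechModel(kds, "exclusive")
        np.testing.assert_allclose(
            mean_occupancy(two_overlapping_sites, c, perm),
            mean_occupancy(two_overlapping_sites, c, excl),
            atol=1e-8,
        )

    def test_occupancy_nonincreasing_in_eps(self, two_overlapping_sites):
        c = 50.0
        occs = [
            mean_occupancy(
                two_overlapping_sites,
                c,
                StatMechModel([10.0, 10.0], "permissive", eps_clash=e),
            )
            for e in np.linspace(0.0, 10.0, 21)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(occs, occs[1:]))

    def test_mixed_affinity_dominance(self):
        """Replacing a strong site by a weak one never raises occupancy."""
        c = np.geomspace(0.01, 1e5, 40)
        strong = chain_design(3, 6)
        m_strong = StatMechModel([10.0, 10.0, 10.0], "permissive", eps_clash=2.0)
        m_weak = StatMechModel([10.0, 100.0, 10.0], "permissive", eps_clash=2.0)
        occ_s = mean_occupancy(strong, c, m_strong)
        occ_w = mean_occupancy(strong, c, m_weak)
        assert np.all(occ_w <= occ_s + 1e-12)

    @given(
        c=st.floats(0.0, 1e5),
        eps=st.floats(0.0, 10.0),
        kd1=st.floats(1.0, 1e3),
        kd2=st.floats(1.0, 1e3),
    )
    @settings(max_examples=100, deadline=None)
    def test_occupancy_bounds_property(self, c, eps, kd1, kd2):
        design = ClusterDesign(
            "pair", [BindingSite("a", 0), BindingSite("b", 6)]
        )
        m = StatMechModel([kd1, kd2], "permissive", eps_clash=eps)
        occ = mean_occupancy(design, c, m)
        assert -1e-12 <= occ <= 2 + 1e-12


class TestCurves:
    def test_occupancy_curve_monotone_and_nmax(self, library):
        grid = np.geomspace(1e-2, 1e6, 80)
        w6 = library["W6"]
        m = StatMechModel.from_design(w6, 10.0, mode="independent")
        curve = occupancy_curve(w6, grid, m)
        assert np.all(np.diff(curve.mean_occupancy) >= -1e-12)
        assert curve.n_max == 6
        assert curve.mean_occupancy[-1] == pytest.approx(6, rel=0.01)

    def test_exclusive_nmax_is_max_independent_set(self, two_overlapping_sites):
        m = StatMechModel([10.0, 10.0], "exclusive")
        assert saturation_occupancy(two_overlapping_sites, m) == 1

    def test_permissive_exceeds_exclusive_cap(self, two_overlapping_sites):
        """Occupancy despite clash: <N> > 1 at high c for finite eps."""
        for eps in (0.5, 3.0, 8.0):
            m = StatMechModel([10.0, 10.0], "permissive", eps_clash=eps)
            grid = np.geomspace(1, 1e9, 60)
            occ = mean_occupancy(two_overlapping_sites, grid, m)
            assert occ.max() > 1.0

    def test_curve_rejects_bad_grid(self, two_overlapping_sites):
        m = StatMechModel([10.0, 10.0], "permissive", eps_clash=1.0)
        with pytest.raises(ValueError):
            occupancy_curve(two_overlapping_sites, [10.0, 5.0], m)


def test_kd_energy_roundtrip():
    assert kd_to_energy(1.0, 1.0) == 0.0
    assert kd_to_energy(10.0, 1.0) == pytest.approx(math.log(10), rel=1e-12)
    for kd in (0.37, 1.0, 55.0, 9e3):
        assert energy_to_kd(kd_to_energy(kd, 2.5), 2.5) == pytest.approx(kd, rel=1e-12)
    with pytest.raises(ValueError):
        kd_to_energy(-1.0)
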
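"""Screening filters, the ipso-complex stability parameter, the thresholded
mechanism classifier, Boltzmann product fractions, and the end-to-end
pipeline against a table-level oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdregio import (
    AromaticSite,
    Call,
    ContractError,
    DomainError,
    Intermediate,
    Mechanism,
    PredictorConfig,
    StabilityParameter,
    Status,
    SyntheticBackend,
    boltzmann_fractions,
    classify_mechanism,
    geometry_filter,
    predict,
    prescreen,
    relative_site_energies,
    stability_parameter,
)
from pdregio.config import GAS_CONSTANT_KCAL, HARTREE_TO_KCAL

BASE = -355.5


def _inter(label="H1", mech="PA", sid="s", energy_kcal=None, gibbs_kcal=None, pd_c=None, conf=0):
    site = AromaticSite(atom_index=-1, h_label=label, ring_id=-1)
    i = Intermediate(sid, site, Mechanism(mech), conf, geometry=None)
    if energy_kcal is not None:
        i.electronic_energy = BASE + energy_kcal / HARTREE_TO_KCAL
    if gibbs_kcal is not None:
        i.gibbs_energy = BASE + gibbs_kcal / HARTREE_TO_KCAL
        i.status = Status.OPTIMIZED
    if pd_c is not None:
        i.pd_c_distance = pd_c
        i.status = Status.OPTIMIZED
    return i


class TestPrescreen:
    def test_discards_above_cutoff(self):
        inters = [_inter(f"H{k+1}", energy_kcal=e) for k, e in enumerate([0, 4, 11])]
        survivors = prescreen(inters, 10.0)
        assert [i.site.h_label for i in survivors] == ["H1", "H2"]
        assert inters[2].status is Status.DISCARDED
        assert inters[2].discard_reason == "prescreen"

    def test_boundary_is_inclusive(self):
        inters = [_inter("H1", energy_kcal=0.0), _inter("H2", energy_kcal=10.0)]
        assert len(prescreen(inters, 10.0)) == 2

    def test_cutoff_is_group_relative(self):
        # all far above zero on an absolute scale but within 10 of each other
        inters = [_inter(f"H{k+1}", energy_kcal=500.0 + e) for k, e in enumerate([0, 3, 9])]
        assert len(prescreen(inters, 10.0)) == 3

    def test_groups_are_substrate_by_mechanism(self):
        inters = [
            _inter("H1", mech="PA", energy_kcal=0.0),
            _inter("H1", mech="SEAR", energy_kcal=50.0),  # its own group minimum
        ]
        assert len(prescreen(inters, 10.0)) == 2

    def test_empty_input_gives_empty_output(self):
        assert prescreen([], 10.0) == []

    def test_missing_energy_is_a_contract_error(self):
        with pytest.raises(ContractError):
            prescreen([_inter("H1")], 10.0)


class TestGeometryFilter:
    @pytest.mark.parametrize(
        "distance,kept", [(2.3005, True), (7.1781, False), (2.4, True), (2.4001, False)]
    )
    def test_pd_c_boundary(self, distance, kept):
        (i,) = [_inter("H1", pd_c=distance)]
        survivors = geometry_filter([i], 2.4)
        assert (len(survivors) == 1) is kept
        if not kept:
            assert i.discard_reason == "no stable Pd-C bond"

    def test_missing_distance_is_a_contract_error(self):
        i = _inter("H1", gibbs_kcal=0.0)
        with pytest.raises(ContractError):
            geometry_filter([i], 2.4)


class TestRelativeSiteEnergies:
    def test_minimum_is_exactly_zero(self):
        inters = [_inter(l, gibbs_kcal=e) for l, e in [("H1", 1.9), ("H5", 9.8), ("H6", 0.0)]]
        rel = relative_site_energies(inters)
        assert rel["H6"] == 0.0
        assert rel["H1"] == pytest.approx(1.9, abs=1e-9)
        assert rel["H5"] == pytest.approx(9.8, abs=1e-9)

    def test_shift_invariance(self):
        a = relative_site_energies([_inter(l, gibbs_kcal=e) for l, e in [("H1", 0.0), ("H2", 2.5)]])
        b = relative_site_energies([_inter(l, gibbs_kcal=e + 77.0) for l, e in [("H1", 0.0), ("H2", 2.5)]])
        assert a["H2"] == pytest.approx(b["H2"], abs=1e-8)

    def test_site_energy_is_minimum_over_conformers(self):
        inters = [
            _inter("H1", gibbs_kcal=3.0, conf=0),
            _inter("H1", gibbs_kcal=1.0, conf=1),
            _inter("H2", gibbs_kcal=0.0, conf=0),
        ]
        rel = relative_site_energies(inters)
        assert rel["H1"] == pytest.approx(1.0, abs=1e-9)

    def test_singleton(self):
        assert relative_site_energies([_inter("H1", gibbs_kcal=0.0)]) == {"H1": 0.0}

    def test_no_survivors_returns_absence_marker(self):
        assert relative_site_energies([]) is None


class TestStabilityParameter:
    def test_equal_minima_give_zero(self):
        assert stability_parameter(-355.5, -355.5).delta == 0.0

    def test_unit_conversion(self):
        sp = stability_parameter(-355.5 + 2.0 / HARTREE_TO_KCAL, -355.5)
        assert sp.delta == pytest.approx(2.0, abs=1e-9)

    def test_more_stable_ipso_complex_gives_larger_delta(self):
        shallow = stability_parameter(-355.5, -355.5 + 1.0 / HARTREE_TO_KCAL)
        deep = stability_parameter(-355.5, -355.5 - 1.0 / HARTREE_TO_KCAL)
        assert deep.delta > shallow.delta

    def test_absent_sear_recorded(self):
        sp = stability_parameter(-355.5, None)
        assert sp.delta is None and sp.sear_min_G is None

    def test_both_absent_is_a_domain_error(self):
        with pytest.raises(DomainError, match="either mechanism"):
            stability_parameter(None, None)


class TestClassifyMechanism:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (3.0777, Call.AMBIGUOUS),
            (-1.6369, Call.PA),
            (1.4558, Call.AMBIGUOUS),
            (-21.9298, Call.PA),
            (0.0, Call.AMBIGUOUS),  # boundaries are ambiguous-inclusive
            (5.0, Call.AMBIGUOUS),
            (5.0001, Call.SEAR),
            (-0.0001, Call.PA),
        ],
    )
    def test_threshold_rule(self, delta, expected):
        sp = StabilityParameter(delta, -1.0, -1.0)
        assert classify_mechanism(sp).call is expected

    def test_absent_mechanism_forfeits(self):
        assert classify_mechanism(StabilityParameter(None, -1.0, None)).call is Call.PA
        assert classify_mechanism(StabilityParameter(None, None, -1.0)).call is Call.SEAR

    def test_agrees_with_brute_force_rule_on_dense_grid(self):
        def oracle(delta):  # independent three-branch restatement
            if delta < 0.0:
                return Call.PA
            if delta > 5.0:
                return Call.SEAR
            return Call.AMBIGUOUS

        for delta in np.arange(-30.0, 30.0 + 1e-9, 0.01):
            d = float(delta)
            assert classify_mechanism(StabilityParameter(d, -1.0, -1.0)).call is oracle(d)


class TestBoltzmannFractions:
    def test_singleton_normalises_to_one(self):
        assert boltzmann_fractions({"H1": 0.0}) == {"H1": 1.0}

    def test_degenerate_sites_split_evenly(self):
        fr = boltzmann_fractions({"A": 0.0, "B": 0.0, "C": 0.0})
        for v in fr.values():
            assert v == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_hand_oracle_half_kcal_split(self):
        """Two sites 0.5 kcal/mol apart at 298.15 K: direct evaluation of
        exp(-dG/RT)/sum gives 0.699/0.301."""
        w = math.exp(-0.5 / (GAS_CONSTANT_KCAL * 298.15))
        expected_h1 = 1.0 / (1.0 + w)
        fr = boltzmann_fractions({"H1": 0.0, "H2": 0.5}, temperature=298.15)
        assert fr["H1"] == pytest.approx(expected_h1, abs=1e-12)
        assert fr["H1"] == pytest.approx(0.699, abs=0.001)
        assert fr["H2"] == pytest.approx(0.301, abs=0.001)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(
        energies=st.lists(st.floats(0, 50, allow_nan=False), min_size=1, max_size=8),
        shift=st.floats(-100, 100, allow_nan=False),
        temperature=st.floats(1.0, 2000.0, allow_nan=False),
    )
    def test_sum_shift_and_monotonicity_properties(self, energies, shift, temperature):
        ddg = {f"H{k+1}": e for k, e in enumerate(energies)}
        fr = boltzmann_fractions(ddg, temperature)
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)
        shifted = boltzmann_fractions({k: v + shift for k, v in ddg.items()}, temperature)
        for k in ddg:
            assert fr[k] == pytest.approx(shifted[k], abs=1e-9)
        for k1 in ddg:
            for k2 in ddg:
                if ddg[k1] < ddg[k2]:
                    assert fr[k1] >= fr[k2]

    def test_high_temperature_limit_is_uniform(self):
        fr = boltzmann_fractions({"A": 0.0, "B": 3.0, "C": 9.0}, temperature=1e9)
        for v in fr.values():
            assert v == pytest.approx(1.0 / 3.0, abs=1e-6)

    def test_low_temperature_limit_selects_the_minimum(self):
        fr = boltzmann_fractions({"A": 0.0, "B": 0.5}, temperature=1e-3)
        assert fr["A"] > 1.0 - 1e-9

    def test_empty_map_is_a_domain_error(self):
        with pytest.raises(DomainError):
            boltzmann_fractions({})


def _table_oracle(table, sid, cfg):
    """Short-path oracle: the decision layer applied directly to the energy
    table, bypassing the pipeline machinery."""
    df = table.df
    mins, sites = {}, {}
    for mech in ("PA", "SEAR"):
        grp = df[(df["substrate_id"] == sid) & (df["mechanism"] == mech)]
        if grp.empty:
            mins[mech] = None
            continue
        keep = grp[(grp["stable"] == 1)]
        keep = keep[keep["rel_gibbs_kcal"] <= cfg.prescreen_cutoff + 1e-12]
        keep = keep[keep["pd_c_angstrom"] <= cfg.pd_c_max]
        if keep.empty:
            mins[mech] = None
            continue
        rel = keep["rel_gibbs_kcal"] - keep["rel_gibbs_kcal"].min()
        sites[mech] = dict(zip(keep["h_label"], rel))
        mins[mech] = float(keep["rel_gibbs_kcal"].min() + keep["group_offset_kcal"].iloc[0])
    delta = None
    if mins["PA"] is not None and mins["SEAR"] is not None:
        delta = mins["PA"] - mins["SEAR"]
        call = (
            Call.PA if delta < cfg.threshold_pa
            else Call.SEAR if delta > cfg.threshold_sear
            else Call.AMBIGUOUS
        )
    elif mins["SEAR"] is None and mins["PA"] is None:
        call = None
    elif mins["SEAR"] is None:
        call = Call.PA
    else:
        call = Call.SEAR
    return delta, call, sites


class TestEndToEndOracleEquivalence:
    def test_predict_matches_table_level_oracle_for_every_fixture_substrate(
        self, fixture_set, tabulated_backend, default_cfg
    ):
        for sid in fixture_set.energy_table.substrates():
            delta, call, sites = _table_oracle(fixture_set.energy_table, sid, default_cfg)
            report = predict(sid, tabulated_backend, default_cfg)
            assert report.call.call is call, sid
            if delta is None:
                assert report.stability.delta is None
            else:
                assert report.stability.delta == pytest.approx(delta, abs=1e-9)
            for mech, expected_sites in sites.items():
                got = report.site_energies[mech]
                assert set(got) == set(expected_sites)
                for label, e in expected_sites.items():
                    assert got[label] == pytest.approx(e, abs=1e-9)

    def test_close_energy_sites_are_all_reported_as_products(self, tabulated_backend):
        report = predict("t2e2", tabulated_backend)
        assert report.predicted_products["SEAR"] == ["H1", "H2"]


class TestParameterRecovery:
    def test_stability_parameter_recovered_exactly_without_noise(self):
        rng = np.random.default_rng(7)
        for seed in range(100):
            offset = float(rng.uniform(-15.0, 15.0))
            be = SyntheticBackend(seed=seed, mech_offset=offset, noise_sd=0.0)
            report = predict(f"s{seed}", be)
            assert report.stability.delta == pytest.approx(offset, abs=1e-9)
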
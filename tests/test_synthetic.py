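"""Determinism and forward-model consistency of the synthetic generators."""

import numpy as np
import pytest

from csptitr.binding import BindingSystem, fraction_bound, fraction_bound_tight
from csptitr.csp import ResidueStatus, classify_residues, perturbation_profile, sigma0
from csptitr.io import write_peak_list
from csptitr.synthetic import (
    SimulationSpec,
    saturation_schedule,
    simulate_epitope_profile,
    simulate_fluorescence_titration,
    simulate_hsqc_titration,
    simulate_shift_series,
    synthetic_sequence,
)


class TestSequence:
    def test_marker_residues_and_length(self):
        seq = synthetic_sequence()
        assert len(seq) == 66
        assert seq[6] == "W" and seq[28] == "W" and seq[56] == "P"

    def test_deterministic(self):
        assert synthetic_sequence() == synthetic_sequence()


class TestShiftSeries:
    def test_noiseless_series_lies_on_tight_binding_kink(self):
        # millimolar protein, nanomolar K_D: the exact isotherm deviates
        # from the stoichiometric kink by at most sqrt(K_D/c_A) (at the
        # breakpoint itself)
        spec = SimulationSpec(normalized_noise=0.0, seed=0)
        series, _ = simulate_shift_series(spec)
        tight = np.asarray(
            fraction_bound_tight(
                BindingSystem(spec.c_protein, series.ratios * spec.c_protein, spec.n_sites)
            )
        )
        np.testing.assert_allclose(series.values, tight, atol=np.sqrt(spec.kd / spec.c_protein))

    def test_shifts_saturate_beyond_half_ratio(self):
        # in the strict stoichiometric limit the shift change is constant
        # above the breakpoint ratio 1/N = 0.5
        spec = SimulationSpec(kd=0.0, normalized_noise=0.0, seed=0)
        series, _ = simulate_shift_series(spec)
        at_half = series.values[series.ratios == 0.5][0]
        beyond = series.values[series.ratios > 0.5]
        np.testing.assert_allclose(beyond, at_half, atol=1e-12)
        assert at_half == pytest.approx(1.0)

    def test_same_seed_identical(self):
        s1, _ = simulate_shift_series(SimulationSpec(seed=42))
        s2, _ = simulate_shift_series(SimulationSpec(seed=42))
        np.testing.assert_array_equal(s1.values, s2.values)

    def test_renormalization_anchors_final_point(self):
        series, _ = simulate_shift_series(SimulationSpec(seed=4), normalize=True)
        assert series.values[-1] == 1.0


class TestFluorescence:
    def test_zero_quench_gives_flat_curve(self):
        spec = SimulationSpec(c_protein=5e-9, kd=4e-9, max_quench=0.0,
                              fluorescence_noise=0.0, seed=0)
        curve, _ = simulate_fluorescence_titration(spec)
        np.testing.assert_allclose(curve.intensity, spec.f0)

    def test_halfway_intensity_at_analytic_midpoint(self):
        # invert the quadratic isotherm for P = 1/2 in closed form and
        # check the noiseless forward model passes through it
        spec = SimulationSpec(c_protein=5e-9, kd=4e-9, fluorescence_noise=0.0, seed=0)
        c_half = (0.5 * spec.c_protein + spec.kd) / spec.n_sites
        p = fraction_bound(BindingSystem(spec.c_protein, c_half, spec.n_sites, spec.kd))
        assert p == pytest.approx(0.5, rel=1e-12)
        curve, _ = simulate_fluorescence_titration(spec)
        halfway = spec.f0 * (1.0 - spec.max_quench / 2.0)
        interp = np.interp(c_half, curve.c_ligand, curve.intensity)
        assert interp == pytest.approx(halfway, rel=0.02)

    def test_schedule_reaches_saturation(self):
        spec = SimulationSpec(c_protein=5e-9, kd=4e-9, fluorescence_noise=0.0, seed=0)
        curve, _ = simulate_fluorescence_titration(spec)
        p = fraction_bound(
            BindingSystem(spec.c_protein, float(curve.c_ligand[-1]), spec.n_sites, spec.kd)
        )
        assert p >= 0.985

    def test_warns_in_stoichiometric_regime(self):
        with pytest.warns(UserWarning, match="stoichiometric"):
            simulate_fluorescence_titration(SimulationSpec(c_protein=1e-3, kd=4e-9, seed=0))

    def test_warns_when_schedule_stops_short(self):
        spec = SimulationSpec(
            c_protein=5e-9, kd=4e-9,
            c_ligand_schedule=tuple(np.linspace(0, 2e-9, 8)), seed=0,
        )
        with pytest.warns(UserWarning, match="saturation"):
            simulate_fluorescence_titration(spec)

    def test_same_seed_identical(self):
        c1, _ = simulate_fluorescence_titration(SimulationSpec(c_protein=5e-9, kd=4e-9, seed=9))
        c2, _ = simulate_fluorescence_titration(SimulationSpec(c_protein=5e-9, kd=4e-9, seed=9))
        np.testing.assert_array_equal(c1.intensity, c2.intensity)

    def test_saturation_schedule_closed_form(self):
        sched = saturation_schedule(5e-9, 2.0, 4e-9, n_points=12)
        assert sched[0] == 0.0
        assert len(sched) == 13
        p = np.asarray(fraction_bound(BindingSystem(5e-9, sched, 2.0, 4e-9)))
        assert p[-1] == pytest.approx(0.99, rel=1e-9)


class TestHsqcTitration:
    def test_same_seed_gives_identical_files(self, tmp_path):
        for tag in ("a", "b"):
            lists, _ = simulate_hsqc_titration(SimulationSpec(seed=13))
            write_peak_list(lists[-1], tmp_path / f"{tag}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_fast_residue_tracks_bound_fraction(self):
        spec = SimulationSpec(shift_noise_ppm=0.0, seed=2)
        lists, truth = simulate_hsqc_titration(spec)
        # residue 16 is a fast-exchange epitope residue
        free = dict(lists[0].endpoint_shifts())[(16, "H")]
        positions = np.array([pl.endpoint_shifts()[(16, "H")] for pl in lists])
        delta_end = truth["endpoint_deltas"]["16:H"]
        expected = free + np.asarray(truth["bound_fraction"]) * delta_end
        np.testing.assert_allclose(positions, expected, atol=1e-12)

    def test_slow_residue_splits_into_two_peaks(self):
        spec = SimulationSpec(shift_noise_ppm=0.0, seed=2)
        lists, truth = simulate_hsqc_titration(spec)
        # mid-titration: both free and bound W29 side-chain peaks present
        mid = lists[2]
        states = {p.state for p in mid.peaks if p.residue_index == 29 and p.atom == "HE1"}
        assert states == {"free", "bound"}
        intens = {p.state: p.intensity for p in mid.peaks
                  if p.residue_index == 29 and p.atom == "HE1"}
        assert intens["free"] + intens["bound"] == pytest.approx(1.0)
        # endpoint beyond the breakpoint: free peak gone
        last_states = {p.state for p in lists[-1].peaks
                       if p.residue_index == 29 and p.atom == "HE1"}
        assert last_states == {"bound"}

    def test_disappear_residue_dropped_mid_titration(self):
        spec = SimulationSpec(shift_noise_ppm=0.0, seed=2)
        lists, truth = simulate_hsqc_titration(spec)
        p_bound = truth["bound_fraction"]
        lo, hi = spec.disappear_band
        for pl, p in zip(lists, p_bound):
            present = any(pk.residue_index == 9 for pk in pl.peaks)
            assert present == (not lo <= p <= hi)


class TestEpitopeProfile:
    def test_zero_noise_single_epitope_residue(self):
        spec = SimulationSpec(
            epitope_residues=frozenset({16}), disappear_residues=frozenset(),
            slow_residues=frozenset(), background_sigma_ppm=0.0,
            shift_noise_ppm=0.0, epitope_sigma_ppm=0.01, seed=0,
        )
        free, bound, _ = simulate_epitope_profile(spec)
        profile = perturbation_profile(
            free.endpoint_shifts(("free", "")), bound.endpoint_shifts(("bound", ""))
        )
        nonzero = {p.residue_index for p in profile if p.delta_comb > 0}
        assert nonzero == {16}

    def test_disappear_flag_round_trips_to_classification(self):
        spec = SimulationSpec(seed=6)
        free, bound, truth = simulate_epitope_profile(spec)
        profile = perturbation_profile(
            free.endpoint_shifts(("free", "")), bound.endpoint_shifts(("bound", ""))
        )
        emap = classify_residues(profile, sigma0(profile))
        for idx in truth["disappear_residues"]:
            assert emap.classes[idx].value == "disappeared-high"

    def test_proline_absent_from_peak_lists(self):
        free, bound, _ = simulate_epitope_profile(SimulationSpec(seed=1))
        assert 57 not in {p.residue_index for p in free.peaks}

    def test_empty_epitope_rejected(self):
        with pytest.raises(ValueError):
            spec = SimulationSpec(
                epitope_residues=frozenset(), disappear_residues=frozenset(),
                slow_residues=frozenset(), seed=0,
            )
            simulate_epitope_profile(spec)
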
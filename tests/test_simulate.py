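"""Tests for the synthetic-data generators against their stated statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from smstoich.simulate import (
    ElutionSpec,
    FieldSpec,
    PopulationSpec,
    TraceSpec,
    montecarlo_observables,
    render_field,
    simulate_elution,
    simulate_population,
    simulate_titration,
    simulate_traces,
)
from smstoich.stoichiometry import forward_colocalization, forward_onestep


class TestPopulation:
    def test_pure_labeled_monomers(self):
        pop = simulate_population(
            PopulationSpec(
                fraction_monomer=1.0, labeling_efficiency=1.0, n_complexes=100, seed=0
            )
        )
        assert (pop.sizes == 1).all()
        assert ((pop.n_red + pop.n_green) == 1).all()

    def test_deterministic_given_seed(self):
        spec = PopulationSpec(fraction_monomer=0.7, n_complexes=5000, seed=42)
        a, b = simulate_population(spec), simulate_population(spec)
        assert (a.sizes == b.sizes).all()
        assert (a.n_red == b.n_red).all()
        assert (a.n_green == b.n_green).all()

    def test_dimer_tag_assortment_converges(self):
        """Among dimers, tag classes approach 0.25 : 0.25 : 0.5."""
        pop = simulate_population(
            PopulationSpec(fraction_monomer=0.0, n_complexes=200_000, seed=1)
        )
        counts = np.bincount(pop.n_tag_a, minlength=3)
        freqs = counts / counts.sum()
        se = 3 * np.sqrt(0.25 * 0.75 / counts.sum())
        assert freqs[2] == pytest.approx(0.25, abs=se)  # same-A
        assert freqs[0] == pytest.approx(0.25, abs=se)  # same-B
        assert freqs[1] == pytest.approx(0.50, abs=2 * se)  # mixed

    def test_dimer_red_labeling_matches_binomial(self):
        """P(>=1 red | A-tag-containing dimer class) follows Bernoulli(L) labeling."""
        L, n = 0.82, 1_000_000
        pop = simulate_population(
            PopulationSpec(
                fraction_monomer=0.0, labeling_efficiency=L, n_complexes=n, seed=2
            )
        )
        # same-A dimers: P(>=1 red) = 1 - (1-L)^2; mixed: P(red) = L
        for n_a, expected in ((2, 1 - (1 - L) ** 2), (1, L)):
            sel = pop.n_tag_a == n_a
            obs = (pop.n_red[sel] >= 1).mean()
            se = 3 * np.sqrt(expected * (1 - expected) / sel.sum())
            assert obs == pytest.approx(expected, abs=se)

    def test_montecarlo_matches_closed_forms(self):
        """Simulated observables agree with the enumerated mixture models."""
        M, L, n = 0.6, 0.7, 400_000
        C_mc, B1_mc = montecarlo_observables(M, L, n=n, seed=3)
        C_th, B1_th = forward_colocalization(M, L), forward_onestep(M, L)
        # red-conditioned sample sizes are smaller than n; bound SE conservatively
        se_c = 3 * np.sqrt(C_th * (1 - C_th) / (0.3 * n))
        se_b = 3 * np.sqrt(B1_th * (1 - B1_th) / (0.3 * n))
        assert C_mc == pytest.approx(C_th, abs=se_c)
        assert B1_mc == pytest.approx(B1_th, abs=se_b)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            PopulationSpec(fraction_monomer=0.7, fraction_dimer=0.7)


class TestRenderField:
    def test_empty_population_background_only(self):
        pop = simulate_population(
            PopulationSpec(
                fraction_monomer=1.0, labeling_efficiency=0.0001,
                n_complexes=3, seed=0,
            )
        )
        # force all-unlabeled by filtering
        pop.n_red[:] = 0
        pop.n_green[:] = 0
        field = FieldSpec(noise=False)
        images, truth = render_field(pop, field, seed=1)
        assert truth.empty
        assert images["red"] == pytest.approx(field.background_mean)

    def test_expected_spot_count_arithmetic(self):
        field = FieldSpec(spot_density=2.0, pixel_size_um=0.27)
        assert field.expected_spot_count() == pytest.approx(
            2 * (512 * 0.27) ** 2 / 100, rel=1e-12
        )
        assert field.expected_spot_count() == pytest.approx(382, abs=1)

    def test_noiseless_integrated_intensity_exact(self):
        pop = simulate_population(
            PopulationSpec(
                fraction_monomer=1.0, labeling_efficiency=1.0, n_complexes=5, seed=4
            )
        )
        field = FieldSpec(noise=False, psf_sigma=1.2)
        images, truth = render_field(pop, field, seed=5)
        total = images["red"].sum() + images["green"].sum()
        background = 2 * 512 * 512 * field.background_mean
        n_dyes = truth["n_red"].sum() + truth["n_green"].sum()
        assert total - background == pytest.approx(
            n_dyes * field.unit_intensity, rel=1e-9
        )

    def test_minimum_separation_enforced(self):
        pop = simulate_population(
            PopulationSpec(
                fraction_monomer=1.0, labeling_efficiency=1.0,
                n_complexes=300, seed=6,
            )
        )
        field = FieldSpec(noise=False)
        _, truth = render_field(pop, field, seed=7)
        xy = truth[["x_px", "y_px"]].to_numpy()
        d = np.hypot(*(xy[None] - xy[:, None]).T)[np.triu_indices(len(xy), 1)]
        assert d.min() >= field.min_separation_factor * field.psf_sigma

    def test_overdense_request_rejected(self):
        pop = simulate_population(
            PopulationSpec(
                fraction_monomer=1.0, labeling_efficiency=1.0,
                n_complexes=5000, seed=8,
            )
        )
        with pytest.raises(ValueError):
            render_field(pop, FieldSpec(image_size=(64, 64)), seed=9)


class TestTraces:
    def test_single_dye_noiseless_one_step(self):
        spec = TraceSpec(noise_sigma=0.0, bleach_rate_per_s=0.1)
        traces, truth = simulate_traces([1], spec, seed=0)
        y = traces[0]
        drops = np.nonzero(np.diff(y) < 0)[0]
        assert truth.loc[0, "n_dyes"] == 1
        if truth.loc[0, "complete"]:
            assert len(drops) == 1
            assert y[-1] == 0.0

    def test_two_dyes_bleach_within_long_movie(self):
        """At 0.01/frame over 1000 frames both dyes bleach essentially always."""
        spec = TraceSpec(
            n_frames=1000, frame_interval_s=0.1, bleach_rate_per_s=0.1,
            noise_sigma=0.0,
        )
        _, truth = simulate_traces([2] * 500, spec, seed=1)
        assert truth["complete"].mean() >= 0.99

    def test_step_times_exponential(self):
        """Observed single-dye bleach times pass a KS test for exponential."""
        spec = TraceSpec(n_frames=5000, bleach_rate_per_s=0.05, noise_sigma=0.0)
        _, truth = simulate_traces([1] * 2000, spec, seed=2)
        sel = truth["complete"] & (truth["step_frames"] != "")
        frames = truth.loc[sel, "step_frames"].astype(int)
        times = frames * spec.frame_interval_s
        ks = stats.kstest(times, "expon", args=(0, 1 / spec.bleach_rate_per_s))
        assert ks.pvalue > 0.01

    def test_red_conditioning_required(self):
        with pytest.raises(ValueError):
            simulate_traces([0, 1], TraceSpec(), seed=0)

    def test_short_movie_warns(self):
        with pytest.warns(UserWarning):
            simulate_traces([1], TraceSpec(n_frames=60, bleach_rate_per_s=0.01),
                            seed=3)


class TestTitration:
    def test_half_saturation_and_plateau_means(self):
        amp = 400.0
        df = simulate_titration(
            kd_nM=5.0, amplitude=amp,
            concentrations_nM=(5.0, 5000.0), n_fields=400, seed=0,
        )
        g = df.groupby("concentration_nM")["spot_count"].mean()
        assert g[5.0] == pytest.approx(amp / 2, rel=0.05)
        assert g[5000.0] == pytest.approx(amp, rel=0.05)

    def test_occupancy_at_top_concentration(self):
        df = simulate_titration(4.9, 1000.0, concentrations_nM=(30.0,),
                                n_fields=200, seed=1)
        assert df["spot_count"].mean() / 1000.0 == pytest.approx(30 / 34.9, rel=0.02)

    def test_invalid_kd(self):
        with pytest.raises(ValueError):
            simulate_titration(0.0, 100.0)


class TestElution:
    def test_no_productive_fraction_conditions_identical(self):
        spec = ElutionSpec(fraction_productive=0.0, k_specific_per_min=0.1,
                           k_background_per_min=0.01)
        df = simulate_elution(spec, n_spots=20_000, seed=0)
        at30 = df[df["time_min"] == 30.0].groupby("condition")["spot_count"].sum()
        assert at30["dNTP"] == pytest.approx(at30["buffer"], rel=0.03)

    def test_half_life_under_dntps(self):
        """k_specific * t = ln 2 with no background leaves half the spots."""
        k = np.log(2) / 30.0
        spec = ElutionSpec(fraction_productive=1.0, k_specific_per_min=k,
                           k_background_per_min=0.0, timepoints_min=(0.0, 30.0))
        df = simulate_elution(spec, n_spots=50_000, seed=1)
        d = df[df["condition"] == "dNTP"].groupby("time_min")["spot_count"].sum()
        assert d[30.0] / d[0.0] == pytest.approx(0.5, abs=0.02)
        b = df[df["condition"] == "buffer"].groupby("time_min")["spot_count"].sum()
        assert b[30.0] == b[0.0]  # nothing leaves without dNTPs


class TestDepletionEmulation:
    @pytest.mark.parametrize("L", [0.51, 0.82, 1.0])
    def test_labeling_efficiency_recovered(self, L):
        """Depletion correction on simulated counts recovers L within 0.03."""
        from smstoich.simulate import simulate_depletion
        from smstoich.stoichiometry import estimate_labeling_efficiency

        d = simulate_depletion(L, capture_efficiency=0.62, seed=13)
        est = estimate_labeling_efficiency(d)
        assert est.value == pytest.approx(L, abs=0.03)
        assert est.lower_bound <= est.value <= est.upper_bound


class TestGroundTruthConsistency:
    def test_spot_table_dye_counts_feed_trace_truth(self):
        """Rendered red-dye counts and trace-truth dye counts agree."""
        pop = simulate_population(
            PopulationSpec(fraction_monomer=0.8, labeling_efficiency=0.82,
                           protocol="single_color", n_complexes=200, seed=10)
        )
        _, spot_truth = render_field(pop, FieldSpec(noise=False), seed=11)
        red = spot_truth.loc[spot_truth["n_red"] >= 1, "n_red"].to_numpy()
        _, trace_truth = simulate_traces(red, TraceSpec(), seed=12)
        assert (trace_truth["n_dyes"].to_numpy() == red).all()
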
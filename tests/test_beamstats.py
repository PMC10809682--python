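"""Spectra/angular/fluence binning against naive loops, and PA properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linacqa.beamstats import (
    Histogram1D, RegionSpec, angular_distribution, default_regions,
    pa_matrix, percentage_agreement, radial_energy_fluence,
    ring_energy_spectrum,
)
from linacqa.phasespace import ELECTRON, PHOTON, DECODED_DTYPE, ParticleRecord, \
    PhaseSpace
from linacqa.synthetic import beam_preset, generate_phasespace
from conftest import make_phasespace


def _mono_ps(n, energy, r, weight=1.0, n_hist=None):
    """Phase space of identical axial photons at radius r from the CAX."""
    recs = [ParticleRecord(PHOTON, energy, r, 0.0, 0.0, 0.0, 1, weight, True)
            for _ in range(n)]
    return PhaseSpace.from_records(recs, 26.7, n_hist or n)


# ---------------------------------------------------------------- spectra

class TestRingSpectrum:
    def test_counting_example(self):
        ps = _mono_ps(5, energy=1.0, r=0.5)
        h = ring_energy_spectrum(ps, RegionSpec("ring", 0, 1), [0.9, 1.1])
        assert h.values[0] == pytest.approx(1.0)

    def test_disjoint_region_is_zero(self):
        ps = _mono_ps(5, energy=1.0, r=0.5)
        h = ring_energy_spectrum(ps, RegionSpec("ring", 3, 4), [0.9, 1.1])
        assert (h.values == 0).all()

    def test_conservation_against_weighted_sum(self):
        ps = make_phasespace(n=10_000, seed=13)
        region = RegionSpec("ring", 1, 3)
        edges = np.arange(0.0, 6.5, 0.05)
        h = ring_energy_spectrum(ps, region, edges)
        r = np.hypot(ps.records["x"], ps.records["y"])
        in_region = ((r >= 1) & (r < 3) & (ps.records["kind"] == PHOTON)
                     & (ps.records["energy"] < edges[-1]))
        direct = float(ps.records["weight"][in_region].sum())
        n = ps.header.n_original_histories
        assert h.values.sum() * n == pytest.approx(direct, rel=1e-12)

    def test_matches_naive_loop_exactly(self):
        ps = make_phasespace(n=5_000, seed=17, kinds=(PHOTON, ELECTRON))
        region = RegionSpec("ring", 0, 2)
        edges = np.arange(0.0, 6.5, 0.25)
        h = ring_energy_spectrum(ps, region, edges)
        want = np.zeros(len(edges) - 1)
        n = ps.header.n_original_histories
        for rec in ps.iter_particles():  # independent brute-force oracle
            if rec.kind != PHOTON:
                continue
            rr = math.hypot(rec.x, rec.y)
            if not (region.r_lo <= rr < region.r_hi):
                continue
            for b in range(len(edges) - 1):
                closed = (b == len(edges) - 2)
                if edges[b] <= rec.energy < edges[b + 1] or (
                        closed and rec.energy == edges[-1]):
                    want[b] += rec.weight
        np.testing.assert_array_equal(h.values, want / n)

    def test_empty_phasespace_gives_zero_histogram(self):
        ps = PhaseSpace.from_records([], 26.7, 10)
        h = ring_energy_spectrum(ps, RegionSpec("ring", 0, 1), [0, 1, 2])
        assert (h.values == 0).all()

    def test_zero_histories_is_normalization_error(self):
        ps = PhaseSpace.from_records([], 26.7, 0)
        with pytest.raises(ValueError, match="histories"):
            ring_energy_spectrum(ps, RegionSpec("ring", 0, 1), [0, 1])


# ------------------------------------------------------------- angular

class TestAngularDistribution:
    def test_axial_beam_fills_first_bin(self):
        ps = _mono_ps(20, energy=1.0, r=0.5, weight=0.7)
        h = angular_distribution(ps, RegionSpec("circle", 0, 6),
                                 theta_edges=np.arange(0.0, 90.5, 1.0))
        domega = 2 * np.pi * (1 - math.cos(math.radians(1.0)))
        assert h.values[0] == pytest.approx(20 * 0.7 / (20 * domega))
        assert (h.values[1:] == 0).all()

    def test_isotropic_forward_hemisphere_is_flat(self):
        rng = np.random.default_rng(8)
        n = 200_000
        rec = np.zeros(n, dtype=DECODED_DTYPE)
        rec["kind"] = PHOTON
        rec["energy"] = 1.0
        rec["weight"] = 1.0
        rec["w"] = rng.random(n)  # uniform cos(theta): isotropic per solid angle
        rec["new_history"] = True
        ps = PhaseSpace.from_records(rec, 26.7, n)
        h = angular_distribution(ps, RegionSpec("circle", 0, 6),
                                 theta_edges=np.linspace(0, 90, 19))
        se = h.unc
        mean = np.average(h.values, weights=1 / se**2)
        assert (np.abs(h.values - mean) < 3.5 * se).all()

    def test_backward_particles_reported_not_dropped(self):
        rec = np.zeros(3, dtype=DECODED_DTYPE)
        rec["kind"] = PHOTON
        rec["energy"] = 1.0
        rec["weight"] = [1.0, 2.0, 3.0]
        rec["w"] = [0.5, -0.8, -0.6]
        ps = PhaseSpace.from_records(rec, 26.7, 3)
        h = angular_distribution(ps, RegionSpec("circle", 0, 6))
        assert h.overflow_weight == pytest.approx(5.0 / 3)

    def test_solid_angle_integral_recovers_weight(self, small_ps):
        region = RegionSpec("circle", 0, 6)
        h = angular_distribution(small_ps, region)
        rad = np.radians(h.edges)
        domega = 2 * np.pi * (np.cos(rad[:-1]) - np.cos(rad[1:]))
        integral = float(np.sum(h.values * domega))
        rec = small_ps.records
        r = np.hypot(rec["x"], rec["y"])
        sel = (r < 6) & (rec["w"] > 0) & (rec["kind"] == PHOTON)
        direct = float(rec["weight"][sel].sum()) / small_ps.header.n_original_histories
        assert integral == pytest.approx(direct, rel=1e-12)

    def test_empty_region_zero(self, small_ps):
        far = RegionSpec("ring", 50, 60)
        h = ring_energy_spectrum(small_ps, far, [0, 1, 2])
        assert (h.values == 0).all()


# ------------------------------------------------------------- radial

class TestRadialEnergyFluence:
    def test_single_particle_arithmetic(self):
        ps = _mono_ps(1, energy=2.0, r=0.1)
        h = radial_energy_fluence(ps, r_max=5.0, dr=0.2)
        assert h.values[0] == pytest.approx(2.0 / (np.pi * 0.2**2))
        assert (h.values[1:] == 0).all()

    def test_weight_linearity(self, small_ps):
        h1 = radial_energy_fluence(small_ps)
        doubled = small_ps.records.copy()
        doubled["weight"] *= 2
        ps2 = PhaseSpace.from_records(doubled, 26.7,
                                      small_ps.header.n_original_histories)
        h2 = radial_energy_fluence(ps2)
        np.testing.assert_array_equal(h2.values, 2 * h1.values)

    def test_uniform_disc_is_flat(self):
        ps = make_phasespace(n=150_000, seed=10, r_max=5.0)
        rec = ps.records
        rec["energy"] = 1.0
        rec["weight"] = 1.0
        h = radial_energy_fluence(ps, r_max=5.0, dr=0.5)
        se = h.unc
        mean = np.average(h.values, weights=1 / se**2)
        assert (np.abs(h.values - mean) < 3.5 * se).all()

    def test_matches_naive_loop_exactly(self, small_ps):
        h = radial_energy_fluence(small_ps, r_max=5.0, dr=0.2)
        edges = h.edges
        want = np.zeros(len(edges) - 1)
        for rec in small_ps.iter_particles():
            if rec.kind != PHOTON:
                continue
            rr = math.hypot(rec.x, rec.y)
            if rr >= 5.0:
                continue
            b = min(int(rr / 0.2), len(want) - 1)
            if not (edges[b] <= rr < edges[b + 1]):
                b = int(np.searchsorted(edges, rr, side="right")) - 1
            want[b] += rec.energy * rec.weight
        areas = np.pi * (edges[1:]**2 - edges[:-1]**2)
        np.testing.assert_allclose(
            h.values, want / (small_ps.header.n_original_histories * areas),
            rtol=1e-12)


# ------------------------------------------------------------------ PA

def histograms(n_bins=4):
    vals = st.lists(st.floats(0, 10, allow_nan=False), min_size=n_bins,
                    max_size=n_bins)
    return vals.map(lambda v: Histogram1D(
        edges=np.arange(n_bins + 1, dtype=float), values=np.array(v),
        unc=np.zeros(n_bins), norm_tag="per_history_fluence"))


class TestPercentageAgreement:
    def test_identity_scores_100(self):
        h = Histogram1D([0, 1, 2], [2.0, 3.0], [0, 0], "per_history_fluence")
        assert percentage_agreement(h, h).pa == 100.0

    def test_zero_against_nonzero_scores_0(self):
        h = Histogram1D([0, 1, 2], [2.0, 3.0], [0, 0], "per_history_fluence")
        z = Histogram1D([0, 1, 2], [0.0, 0.0], [0, 0], "per_history_fluence")
        assert percentage_agreement(h, z).pa == 0.0

    def test_both_zero_defined_as_100(self):
        z = Histogram1D([0, 1, 2], [0.0, 0.0], [0, 0], "per_history_fluence")
        assert percentage_agreement(z, z).pa == 100.0

    def test_hand_example(self):
        """Unit bins, [2,2] vs [1,3]: areas 4 and 4, delta 2, PA 50."""
        a = Histogram1D([0, 1, 2], [2.0, 2.0], [0, 0], "per_history_fluence")
        b = Histogram1D([0, 1, 2], [1.0, 3.0], [0, 0], "per_history_fluence")
        res = percentage_agreement(a, b)
        assert res.area_a == res.area_b == 4.0
        assert res.delta == 2.0
        assert res.pa == 50.0

    def test_mismatched_binning_rejected(self):
        a = Histogram1D([0, 1, 2], [1.0, 1.0], [0, 0], "per_history_fluence")
        b = Histogram1D([0, 2, 4], [1.0, 1.0], [0, 0], "per_history_fluence")
        with pytest.raises(ValueError):
            percentage_agreement(a, b)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(histograms(), histograms())
    def test_symmetry_and_bounds(self, h_a, h_b):
        r_ab = percentage_agreement(h_a, h_b)
        r_ba = percentage_agreement(h_b, h_a)
        assert r_ab.pa == pytest.approx(r_ba.pa, abs=1e-9)
        assert 0.0 <= r_ab.pa <= 100.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(histograms(), st.lists(st.floats(0, 1), min_size=4, max_size=4))
    def test_monotone_in_added_perturbation(self, h, g_vals):
        """PA(h, h + eps*g) is non-increasing in eps for non-negative g."""
        g = np.array(g_vals)
        prev = 100.0
        for eps in (0.0, 0.5, 1.0, 2.0, 5.0):
            pert = Histogram1D(h.edges, h.values + eps * g, h.unc, h.norm_tag)
            pa = percentage_agreement(h, pert).pa
            assert pa <= prev + 1e-9
            prev = pa


class TestPAMatrix:
    def test_self_comparison_is_all_100(self):
        model = beam_preset("6MV")
        ps = generate_phasespace(model, 20_000, seed=31)
        df = pa_matrix(ps, ps)
        assert df.shape == (1, 8)
        assert (df.iloc[0] == 100.0).all()

    def test_region_labels_match_layout(self):
        labels = [r.label for r in default_regions()]
        assert labels == ["[0-1]", "[1-2]", "[2-3]", "[3-4]", "[4-5]",
                          "[5-6]", "[6-7]", "[0-6]"]

    def test_discrepant_beam_lowers_inner_ring_pa(self):
        base = beam_preset("15MV")
        disc = beam_preset("15MV-discrepant")
        ps_a = generate_phasespace(base, 60_000, seed=2)
        ps_b = generate_phasespace(disc, 60_000, seed=3)
        df = pa_matrix(ps_a, ps_b)
        assert df.iloc[0]["[0-1]"] < 100.0
        self_df = pa_matrix(ps_a, ps_a)
        assert df.iloc[0]["[0-1]"] < self_df.iloc[0]["[0-1]"]
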
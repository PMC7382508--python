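"""Radial histogram → PMF → K_bind → ΔG, bootstrap, experiment comparison."""

import numpy as np
import pytest

from cgbind.constants import C0_STANDARD, rt
from cgbind.datasets import T4_LYSOZYME_DELTA_G
from cgbind.free_energy import (PMFParams, binding_constant,
                                binding_free_energy, bootstrap_error,
                                compare_to_experiment, compute_pmf,
                                radial_histogram, standard_free_energy)
from cgbind.synthetic import (SyntheticModel, sample_boltzmann_radii,
                              square_well_binding_constant)
from cgbind.trajectory import DistanceSeries


def as_series(r, replica="replica-0"):
    r = np.sort(np.asarray(r, dtype=float))
    return DistanceSeries(replica, times=np.arange(r.size) * 1e-3, distances=r)


NOSHIFT = PMFParams(shift=0.0)


class TestRadialHistogram:
    def test_delta_sample_occupies_single_bin(self):
        centers, p = radial_histogram(as_series(np.full(100, 2.025)), NOSHIFT)
        occupied = np.flatnonzero(p > 0)
        assert occupied.size == 1
        assert p[occupied[0]] == pytest.approx(1.0 / NOSHIFT.bin_width)

    def test_normalisation(self, rng):
        centers, p = radial_histogram(as_series(rng.uniform(0.5, 4.0, 10_000)),
                                      NOSHIFT)
        assert np.sum(p) * NOSHIFT.bin_width == pytest.approx(1.0)

    def test_uniform_in_sphere_gives_r_squared_density(self, rng):
        # ideal-gas positions in a sphere: p(r) ∝ r²
        n = 200_000
        pts = rng.uniform(-1, 1, size=(4 * n, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= 1.0][:n] * 4.0
        r = np.linalg.norm(pts, axis=1)
        centers, p = radial_histogram(as_series(r), NOSHIFT)
        sel = (centers > 1.0) & (centers < 3.5)  # away from edges
        ratio = p[sel] / centers[sel] ** 2
        assert np.std(ratio) / np.mean(ratio) < 0.05

    def test_shift_moves_bins(self):
        params = PMFParams(shift=0.25)
        centers, p = radial_histogram(as_series(np.full(50, 1.00)), params)
        occupied_center = centers[np.argmax(p)]
        assert abs(occupied_center - 1.25) <= params.bin_width


class TestComputePMF:
    def test_ideal_gas_pmf_is_flat_zero(self, rng):
        n = 500_000
        pts = rng.uniform(-1, 1, size=(3 * n, 3))
        pts = pts[np.linalg.norm(pts, axis=1) <= 1.0][:n] * 5.0
        r = np.linalg.norm(pts, axis=1)
        params = PMFParams(shift=0.0, r_ref=4.5)
        centers, p = radial_histogram(as_series(r), params)
        pmf = compute_pmf(centers, p, params)
        sel = (centers > 0.5) & (centers < 4.8) & pmf.occupied()
        assert np.max(np.abs(pmf.pmf[sel])) < 0.35  # kJ/mol, sampling noise

    def test_recovers_imposed_square_well_depth(self):
        model = SyntheticModel(potential_kind="square_well", well_depth=20.0,
                              well_width=0.5, seed=5)
        r = sample_boltzmann_radii(model, 2_000_000, r_max=5.0, seed=6)
        params = PMFParams(shift=0.0)
        centers, p = radial_histogram(as_series(r), params)
        pmf = compute_pmf(centers, p, params)
        well = pmf.occupied() & (centers < 0.45)
        assert np.all(np.abs(pmf.pmf[well] + 20.0) < 0.5)

    def test_pmf_linear_in_rt(self, rng):
        r = rng.uniform(0.2, 5.0, 100_000)
        params300 = PMFParams(shift=0.0, temperature=300.0)
        params600 = PMFParams(shift=0.0, temperature=600.0)
        centers, p = radial_histogram(as_series(r), params300)
        pmf300 = compute_pmf(centers, p, params300)
        pmf600 = compute_pmf(centers, p, params600)
        ok = pmf300.occupied()
        assert np.allclose(pmf600.pmf[ok], 2.0 * pmf300.pmf[ok], atol=1e-9)

    def test_unanchorable_reference_rejected(self):
        params = PMFParams(shift=0.0, r_ref=4.5)
        centers, p = radial_histogram(as_series(np.full(10, 1.0)), params)
        with pytest.raises(ValueError):
            compute_pmf(centers, p, params)


class TestBindingConstant:
    def test_flat_pmf_gives_sphere_volume(self):
        params = PMFParams(shift=0.0)
        centers = np.arange(0.025, 5.0, 0.05)
        p = centers**2
        p /= p.sum() * 0.05
        pmf = compute_pmf(centers, p, params)
        k = binding_constant(pmf, 4.0)
        assert k == pytest.approx(4.0 / 3.0 * np.pi * 4.0**3, rel=0.01)

    def test_boltzmann_sampled_square_well_matches_closed_form(self):
        model = SyntheticModel(potential_kind="square_well", well_depth=20.0,
                              well_width=0.5, seed=5)
        r = sample_boltzmann_radii(model, 2_000_000, r_max=5.0, seed=6)
        params = PMFParams(shift=0.0)
        dg, pmf = binding_free_energy(as_series(r), params)
        k_sharp = square_well_binding_constant(0.5, 20.0, 300.0, 4.0)
        # the simulated well is ramp-smoothed, so compare loosely to the
        # sharp-well closed form
        assert dg.k_bind == pytest.approx(k_sharp, rel=0.2)
        # and tightly to the smoothed-potential quadrature
        from cgbind.synthetic import analytic_binding_constant

        assert dg.k_bind == pytest.approx(analytic_binding_constant(model, 4.0),
                                          rel=0.05)

    def test_deeper_well_gives_larger_k(self):
        ks = []
        for eps in (15.0, 20.0):
            model = SyntheticModel(potential_kind="square_well", well_depth=eps,
                                  well_width=0.5, seed=5)
            r = sample_boltzmann_radii(model, 500_000, r_max=5.0, seed=6)
            dg, _ = binding_free_energy(as_series(r), PMFParams(shift=0.0))
            ks.append(dg.k_bind)
        assert ks[1] > ks[0]

    def test_rc_beyond_range_rejected(self):
        params = PMFParams(shift=0.0)
        centers, p = radial_histogram(as_series(np.linspace(0.2, 2.0, 100)), params)
        pmf = compute_pmf(centers, p, PMFParams(shift=0.0, r_ref=1.9))
        with pytest.raises(ValueError):
            binding_constant(pmf, 4.0)

    def test_masked_bins_contribute_zero(self):
        params = PMFParams(shift=0.0)
        centers = np.arange(0.025, 5.0, 0.05)
        p = centers**2
        p[(centers > 1.0) & (centers < 2.0)] = 0.0  # excluded volume
        p /= p.sum() * 0.05
        pmf = compute_pmf(centers, p, params)
        k_masked = binding_constant(pmf, 4.0)
        full = centers**2 / (centers**2).sum() / 0.05
        k_full = binding_constant(compute_pmf(centers, full, params), 4.0)
        missing = 4.0 / 3.0 * np.pi * (2.0**3 - 1.0**3)
        assert k_full - k_masked == pytest.approx(missing, rel=0.05)


class TestStandardFreeEnergy:
    def test_unit_kc0_is_zero(self):
        assert standard_free_energy(1.66) == pytest.approx(0.0, abs=1e-12)

    def test_square_well_value(self):
        # K = 1.86e3 nm^3 at 300 K -> about -17.5 kJ/mol
        k = square_well_binding_constant(0.5, 20.0, 300.0, 4.0)
        assert standard_free_energy(k) == pytest.approx(-17.5, abs=0.1)

    def test_flat_baseline_value(self):
        k = 4.0 / 3.0 * np.pi * 4.0**3
        assert standard_free_energy(k) == pytest.approx(-12.7, abs=0.1)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            standard_free_energy(0.0)


class TestEndToEnd:
    def test_bin_width_refinement_stable(self, well_series):
        dg1, _ = binding_free_energy(well_series, PMFParams(shift=0.0, bin_width=0.05))
        dg2, _ = binding_free_energy(well_series, PMFParams(shift=0.0, bin_width=0.025))
        assert abs(dg1.delta_g - dg2.delta_g) < 0.3

    def test_flat_potential_pmf_flat_within_bootstrap_band(self, flat_series):
        """Flat potential: |PMF| stays within its per-bin bootstrap error.

        With ~90 bins a few 3σ excursions are expected by chance, so the
        bound is 95% of bins within 3σ and every bin within 5σ.
        """
        from cgbind.free_energy import bootstrap_pmf_band, compute_pmf, radial_histogram

        pooled_max = float(max(np.max(s.distances) for s in flat_series))
        params = PMFParams(shift=0.0, r_max=pooled_max)
        centers, sd = bootstrap_pmf_band(flat_series, params, n_boot=100, seed=1)
        c, p = radial_histogram(flat_series, params)
        pmf = compute_pmf(c, p, params)
        sel = pmf.occupied() & (centers > 0.5) & (centers < 5.0) & (sd > 0)
        ratio = np.abs(pmf.pmf[sel]) / sd[sel]
        assert np.mean(ratio <= 3.0) >= 0.95
        assert np.max(ratio) <= 5.0

    def test_consistency_of_equivalent_k_expressions(self, well_series):
        """K from e^(−PMF/RT) equals K from normalized p(r) rescaled at the
        anchor — the two integrands are proportional by construction."""
        params = PMFParams(shift=0.0)
        dg, pmf = binding_free_energy(well_series, params)
        centers = pmf.bin_centers
        occ = pmf.occupied()
        anchor = np.flatnonzero(occ)[
            np.argmin(np.abs(centers[occ] - params.r_ref))]
        scale = pmf.r_effective[anchor] ** 2 / pmf.p[anchor]
        integrand = np.where(occ, 4 * np.pi * pmf.p * scale, 0.0)
        inside = centers <= params.r_c
        x = np.concatenate([[0.0], centers[inside],
                            [min(params.r_c, centers[-1] + pmf.bin_width / 2)]])
        y = np.concatenate([[0.0], integrand[inside], [integrand[inside][-1]]])
        k_alt = np.trapezoid(y, x)
        assert k_alt == pytest.approx(dg.k_bind, rel=1e-9)


class TestBootstrap:
    def test_identical_replicas_zero_error(self, rng):
        r = rng.uniform(0.2, 5.0, 50_000)
        reps = [as_series(r, f"replica-{i}") for i in range(4)]
        err = bootstrap_error(reps, PMFParams(shift=0.0), n_boot=50, seed=2)
        assert err == pytest.approx(0.0, abs=1e-9)

    def test_seed_reproducibility(self, well_series):
        params = PMFParams(shift=0.0)
        e1 = bootstrap_error(well_series, params, n_boot=50, seed=9)
        e2 = bootstrap_error(well_series, params, n_boot=50, seed=9)
        assert e1 == e2

    def test_error_shrinks_with_replica_count(self, flat_series):
        """CLT scaling: the 12-replica error vs the mean 4-replica error.

        Disjoint 4-replica subsets average out the instability of a
        small-sample bootstrap; expected ratio sqrt(4/12) ≈ 0.58, checked
        within a factor 2.
        """
        params = PMFParams(shift=0.0)
        subset_errs = [bootstrap_error(flat_series[i:i + 4], params,
                                       n_boot=100, seed=3) for i in (0, 4, 8)]
        full = bootstrap_error(flat_series, params, n_boot=100, seed=3)
        ratio = full / np.mean(subset_errs)
        assert 0.29 < ratio < 1.16

    def test_single_replica_rejected(self, well_series):
        with pytest.raises(ValueError):
            bootstrap_error(well_series[:1], PMFParams())


class TestExperimentComparison:
    def test_published_benchmark_table(self):
        cmp = compare_to_experiment(T4_LYSOZYME_DELTA_G, rounding=1.0)
        assert len(cmp.systems) == 6  # non-binders dropped
        assert cmp.mae == pytest.approx(1.0)
        assert cmp.max_error == pytest.approx(2.0)

    def test_identical_columns(self):
        cmp = compare_to_experiment({"a": (-10.0, -10.0), "b": (-12.0, -12.0)})
        assert cmp.mae == 0.0 and cmp.max_error == 0.0

    def test_single_pair(self):
        cmp = compare_to_experiment({"toluene": (-21.2, -23.1)})
        assert cmp.mae == pytest.approx(1.9)
        assert cmp.max_error == pytest.approx(1.9)

    def test_experimental_pick_convention(self):
        table = {"benzene": (-18.6, (-21.7, -17.7))}
        last = compare_to_experiment(table)
        first = compare_to_experiment(table, experimental_pick="first")
        assert last.errors[0] == pytest.approx(0.9)
        assert first.errors[0] == pytest.approx(3.1)

    def test_empty_comparison_rejected(self):
        with pytest.raises(ValueError):
            compare_to_experiment({"x": (-10.0, None)})
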
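import numpy as np
import pytest

from psqakit import (
    ApertureSequence,
    DeliveryPerturbation,
    FluenceMap,
    SimConfig,
    compute_complexity_vector,
    gen_aperture_sequence,
    generate_dataset,
    render_fluence,
    simulate_delivery,
    validate_sample,
)
from psqakit.data_model import LESION_SITES, METRIC_NAMES
from psqakit.synth import site_allocation


def rect_sequence(gap=20.0, n_cp=5, pairs=8, field=64.0):
    """Constant rectangular aperture centred in the field."""
    left = np.full((n_cp, pairs), (field - gap) / 2)
    right = np.full((n_cp, pairs), (field + gap) / 2)
    return ApertureSequence(left, right, np.full(n_cp, 10.0), field)


class TestApertureSequence:
    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError, match="gap"):
            ApertureSequence(np.full((2, 3), 30.0), np.full((2, 3), 20.0),
                             np.ones(2))

    def test_determinism(self):
        a = gen_aperture_sequence("H&N", seed=5)
        b = gen_aperture_sequence("H&N", seed=5)
        np.testing.assert_array_equal(a.left_edges, b.left_edges)
        np.testing.assert_array_equal(a.right_edges, b.right_edges)
        np.testing.assert_array_equal(a.mu_per_cp, b.mu_per_cp)

    def test_site_gap_ordering(self):
        """H&N apertures are more modulated (smaller gaps) than chest."""
        def mean_open_gap(site, seed):
            ap = gen_aperture_sequence(site, seed)
            g = ap.gaps()
            return g[g > 0].mean()

        hn = np.mean([mean_open_gap("H&N", s) for s in range(100)])
        chest = np.mean([mean_open_gap("C", s) for s in range(100)])
        assert hn < chest

    def test_single_control_point(self):
        ap = gen_aperture_sequence("A", seed=1, n_control_points=1)
        assert ap.n_control_points == 1
        assert ap.total_mu > 0

    def test_unknown_site(self):
        with pytest.raises(ValueError):
            gen_aperture_sequence("brain", seed=0)


class TestRenderFluence:
    def test_full_open_is_all_ones(self):
        ap = ApertureSequence(np.zeros((1, 8)), np.full((1, 8), 64.0),
                              np.array([10.0]), 64.0)
        fm = render_fluence(ap, (64, 64))
        np.testing.assert_array_equal(fm.values, np.ones((64, 64)))

    def test_all_closed_is_all_zeros(self):
        ap = ApertureSequence(np.full((3, 8), 32.0), np.full((3, 8), 32.0),
                              np.ones(3), 64.0)
        fm = render_fluence(ap, (64, 64))
        np.testing.assert_array_equal(fm.values, np.zeros((64, 64)))

    def test_disjoint_strips_footprint(self):
        # two pairs open at disjoint column ranges; no smoothing so support
        # is exactly the geometric footprint
        left = np.full((1, 4), 32.0)
        right = np.full((1, 4), 32.0)
        left[0, 0], right[0, 0] = 0.0, 16.0
        left[0, 2], right[0, 2] = 40.0, 56.0
        ap = ApertureSequence(left, right, np.array([5.0]), 64.0)
        fm = render_fluence(ap, (64, 64), smoothing_sigma_px=0.0)
        expected = np.zeros((64, 64), dtype=bool)
        expected[0:16, 0:16] = True    # pair 0 rows, columns [0, 16)
        expected[32:48, 40:56] = True  # pair 2 rows
        np.testing.assert_array_equal(fm.values > 0, expected)

    def test_mu_scale_invariance(self):
        ap = gen_aperture_sequence("C", seed=3)
        doubled = ApertureSequence(ap.left_edges, ap.right_edges,
                                   2.0 * ap.mu_per_cp, ap.field_width_mm,
                                   ap.leaf_width_mm)
        a = render_fluence(ap, (64, 64))
        b = render_fluence(doubled, (64, 64))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_values_normalized(self):
        fm = render_fluence(gen_aperture_sequence("P", seed=9), (64, 64))
        assert fm.values.min() >= 0.0 and fm.values.max() <= 1.0
        assert fm.values.max() == 1.0

    def test_grid_too_small(self):
        with pytest.raises(ValueError):
            render_fluence(rect_sequence(), (4, 4))


class TestComplexityVector:
    def test_length_and_names(self):
        cv = compute_complexity_vector(gen_aperture_sequence("C", seed=0))
        assert cv.values.shape == (33,)
        assert tuple(cv.names) == METRIC_NAMES
        assert np.all(np.isfinite(cv.values))

    def test_all_closed(self):
        ap = ApertureSequence(np.full((4, 8), 32.0), np.full((4, 8), 32.0),
                              np.ones(4), 64.0)
        cv = compute_complexity_vector(ap)
        d = cv.as_dict()
        assert d["d-CLS"] == 1.0
        assert d["d-BA"] == 0.0
        assert d["d-UAA"] == 0.0

    def test_constant_rectangle_no_variability(self):
        cv = compute_complexity_vector(rect_sequence()).as_dict()
        assert cv["d-AAV"] == 0.0
        assert cv["d-PM"] == 0.0
        assert cv["d-SLG"] == 0.0

    def test_widening_gaps(self):
        ap = gen_aperture_sequence("H&N", seed=2)
        open_mask = ap.gaps() > 0
        left = ap.left_edges - 2.5 * open_mask
        right = ap.right_edges + 2.5 * open_mask
        wide = ApertureSequence(np.clip(left, 0, ap.field_width_mm),
                                np.clip(right, 0, ap.field_width_mm),
                                ap.mu_per_cp, ap.field_width_mm,
                                ap.leaf_width_mm)
        a = compute_complexity_vector(ap).as_dict()
        b = compute_complexity_vector(wide).as_dict()
        assert b["d-UAA"] > a["d-UAA"]
        assert b["d-SAS-2mm"] <= a["d-SAS-2mm"]

    def test_mu_slot(self):
        ap = rect_sequence()
        cv = compute_complexity_vector(ap)
        assert cv.as_dict()["MU"] == pytest.approx(ap.total_mu)

    def test_zero_mu_error(self):
        ap = ApertureSequence(np.zeros((2, 4)), np.full((2, 4), 10.0),
                              np.zeros(2), 64.0)
        with pytest.raises(ValueError, match="MU"):
            compute_complexity_vector(ap)

    def test_distal_proximal_differ_but_deterministic(self):
        ap = gen_aperture_sequence("A", seed=4)
        a = compute_complexity_vector(ap).values
        b = compute_complexity_vector(ap).values
        np.testing.assert_array_equal(a, b)
        d = dict(zip(METRIC_NAMES, a))
        assert d["d-ALG"] != d["p-ALG"]


class TestSimulateDelivery:
    def test_identity(self):
        planned = render_fluence(gen_aperture_sequence("C", seed=1), (64, 64))
        measured, dd = simulate_delivery(planned, DeliveryPerturbation())
        np.testing.assert_array_equal(measured, planned.values)
        np.testing.assert_array_equal(dd, np.zeros_like(dd))

    def test_pure_gain(self):
        planned = render_fluence(gen_aperture_sequence("C", seed=1), (64, 64))
        _, dd = simulate_delivery(planned, DeliveryPerturbation(gain=1.03))
        np.testing.assert_allclose(dd, 0.03 * planned.values, rtol=1e-12,
                                   atol=1e-15)

    def test_noise_determinism(self):
        planned = render_fluence(gen_aperture_sequence("C", seed=1), (64, 64))
        pert = DeliveryPerturbation(noise_sd=0.01, seed=77)
        m1, _ = simulate_delivery(planned, pert)
        m2, _ = simulate_delivery(planned, pert)
        np.testing.assert_array_equal(m1, m2)

    def test_clip_at_zero(self):
        planned = FluenceMap(np.full((8, 8), 0.01))
        m, _ = simulate_delivery(planned, DeliveryPerturbation(noise_sd=0.5,
                                                               seed=1))
        assert m.min() >= 0.0

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            DeliveryPerturbation(blur_sigma_mm=-1)


class TestSimConfig:
    def test_lesion_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimConfig(lesion_mix=(0.5, 0.5, 0.5, 0.5))

    def test_rho_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(rho_tab=1.5)


class TestGenerateDataset:
    def test_reproducible(self):
        cfg = SimConfig(n_samples=6, seed=123)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        for x, y in zip(a, b):
            assert x.sample_id == y.sample_id and x.lesion_site == y.lesion_site
            np.testing.assert_array_equal(x.fluence.values, y.fluence.values)
            np.testing.assert_array_equal(x.targets.gpr_percent,
                                          y.targets.gpr_percent)
            np.testing.assert_array_equal(x.targets.dd_map, y.targets.dd_map)

    def test_site_allocation_cohort(self):
        # largest-remainder allocation of the reference cohort mix
        counts = site_allocation(210, (19 / 210, 138 / 210, 31 / 210, 22 / 210))
        assert counts == [19, 138, 31, 22]

    def test_all_samples_valid(self, small_dataset):
        for s in small_dataset:
            assert validate_sample(s) == []

    def test_gpr_monotone_across_criteria(self, small_dataset):
        for s in small_dataset:
            g = s.targets.gpr_percent
            assert g[0] <= g[1] + 1e-9 <= g[2] + 2e-9

    def test_identity_perturbation_all_pass(self):
        cfg = SimConfig(n_samples=6, seed=2, gain_dev_range=(0, 0),
                        noise_sd_range=(0, 0), blur_base_mm=0.0,
                        blob_amp_range=(0, 0), hot_density_max=0.0)
        for s in generate_dataset(cfg):
            np.testing.assert_array_equal(s.targets.gpr_percent,
                                          [100.0, 100.0, 100.0])
            np.testing.assert_array_equal(s.targets.dd_map,
                                          np.zeros_like(s.targets.dd_map))

    def test_noise_degrades_gpr(self):
        """Mean GPR decreases along an increasing noise grid (3 seeds)."""
        means = []
        for noise in (0.0, 0.01, 0.025):
            vals = []
            for seed in (0, 1, 2):
                cfg = SimConfig(n_samples=12, seed=seed,
                                noise_sd_range=(noise, 0.0),
                                gain_dev_range=(0, 0), blur_base_mm=0.0,
                                blob_amp_range=(0, 0), hot_density_max=0.0)
                vals.extend(
                    s.targets.gpr_percent[1] for s in generate_dataset(cfg)
                )
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_sites_from_configured_mix(self):
        cfg = SimConfig(n_samples=20, seed=0, lesion_mix=(1.0, 0.0, 0.0, 0.0))
        assert all(s.lesion_site == "H&N" for s in generate_dataset(cfg))
        assert set(LESION_SITES) == {"H&N", "C", "A", "P"}

    def test_provenance_recorded(self, small_dataset):
        for s in small_dataset:
            assert {"aperture_seed", "noise_seed", "severity"} <= set(s.provenance)

    def test_rho_tab_zero_decorrelates_complexity_from_gpr(self):
        """With rho_tab = 0 no complexity metric predicts GPR:
        |r| < 0.1 at n = 500 (correlations averaged over 3 seeds)."""
        corrs = []
        for seed in (0, 1, 2):
            samples = generate_dataset(
                SimConfig(n_samples=500, seed=seed, rho_tab=0.0)
            )
            x = np.stack([s.complexity.values for s in samples])
            g = np.stack([s.targets.gpr_percent for s in samples])
            r = np.zeros((33, 3))
            for i in range(33):
                if x[:, i].std() > 0:
                    for j in range(3):
                        r[i, j] = np.corrcoef(x[:, i], g[:, j])[0, 1]
            corrs.append(r)
        assert np.abs(np.mean(corrs, axis=0)).max() < 0.1

    def test_rho_tab_one_couples_complexity_to_gpr(self):
        samples = generate_dataset(SimConfig(n_samples=300, seed=0, rho_tab=1.0))
        x = np.stack([s.complexity.values for s in samples])
        g = np.stack([s.targets.gpr_percent for s in samples])
        i = METRIC_NAMES.index("d-SAS-5mm")
        assert abs(np.corrcoef(x[:, i], g[:, 1])[0, 1]) > 0.5
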
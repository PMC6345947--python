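"""Phantom construction, the forward photoacoustic model, cohort simulation
and synthetic histology."""

import numpy as np
import pytest
from scipy import ndimage

from paox.errors import GeometryError, RangeError, ValidationError
from paox.optics import isosbestic_wavelength
from paox.phantom import (
    LABEL_PLACENTA,
    CohortDesign,
    FluenceModel,
    draw_cohort_truths,
    forward_pa,
    make_ihc_image,
    make_placenta_phantom,
    simulate_cohort,
)

SMALL = dict(shape=(48, 64), center_mm=(6.0, 7.5), axes_mm=(1.8, 3.0))


class TestPlacentaPhantom:
    def test_fully_oxygenated_has_no_deoxy_in_placenta(self):
        truth, mask = make_placenta_phantom(so2=1.0, **SMALL)
        assert np.all(truth.c_hb[mask] == 0)
        assert np.all(truth.c_hbo2[mask] > 0)

    def test_uniform_truth_saturation(self):
        truth, mask = make_placenta_phantom(so2=0.6, total_hb=1.0, **SMALL)
        assert truth.so2[mask] == pytest.approx(0.6, abs=1e-12)
        assert truth.c_hbo2[mask] == pytest.approx(0.6, abs=1e-12)

    def test_background_tissue_has_lower_hemoglobin(self):
        truth, mask = make_placenta_phantom(so2=0.5, total_hb=2.0, **SMALL)
        tissue = (truth.labels == 1)
        total = truth.c_hb + truth.c_hbo2
        assert np.all(total[tissue] == pytest.approx(0.4))
        assert np.all(total[mask] == pytest.approx(2.0))

    def test_mask_is_single_connected_placenta_region(self):
        truth, mask = make_placenta_phantom(**SMALL)
        assert np.array_equal(mask, truth.labels == LABEL_PLACENTA)
        _, n = ndimage.label(mask)
        assert n == 1

    def test_same_seed_is_bit_identical(self):
        a, _ = make_placenta_phantom(texture=True, seed=9, **SMALL)
        b, _ = make_placenta_phantom(texture=True, seed=9, **SMALL)
        assert np.array_equal(a.c_hb, b.c_hb) and np.array_equal(a.c_hbo2, b.c_hbo2)

    def test_texture_preserves_saturation_and_stays_bounded(self):
        plain, mask = make_placenta_phantom(so2=0.35, **SMALL)
        tex, _ = make_placenta_phantom(so2=0.35, texture=True, seed=4, **SMALL)
        assert tex.so2[mask] == pytest.approx(0.35, abs=1e-12)
        ratio = (tex.c_hb + tex.c_hbo2)[mask] / (plain.c_hb + plain.c_hbo2)[mask]
        assert np.all(np.abs(ratio - 1.0) <= 0.1 + 1e-12)

    def test_geometry_outside_image_raises(self):
        with pytest.raises(GeometryError):
            make_placenta_phantom(shape=(48, 64), center_mm=(6.0, 1.0),
                                  axes_mm=(1.8, 3.0))


class TestForwardModel:
    def test_pure_oxy_amplitude_ratio_is_extinction_times_fluence_ratio(self, table):
        truth, mask = make_placenta_phantom(so2=1.0, **SMALL)
        fl = FluenceModel.default((690.0, 950.0))
        scan = forward_pa(truth, table, wavelengths=(690.0, 950.0), fluence=fl,
                          noise_sd=0.0)
        iy, ix = np.argwhere(mask)[0]
        from paox.optics import epsilon_at
        expect = (epsilon_at(table, 690, "hbo2") * fl.surface(690)) / (
            epsilon_at(table, 950, "hbo2") * fl.surface(950))
        assert scan.frames[0, iy, ix] / scan.frames[1, iy, ix] == pytest.approx(
            expect, rel=1e-12)

    def test_linearity_in_concentrations(self, table):
        truth, _ = make_placenta_phantom(so2=0.6, total_hb=1.0, **SMALL)
        doubled, _ = make_placenta_phantom(so2=0.6, total_hb=2.0, **SMALL)
        s1 = forward_pa(truth, table, noise_sd=0.0)
        s2 = forward_pa(doubled, table, noise_sd=0.0)
        # background tissue scales with the placental total, so every frame doubles
        assert np.allclose(s2.frames, 2.0 * s1.frames, rtol=1e-12)

    def test_isosbestic_frame_insensitive_to_saturation(self, table):
        """At the table's own isosbestic wavelength the frame barely depends
        on sO2; at the nominal 808 nm the residual sensitivity is bounded by
        the table's extinction gap there."""
        iso = isosbestic_wavelength(table, 750, 850)
        lo, _ = make_placenta_phantom(so2=0.2, **SMALL)
        hi, _ = make_placenta_phantom(so2=0.9, **SMALL)
        for wl, tol in ((iso, 0.02), (808.0, 0.20)):
            fl = FluenceModel.unit((wl,))
            a = forward_pa(lo, table, wavelengths=(wl,), fluence=fl, noise_sd=0.0)
            b = forward_pa(hi, table, wavelengths=(wl,), fluence=fl, noise_sd=0.0)
            rel = np.abs(a.frames - b.frames) / np.maximum(a.frames, b.frames).max()
            assert rel.max() < tol

    def test_noise_is_seeded_and_reproducible(self, table):
        truth, _ = make_placenta_phantom(**SMALL)
        a = forward_pa(truth, table, noise_sd=None, seed=11)
        b = forward_pa(truth, table, noise_sd=None, seed=11)
        c = forward_pa(truth, table, noise_sd=None, seed=12)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_wavelength_outside_table_raises(self, table):
        truth, _ = make_placenta_phantom(**SMALL)
        with pytest.raises(RangeError):
            forward_pa(truth, table, wavelengths=(500.0, 808.0),
                       fluence=FluenceModel.unit((500.0, 808.0)), noise_sd=0.0)

    def test_structural_image_shares_shape_and_range(self, table, noise_free_scan):
        _, _, scan = noise_free_scan
        assert scan.structural.shape == scan.shape
        assert scan.structural.min() >= 0 and scan.structural.max() <= 1


class TestCohortDesign:
    def test_default_design_has_300_placentas(self):
        truths = draw_cohort_truths(CohortDesign())
        assert len(truths) == 2 * 10 * 3 * 5
        assert truths["true_so2"].between(0.02, 0.98).all()

    def test_zero_variance_design_hits_means_exactly(self):
        d = CohortDesign(between_animal_sd=0.0, within_animal_sd=0.0)
        truths = draw_cohort_truths(d)
        np_rows = truths[truths.group == "NP"]
        assert np.allclose(np_rows.true_so2, d.np_mean_so2)
        gd16 = truths[(truths.group == "RUPP") & (truths.gd == 16)]
        assert np.allclose(gd16.true_so2, d.np_mean_so2 * (1 - 0.12))
        gd14 = truths[(truths.group == "RUPP") & (truths.gd == 14)]
        assert np.allclose(gd14.true_so2, d.np_mean_so2)  # pre-surgery

    def test_truth_means_match_design_within_3se(self):
        d = CohortDesign(seed=0)
        truths = draw_cohort_truths(d)
        for group, gd in [("NP", 14), ("NP", 18), ("RUPP", 16), ("RUPP", 18)]:
            sub = truths[(truths.group == group) & (truths.gd == gd)].true_so2
            se = sub.std(ddof=1) / np.sqrt(len(sub))
            assert abs(sub.mean() - d.group_mean_so2(group, gd)) < 3 * se + 1e-12

    def test_gd16_deficit_in_sample_means(self):
        truths = draw_cohort_truths(CohortDesign(seed=0))
        m = truths.groupby(["group", "gd"]).true_so2.mean()
        rel = 1 - m["RUPP", 16] / m["NP", 16]
        # Monte-Carlo error of the 50-placenta means: ~3 se
        assert rel == pytest.approx(0.12, abs=0.05)

    def test_cohort_simulation_is_byte_identical_under_fixed_seed(self, table):
        d = CohortDesign(n_animals_per_group=1, gestational_days=(16,),
                         n_placentas_per_animal=2, seed=5)
        run1 = list(simulate_cohort(d, table, shape=(48, 64)))
        run2 = list(simulate_cohort(d, table, shape=(48, 64)))
        assert len(run1) == 1 * 2 * 1 * 2
        for a, b in zip(run1, run2):
            assert a.true_so2 == b.true_so2
            assert np.array_equal(a.scan.frames, b.scan.frames)
            assert np.array_equal(a.scan.structural, b.scan.structural)
            assert np.array_equal(a.mask, b.mask)

    def test_design_yaml_round_trip(self, tmp_path):
        d = CohortDesign(seed=42, np_mean_so2=0.55)
        p = tmp_path / "design.yaml"
        d.to_yaml(p)
        assert CohortDesign.from_yaml(p) == d

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValidationError):
            CohortDesign(np_mean_so2=1.5)
        with pytest.raises(ValidationError):
            CohortDesign(rupp_gd16_relative_decrease=-0.1)


class TestSyntheticHistology:
    @pytest.mark.parametrize("frac", [0.0, 25.0, 100.0])
    def test_requested_fraction_achieved_by_construction(self, frac):
        img = make_ihc_image(shape=(128, 128), dab_fraction=frac, seed=1)
        assert img.true_dab_fraction == pytest.approx(frac, abs=0.5)
        achieved = 100.0 * (img.dab_amount > 0)[img.placenta_mask].mean()
        assert achieved == pytest.approx(img.true_dab_fraction, abs=1e-9)

    def test_dab_confined_to_mask(self):
        img = make_ihc_image(shape=(128, 128), dab_fraction=40.0, seed=2)
        assert not np.any(img.dab_amount[~img.placenta_mask] > 0)

    def test_zero_fraction_means_no_dab_anywhere(self):
        img = make_ihc_image(shape=(96, 96), dab_fraction=0.0, seed=3)
        assert np.all(img.dab_amount == 0)

    def test_out_of_range_fraction_and_empty_mask_raise(self):
        with pytest.raises(ValidationError):
            make_ihc_image(dab_fraction=120.0)
        with pytest.raises(GeometryError):
            make_ihc_image(shape=(32, 32), placenta_mask=np.zeros((32, 32), bool),
                           dab_fraction=10.0)
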
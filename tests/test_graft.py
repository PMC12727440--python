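"""Lesion filling: brain extraction, enantiomorphic donor, graft, full fill."""

import numpy as np
import pytest

from lesionbench.graft import (
    SOURCE_FLIP,
    SOURCE_RECIPIENT,
    SOURCE_TPM,
    apply_graft,
    brain_extract,
    build_donor,
    fill,
    flip_lr,
)
from lesionbench.image import Volume, ras_affine
from lesionbench.metrics import dsc
from lesionbench.phantom import LesionSpec, make_lesion_mask, make_subject
from lesionbench.simulate import SimulatedSet, insert_lesion, simulation_qc, smooth_mask


def _ball_mask(template, centre, radius):
    idx = np.indices(template.shape).astype(float)
    r2 = sum((idx[i] - centre[i]) ** 2 for i in range(3))
    return template.with_data(r2 <= radius**2)


def _make_set(template, mask, lesion_level=30.0, fwhm=2.0):
    tbi = template.with_data(template.data.copy())
    tbi.data[mask.data.astype(bool)] = lesion_level
    lesioned, w = insert_lesion(template, tbi, mask, fwhm_mm=fwhm)
    sim = SimulatedSet(
        set_id="s", tbi_id="t", hc_id="h",
        lesion_free=template, lesioned=lesioned,
        repair_mask=mask, smoothed_mask=w,
    )
    simulation_qc(sim)
    return sim


class TestBrainExtract:
    def test_noise_free_phantom_recovers_exact_head(self, clean48):
        _, (template, _, tpms) = clean48
        mask = brain_extract(template)
        assert np.array_equal(mask.data, tpms.head.data)

    def test_constant_volume_fails(self):
        vol = Volume(np.zeros((24, 24, 24)), ras_affine((24, 24, 24)))
        with pytest.raises(ValueError, match="head mask"):
            brain_extract(vol)

    def test_noisy_phantom_head_dice(self, template48):
        template, labels, tpms = template48
        subject, _, _ = make_subject(
            template, labels, max_magnitude_mm=0.0, noise_sd=5.0, seed=6
        )
        mask = brain_extract(subject)
        assert dsc(mask.data, tpms.head.data) >= 0.99


class TestFlipLR:
    def test_involution_bit_exact(self, template48):
        template, _, _ = template48
        noisy = template.with_data(template.data + np.random.default_rng(0).normal(size=template.shape))
        assert np.array_equal(flip_lr(flip_lr(noisy)).data, noisy.data)

    def test_mirror_symmetric_template_is_fixed_point(self, clean48):
        _, (template, _, _) = clean48
        assert np.allclose(flip_lr(template).data, template.data)

    def test_single_voxel_index_arithmetic(self):
        shape = (10, 12, 14)
        data = np.zeros(shape)
        data[2, 5, 7] = 1.0
        flipped = flip_lr(Volume(data, ras_affine(shape)))
        assert flipped.data[shape[0] - 1 - 2, 5, 7] == 1.0
        assert flipped.data.sum() == 1.0

    def test_oblique_affine_rejected(self):
        aff = np.eye(4)
        theta = np.pi / 4
        aff[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        with pytest.raises(ValueError, match="oblique"):
            flip_lr(Volume(np.zeros((8, 8, 8)), aff))


class TestBuildDonor:
    def test_unilateral_lesion_sources_entirely_from_flip(self, clean48):
        _, (template, labels, tpms) = clean48
        mask = _ball_mask(template, (12, 24, 24), 4)  # far left, intact mirror
        sim = _make_set(template, mask)
        donor = build_donor(sim.lesioned, mask, template, tpms)
        in_mask = mask.data.astype(bool)
        assert np.all(donor.source_map[in_mask] == SOURCE_FLIP)
        # symmetric phantom: flipped healthy tissue restores the truth exactly
        assert np.allclose(donor.volume.data[in_mask], template.data[in_mask])

    def test_mirrored_bilateral_lesion_sources_entirely_from_tpm(self, clean48):
        _, (template, labels, tpms) = clean48
        left = _ball_mask(template, (12, 24, 24), 4).data
        mask = template.with_data(left | np.flip(left, axis=0))
        sim = _make_set(template, mask)
        donor = build_donor(sim.lesioned, mask, template, tpms)
        in_mask = mask.data.astype(bool)
        assert np.all(donor.source_map[in_mask] == SOURCE_TPM)

    def test_empty_mask_donor_is_recipient(self, clean48):
        _, (template, _, tpms) = clean48
        empty = template.with_data(np.zeros(template.shape, dtype=bool))
        donor = build_donor(template, empty, template, tpms)
        assert np.array_equal(donor.volume.data, template.data)
        assert np.all(donor.source_map == SOURCE_RECIPIENT)

    def test_whole_head_mask_fails(self, clean48):
        _, (template, _, tpms) = clean48
        mask = template.with_data(tpms.head.data.copy())
        with pytest.raises(ValueError, match="whole head"):
            build_donor(template, mask, template, tpms)

    def test_source_map_recipient_outside_support(self, clean48):
        _, (template, _, tpms) = clean48
        mask = _ball_mask(template, (12, 24, 24), 4)
        donor = build_donor(template, mask, template, tpms)
        w = smooth_mask(mask, 2.0).data
        assert np.all(donor.source_map[w == 0.0] == SOURCE_RECIPIENT)


class TestApplyGraft:
    def test_outside_support_recipient_unchanged_bit_exactly(self, clean48):
        _, (template, labels, tpms) = clean48
        mask = make_lesion_mask(LesionSpec(2, 900.0, seed=17), labels)
        sim = _make_set(template, mask)
        donor = build_donor(sim.lesioned, mask, template, tpms)
        out = apply_graft(sim.lesioned, donor, mask, dilate=False)
        w = smooth_mask(mask, 2.0).data
        assert np.array_equal(out.data[w == 0.0], sim.lesioned.data[w == 0.0])

    def test_zero_fwhm_is_hard_replacement(self, clean48):
        _, (template, _, tpms) = clean48
        mask = _ball_mask(template, (12, 24, 24), 4)
        donor = build_donor(template, mask, template, tpms, fwhm_mm=0.0)
        donor.volume.data[mask.data.astype(bool)] = -1.0
        out = apply_graft(template, donor, mask, fwhm_mm=0.0)
        m = mask.data.astype(bool)
        assert np.all(out.data[m] == -1.0)
        assert np.array_equal(out.data[~m], template.data[~m])

    def test_donor_equal_recipient_is_identity(self, clean48):
        _, (template, _, tpms) = clean48
        mask = _ball_mask(template, (12, 24, 24), 4)
        donor = build_donor(template, mask, template, tpms)
        donor.volume.data[:] = template.data
        out = apply_graft(template, donor, mask)
        assert np.allclose(out.data, template.data, atol=1e-9)


class TestFill:
    def test_empty_mask_fill_is_identity(self, clean48):
        _, (template, _, tpms) = clean48
        empty = template.with_data(np.zeros(template.shape, dtype=bool))
        sim = _make_set(template, empty)
        filled = fill(sim, template, tpms)
        assert np.array_equal(filled.data, sim.lesioned.data)
        assert sim.provenance["fill"]["scale"] == 1.0

    def test_no_dilation_guarantee(self, clean48):
        _, (template, labels, tpms) = clean48
        mask = make_lesion_mask(LesionSpec(3, 2500.0, seed=23), labels)
        sim = _make_set(template, mask)
        filled = fill(sim, template, tpms)
        differs = filled.data != sim.lesioned.data
        support = sim.smoothed_mask.data > 0.0
        assert not (differs & ~support).any()

    def test_fill_reduces_in_mask_error_on_symmetric_phantom(self, clean48):
        _, (template, labels, tpms) = clean48
        mask = make_lesion_mask(
            LesionSpec(2, 3000.0, laterality="unilateral-left", seed=29), labels
        )
        sim = _make_set(template, mask)
        filled = fill(sim, template, tpms)
        m = mask.data.astype(bool)
        mae_lesioned = np.abs(sim.lesioned.data[m] - template.data[m]).mean()
        mae_filled = np.abs(filled.data[m] - template.data[m]).mean()
        assert mae_filled < mae_lesioned

    def test_post_match_rmse_not_worse(self, template48):
        template, labels, tpms = template48
        subject, _, _ = make_subject(template, labels, seed=41)
        mask = make_lesion_mask(LesionSpec(3, 4000.0, seed=43), labels)
        sim = _make_set(subject, mask)
        fill(sim, template, tpms)
        prov = sim.provenance["fill"]
        if prov["hist_rmse_before"] is not None:
            assert prov["hist_rmse_after"] <= prov["hist_rmse_before"]

    def test_determinism(self, clean48):
        _, (template, labels, tpms) = clean48
        mask = make_lesion_mask(LesionSpec(2, 1500.0, seed=31), labels)
        a = fill(_make_set(template, mask), template, tpms)
        b = fill(_make_set(template, mask), template, tpms)
        assert np.array_equal(a.data, b.data)

    def test_failed_qc_set_refused(self, clean48):
        spec, (template, labels, tpms) = clean48
        mask = make_lesion_mask(LesionSpec(1, 900.0, seed=37), labels)
        sim = _make_set(template, mask)
        m = mask.data.astype(bool)
        sim.lesioned.data[m] = sim.lesion_free.data[m]  # zero contrast
        sim.simulation_ok = None
        sim.qc_reasons.clear()
        from lesionbench.simulate import simulation_qc as qc
        qc(sim)
        assert sim.simulation_ok is False
        with pytest.raises(ValueError, match="refusing"):
            fill(sim, template, tpms)
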
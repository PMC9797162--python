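"""Templates, difference-of-Gaussians band-pass, NCC, and tracking."""

import numpy as np
import pytest

import detrack
from detrack.phantom import AcquisitionSpec, Ellipsoid, PhantomSpec, ray_basis
from detrack.subtraction import DEImage
from detrack.tracking import (
    BandPassParams,
    SearchConfig,
    bandpass,
    generate_templates,
    ncc_map,
    track_frame,
    track_sequence,
)


def ncc_bruteforce(image, template):
    """Double-loop zero-normalized cross-correlation oracle."""
    th, tw = template.shape
    out = np.empty((image.shape[0] - th + 1, image.shape[1] - tw + 1))
    t0 = template - template.mean()
    tden = np.sqrt(np.sum(t0 * t0))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            win = image[i : i + th, j : j + tw]
            w0 = win - win.mean()
            den = np.sqrt(np.sum(w0 * w0)) * tden
            out[i, j] = 0.0 if den == 0 else np.sum(w0 * t0) / den
    return out


# ---------------------------------------------------------------------------
# band-pass
# ---------------------------------------------------------------------------


def test_bandpass_removes_dc():
    img = np.full((40, 40), 7.25)
    out = bandpass(img, BandPassParams(0.4, 1.6), pixel_spacing=0.5)
    assert np.allclose(out, 0.0, atol=1e-12)


def test_bandpass_rejects_bad_sigmas():
    with pytest.raises(ValueError):
        BandPassParams(0.8, 0.8)
    with pytest.raises(ValueError):
        BandPassParams(-0.1, 0.4)


@pytest.mark.parametrize("freq", [0.04, 0.08, 0.15])  # cycles / pixel
def test_bandpass_matches_dog_transfer_function(freq):
    """Attenuation of a pure sinusoid matches
    exp(-2 pi^2 f^2 s_lo^2) - exp(-2 pi^2 f^2 s_hi^2) within 2%."""
    n = 256
    x = np.arange(n)
    img = np.tile(np.sin(2 * np.pi * freq * x), (32, 1))
    params = BandPassParams(1.5, 4.5)  # mm, with 1 mm pixels
    out = bandpass(img, params, pixel_spacing=1.0)
    core = out[16, n // 4 : 3 * n // 4]
    ref = img[16, n // 4 : 3 * n // 4]
    gain = np.sqrt(np.sum(core**2) / np.sum(ref**2))
    expected = np.exp(-2 * np.pi**2 * freq**2 * 1.5**2) - np.exp(
        -2 * np.pi**2 * freq**2 * 4.5**2
    )
    assert gain == pytest.approx(abs(expected), rel=0.02)


def test_bandpass_commutes_with_integer_shifts(rng):
    img = rng.normal(size=(96, 96))
    params = BandPassParams(0.6, 2.4)
    a = bandpass(np.roll(img, (3, -5), axis=(0, 1)), params, 0.5)
    b = np.roll(bandpass(img, params, 0.5), (3, -5), axis=(0, 1))
    # compare away from the rolled-over borders and filter support
    assert np.allclose(a[30:-30, 30:-30], b[30:-30, 30:-30], atol=1e-9)


# ---------------------------------------------------------------------------
# NCC
# ---------------------------------------------------------------------------


def test_ncc_peak_is_one_at_excision_point(rng):
    img = rng.normal(size=(40, 40))
    tpl = img[10:22, 5:17].copy()
    surf = ncc_map(img, tpl)
    r, c = np.unravel_index(np.argmax(surf), surf.shape)
    assert (r, c) == (10, 5)
    assert surf[r, c] == pytest.approx(1.0, abs=1e-9)
    assert surf.max() <= 1 + 1e-9


def test_ncc_affine_invariance(rng):
    img = rng.normal(size=(30, 30))
    tpl = rng.normal(size=(8, 8))
    a = ncc_map(img, tpl)
    b = ncc_map(3.7 * img + 11.0, tpl)
    assert np.allclose(a, b, atol=1e-9)


def test_ncc_matches_bruteforce_oracle(rng):
    for _ in range(10):
        img = rng.normal(size=(32, 32))
        tpl = rng.normal(size=(8, 8))
        assert np.allclose(ncc_map(img, tpl), ncc_bruteforce(img, tpl), atol=1e-10)


def test_ncc_agrees_with_skimage(rng):
    skimage_feature = pytest.importorskip("skimage.feature")
    img = rng.normal(size=(50, 60))
    tpl = rng.normal(size=(11, 9))
    ours = ncc_map(img, tpl)
    theirs = skimage_feature.match_template(img, tpl, pad_input=False)
    assert ours.shape == theirs.shape
    assert np.allclose(ours, theirs, atol=1e-7)


def test_ncc_degenerate_inputs(rng):
    img = rng.normal(size=(20, 20))
    img[:10, :10] = 4.2  # constant block larger than the template
    tpl = rng.normal(size=(4, 4))
    surf = ncc_map(img, tpl)
    assert surf[2, 2] == 0.0  # zero-variance window
    with pytest.raises(ValueError):
        ncc_map(img, np.full((4, 4), 1.0))
    with pytest.raises(ValueError):
        ncc_map(np.ones((4, 4)), np.ones((8, 8)) * np.arange(8))


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------


def test_spherical_tumor_template_angle_invariant(tumor_only_phantom):
    acq = AcquisitionSpec(detector_shape=(128, 128), fluence_high=1e4, fluence_low=1e4)
    bank = generate_templates(tumor_only_phantom, [0, 45, 117], acq)
    a = bank.entries[0].pixels
    for angle in (45, 117):
        assert np.allclose(bank.entries[angle].pixels, a, atol=1e-9)


def test_template_offset_bookkeeping(default_phantom, template_bank, small_acq):
    from detrack.phantom import mm_to_px

    tumor = default_phantom.tumor_primitives()[0]
    for angle in (0, 90, 180):
        e = template_bank.entries[angle]
        _, u_hat, v_hat = ray_basis(angle)
        c = np.asarray(tumor.center)
        assert e.ref_u_mm == pytest.approx(float(c @ u_hat), abs=1e-12)
        assert e.ref_v_mm == pytest.approx(float(c @ v_hat), abs=1e-12)
        # the recorded offset points at the projected center inside the crop
        row_in_full = mm_to_px(e.ref_v_mm, 256, e.pixel_spacing)
        col_in_full = mm_to_px(e.ref_u_mm, 256, e.pixel_spacing)
        assert 0 <= e.offset_row < e.pixels.shape[0]
        assert 0 <= e.offset_col < e.pixels.shape[1]
        assert (row_in_full - e.offset_row) == pytest.approx(
            round(row_in_full) - round(e.offset_row), abs=0.51
        )


def test_ellipsoidal_template_widths_follow_projection():
    """At 0 deg the u extent is the y semi-axis, at 90 deg the x semi-axis."""
    spec = PhantomSpec(
        volume_extent=(100, 100, 100),
        primitives=[Ellipsoid((0.0, 0.0, 0.0), (4.0, 8.0, 6.0), "tumor")],
        mu={("tumor", "high"): 0.022, ("tumor", "low"): 0.030},
    )
    acq = AcquisitionSpec(detector_shape=(128, 128), fluence_high=1e4, fluence_low=1e4)
    bank = generate_templates(spec, [0, 90], acq, margin_mm=5.0)
    for angle, semi_u in ((0, 8.0), (90, 4.0)):
        tpl = bank.entries[angle].pixels
        attenuated = tpl < tpl.max() - 1e-9
        cols = np.where(attenuated.any(axis=0))[0]
        width_mm = (cols[-1] - cols[0] + 1) * acq.pixel_spacing
        assert width_mm == pytest.approx(2 * semi_u, abs=2 * acq.pixel_spacing)


def test_tumor_outside_detector_rejected(default_phantom):
    tiny = AcquisitionSpec(detector_shape=(32, 32))
    with pytest.raises(ValueError):
        generate_templates(default_phantom, [0], tiny)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def tracked_noisefree(default_phantom, small_acq):
    motion = detrack.default_motion()
    pairs, gt = detrack.simulate_sequence(default_phantom, motion, small_acq, noise=False)
    bank = detrack.generate_templates(default_phantom, range(0, 181), small_acq)
    frames = [
        detrack.wls_soft_tissue(p.high, p.low, angle_deg=p.angle_deg) for p in pairs
    ]
    return frames, bank, gt


def test_noisefree_tracking_recovers_gt_within_one_pixel(tracked_noisefree, small_acq):
    frames, bank, gt = tracked_noisefree
    cfg = SearchConfig(search_half_width=25.0, ncc_threshold=0.5)
    for bp in (BandPassParams(0.2, 0.4), BandPassParams(0.8, 4.0)):
        tr = track_sequence(frames, bank, cfg, bp)
        assert tr.n_missing == 0
        err = np.hypot(tr.u_mm - gt.u_mm, tr.v_mm - gt.v_mm)
        assert np.all(err <= small_acq.pixel_spacing + 1e-9)


def test_unattainable_threshold_gives_missing(tracked_noisefree):
    frames, bank, _ = tracked_noisefree
    cfg = SearchConfig(search_half_width=25.0, ncc_threshold=1.0)
    tr = track_sequence(frames, bank, cfg, BandPassParams(0.4, 1.6))
    assert tr.n_missing == len(frames)
    assert np.all(np.isnan(tr.u_mm))


def test_missing_fraction_monotone_in_threshold(default_phantom, small_acq):
    import dataclasses

    motion = detrack.default_motion()
    noisy_acq = dataclasses.replace(small_acq, seed=5)
    pairs, _ = detrack.simulate_sequence(default_phantom, motion, noisy_acq, noise=True)
    bank = detrack.generate_templates(default_phantom, range(0, 181), noisy_acq)
    frames = [
        detrack.wls_soft_tissue(p.high, p.low, angle_deg=p.angle_deg) for p in pairs
    ]
    bp = BandPassParams(0.8, 4.0)
    counts = []
    for threshold in (-1.0, 0.2, 0.5, 0.8, 1.0):
        cfg = SearchConfig(search_half_width=25.0, ncc_threshold=threshold)
        counts.append(track_sequence(frames, bank, cfg, bp).n_missing)
    assert counts == sorted(counts)


def test_track_frame_matches_bruteforce_recomputation(tracked_noisefree):
    """The reported peak and position agree with an independent
    brute-force NCC scan over the same filtered window and template."""
    import math

    from detrack.phantom import mm_to_px, px_to_mm

    frames, bank, gt = tracked_noisefree
    cfg = SearchConfig(search_half_width=20.0, ncc_threshold=-1.0)
    bp = BandPassParams(0.4, 1.6)
    frame = frames[1]
    entry = bank.entry_for(frame.angle_deg)
    row = track_frame(frame, bank, (entry.ref_u_mm, entry.ref_v_mm), cfg, bp)
    ps = entry.pixel_spacing
    half = math.ceil(cfg.search_half_width / ps)
    r0 = int(round(mm_to_px(entry.ref_v_mm, 256, ps))) - half
    c0 = int(round(mm_to_px(entry.ref_u_mm, 256, ps))) - half
    pad = math.ceil(4.0 * bp.sigma_high / ps)
    pr0, pc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    big = bandpass(
        frame.pixels[pr0 : r0 + 2 * half + 1 + pad, pc0 : c0 + 2 * half + 1 + pad], bp, ps
    )
    window = big[r0 - pr0 : r0 - pr0 + 2 * half + 1, c0 - pc0 : c0 - pc0 + 2 * half + 1]
    surf = ncc_bruteforce(window, entry.filtered(bp))
    pr, pc = np.unravel_index(np.argmax(surf), surf.shape)
    assert row["ncc_peak"] == pytest.approx(surf[pr, pc], abs=1e-9)
    assert row["u_mm"] == pytest.approx(px_to_mm(c0 + pc + entry.offset_col, 256, ps))
    assert row["v_mm"] == pytest.approx(px_to_mm(r0 + pr + entry.offset_row, 256, ps))


def test_out_of_bounds_window_is_missing(tracked_noisefree):
    frames, bank, _ = tracked_noisefree
    cfg = SearchConfig(search_half_width=10.0, ncc_threshold=0.0)
    row = track_frame(frames[0], bank, (2000.0, 2000.0), cfg, BandPassParams(0.4, 1.6))
    assert row["missing"]


def test_previous_frame_expected_position(default_phantom):
    # dense angular sampling so the previous track stays inside the window
    acq = AcquisitionSpec(n_pairs=8, arc_stop=35.0)
    motion = detrack.default_motion()
    pairs, gt = detrack.simulate_sequence(default_phantom, motion, acq, noise=False)
    bank = detrack.generate_templates(default_phantom, range(0, 36), acq)
    frames = [
        detrack.wls_soft_tissue(p.high, p.low, angle_deg=p.angle_deg) for p in pairs
    ]
    cfg = SearchConfig(
        search_half_width=25.0, ncc_threshold=0.5, expected_position_source="previous_frame"
    )
    tr = track_sequence(frames, bank, cfg, BandPassParams(0.4, 1.6))
    err = np.hypot(tr.u_mm - gt.u_mm, tr.v_mm - gt.v_mm)
    assert tr.n_missing == 0 and np.nanmax(err) < 1.0
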
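"""Band-pass-filtered normalized cross-correlation template tracking.

The tumor is located on each projection by scanning a per-gantry-angle
template (one per degree, generated from the noise-free phantom at the
motion reference state) across a search window centered on the expected
tumor position.  Both window and template are band-pass filtered with a
difference of Gaussians (sigma_low < sigma_high, in mm at the tracking
plane), and the placement maximizing the zero-normalized
cross-correlation (NCC) is the tracked position; a peak below the NCC
threshold declares the frame missing.

Pixel/mm conversions follow the conventions in :mod:`detrack.phantom`:
0-based (row, col) indices, u along columns, v along rows, mm measured
from the detector center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .phantom import (
    AcquisitionSpec,
    Ellipsoid,
    MotionModel,
    PhantomSpec,
    _project_grid,
    detector_grid,
    mm_to_px,
    px_to_mm,
    ray_basis,
)
from .subtraction import DEImage, DESubtractionParams, wls_soft_tissue

__all__ = [
    "BandPassParams",
    "TemplateEntry",
    "TemplateBank",
    "SearchConfig",
    "TrackResult",
    "bandpass",
    "ncc_map",
    "generate_templates",
    "track_frame",
    "track_sequence",
    "default_search_half_width",
]


# ---------------------------------------------------------------------------
# band-pass filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BandPassParams:
    """Difference-of-Gaussians band-pass widths in mm."""

    sigma_low: float
    sigma_high: float

    def __post_init__(self) -> None:
        if not (0 < self.sigma_low < self.sigma_high):
            raise ValueError(
                f"require 0 < sigma_low < sigma_high, got ({self.sigma_low}, {self.sigma_high})"
            )


def bandpass(image: np.ndarray, params: BandPassParams, pixel_spacing: float) -> np.ndarray:
    """``G(sigma_low) * I - G(sigma_high) * I`` with reflect padding.

    Sigmas are mm at the tracking plane and are divided by
    ``pixel_spacing``; the transfer function at spatial frequency f is
    ``exp(-2 pi^2 f^2 s_low^2) - exp(-2 pi^2 f^2 s_high^2)``.
    """
    image = np.asarray(image, dtype=float)
    lo = ndimage.gaussian_filter(image, params.sigma_low / pixel_spacing, mode="reflect")
    hi = ndimage.gaussian_filter(image, params.sigma_high / pixel_spacing, mode="reflect")
    return lo - hi


# ---------------------------------------------------------------------------
# NCC
# ---------------------------------------------------------------------------

def ncc_map(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation surface over valid placements.

    At each placement the template is compared against the image window
    under it with both locally zero-meaned; output values lie in
    [-1, 1].  Windows with (numerically) zero variance get NCC 0; a
    zero-variance template is an error.
    """
    image = np.asarray(image, dtype=float)
    template = np.asarray(template, dtype=float)
    th, tw = template.shape
    ih, iw = image.shape
    if th > ih or tw > iw:
        raise ValueError("template must fit inside the search region")
    n = th * tw
    t0 = template - template.mean()
    t_ss = float(np.sum(t0 * t0))
    if t_ss <= 0:
        raise ValueError("zero-variance template")
    # Subtracting the global image mean improves the conditioning of the
    # windowed-variance computation; NCC itself is invariant to it.
    img0 = image - image.mean()
    cross = signal.fftconvolve(img0, t0[::-1, ::-1], mode="valid")
    ones = np.ones_like(template)
    win_sum = signal.fftconvolve(img0, ones, mode="valid")
    win_sum2 = signal.fftconvolve(img0 * img0, ones, mode="valid")
    win_var = np.maximum(win_sum2 - win_sum * win_sum / n, 0.0)
    denom = np.sqrt(win_var * t_ss)
    tiny = np.finfo(float).tiny
    flat = win_var <= 1e-12 * (win_sum2.max() / n + 1e-300)
    out = np.where(flat, 0.0, cross / np.maximum(denom, tiny))
    return np.clip(out, -1.0, 1.0)


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

@dataclass
class TemplateEntry:
    """One per-degree template with the tumor center recorded twice:
    as a (row, col) offset inside the template and as the reference
    (u, v) position in detector mm.

    ``context`` is the same projection with extra margin around the
    matching footprint; band-pass filtering is applied to the context
    and cropped back, so the filtered template is free of boundary
    artifacts even when the filter support exceeds the template.
    """

    angle_deg: int
    pixels: np.ndarray
    offset_row: float
    offset_col: float
    pixel_spacing: float
    ref_u_mm: float
    ref_v_mm: float
    context: np.ndarray | None = None
    context_origin: tuple[int, int] = (0, 0)  # (row, col) of pixels[0,0] in context

    def filtered(self, bp: BandPassParams) -> np.ndarray:
        """Band-passed template, computed over the padded context."""
        if self.context is None:
            return bandpass(self.pixels, bp, self.pixel_spacing)
        full = bandpass(self.context, bp, self.pixel_spacing)
        r0, c0 = self.context_origin
        th, tw = self.pixels.shape
        return full[r0 : r0 + th, c0 : c0 + tw]


class TemplateBank:
    """Per-degree tumor templates; queries round to the nearest degree."""

    def __init__(self, entries: dict[int, TemplateEntry]):
        if not entries:
            raise ValueError("empty template bank")
        for key, e in entries.items():
            h, w = e.pixels.shape
            if not (0 <= e.offset_row < h and 0 <= e.offset_col < w):
                raise ValueError(f"template offset outside bounds at {key} deg")
        self.entries = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def angles(self) -> list[int]:
        return sorted(self.entries)

    def entry_for(self, angle_deg: float) -> TemplateEntry:
        key = int(round(angle_deg))
        if key not in self.entries:
            raise KeyError(f"no template for angle {angle_deg} (rounded {key})")
        return self.entries[key]


def _projected_tumor_halfwidths(tumor: Ellipsoid, angle_deg: float) -> tuple[float, float]:
    """Support half-widths of the projected tumor ellipse along (u, v)."""
    a = np.asarray(tumor.semi_axes, float)
    _, u_hat, v_hat = ray_basis(angle_deg)
    half_u = float(np.sqrt(np.sum((a * u_hat) ** 2)))
    half_v = float(np.sqrt(np.sum((a * v_hat) ** 2)))
    return half_u, half_v


def generate_templates(
    spec: PhantomSpec,
    angles,
    acq: AcquisitionSpec | None = None,
    de_params: DESubtractionParams | None = None,
    margin_mm: float = 5.0,
    context_pad_mm: float = 16.0,
) -> TemplateBank:
    """Noise-free soft-tissue DE templates of the tumor plus local context.

    For each integer angle, the full phantom (all materials) is
    projected at the motion reference state, log-subtracted with the
    tracking weights, and cropped to the projected tumor bounding box
    plus ``margin_mm``.  An extra ``context_pad_mm`` ring (sized to
    cover the support of the widest band-pass kernel) is projected and
    kept so the template can be filtered without boundary artifacts.
    """
    acq = acq or AcquisitionSpec()
    de_params = de_params or DESubtractionParams()
    tumors = spec.tumor_primitives()
    if not tumors:
        raise ValueError("phantom has no tumor primitive")
    tumor = tumors[0]
    n_rows, n_cols = acq.detector_shape
    pad_px = math.ceil(context_pad_mm / acq.pixel_spacing)
    entries: dict[int, TemplateEntry] = {}
    center = np.asarray(tumor.center, float)
    for angle in angles:
        key = int(round(float(angle)))
        _, u_hat, v_hat = ray_basis(key)
        u0 = float(center @ u_hat)
        v0 = float(center @ v_hat)
        half_u, half_v = _projected_tumor_halfwidths(tumor, key)
        half_u_px = math.ceil((half_u + margin_mm) / acq.pixel_spacing)
        half_v_px = math.ceil((half_v + margin_mm) / acq.pixel_spacing)
        row_c = int(round(mm_to_px(v0, n_rows, acq.pixel_spacing)))
        col_c = int(round(mm_to_px(u0, n_cols, acq.pixel_spacing)))
        r0, r1 = row_c - half_v_px, row_c + half_v_px + 1
        c0, c1 = col_c - half_u_px, col_c + half_u_px + 1
        if r0 < 0 or c0 < 0 or r1 > n_rows or c1 > n_cols:
            raise ValueError(f"tumor projects outside the detector at {key} deg")
        # project the padded context in detector-plane coordinates; the
        # grid may extend past the physical detector, which is harmless
        # for a noise-free analytic projection
        ps = acq.pixel_spacing
        rows = np.arange(r0 - pad_px, r1 + pad_px)
        cols = np.arange(c0 - pad_px, c1 + pad_px)
        u_crop = (cols - (n_cols - 1) / 2.0) * ps
        v_crop = (rows - (n_rows - 1) / 2.0) * ps
        i_h = _project_grid(spec, key, spec.energy_high, acq.fluence_high, u_crop, v_crop)
        i_l = _project_grid(spec, key, spec.energy_low, acq.fluence_low, u_crop, v_crop)
        context = wls_soft_tissue(i_h, i_l, de_params).pixels
        core = context[pad_px : pad_px + (r1 - r0), pad_px : pad_px + (c1 - c0)]
        entries[key] = TemplateEntry(
            angle_deg=key,
            pixels=core,
            offset_row=mm_to_px(v0, n_rows, ps) - r0,
            offset_col=mm_to_px(u0, n_cols, ps) - c0,
            pixel_spacing=ps,
            ref_u_mm=u0,
            ref_v_mm=v0,
            context=context,
            context_origin=(pad_px, pad_px),
        )
    return TemplateBank(entries)


# ---------------------------------------------------------------------------
# tracking
# ---------------------------------------------------------------------------

@dataclass
class SearchConfig:
    search_half_width: float = 25.0          # mm per axis
    ncc_threshold: float = 0.5               # peak below this -> missing frame
    expected_position_source: str = "static_reference"
    subpixel: bool = False                   # 3-point parabolic peak refinement

    def __post_init__(self) -> None:
        if self.search_half_width <= 0:
            raise ValueError("search_half_width must be > 0")
        if not -1.0 <= self.ncc_threshold <= 1.0:
            raise ValueError("ncc_threshold must lie in [-1, 1]")
        if self.expected_position_source not in (
            "static_reference",
            "previous_frame",
            "ground_truth",
        ):
            raise ValueError(
                f"unknown expected_position_source {self.expected_position_source!r}"
            )


def default_search_half_width(spec: PhantomSpec, motion: MotionModel, margin_mm: float = 5.0) -> float:
    """Tumor max radius + motion amplitude + margin, per axis-agnostic mm."""
    tumor = spec.tumor_primitives()[0]
    return float(max(tumor.semi_axes) + max(motion.amplitude) + margin_mm)


@dataclass
class TrackResult:
    """Per-frame tracked positions (NaN where missing) plus peak NCC."""

    frame_index: np.ndarray
    angle_deg: np.ndarray
    u_mm: np.ndarray
    v_mm: np.ndarray
    ncc_peak: np.ndarray
    missing: np.ndarray
    template_angle: np.ndarray

    def __len__(self) -> int:
        return len(self.frame_index)

    def positions(self) -> np.ndarray:
        return np.column_stack([self.u_mm, self.v_mm])

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.missing))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "angle_deg": self.angle_deg,
                "tracked_u_mm": self.u_mm,
                "tracked_v_mm": self.v_mm,
                "ncc_peak": self.ncc_peak,
                "missing": self.missing.astype(int),
                "template_angle": self.template_angle,
            }
        )


def _parabolic_refine(surface: np.ndarray, r: int, c: int) -> tuple[float, float]:
    """3-point parabola through the peak and its axial neighbors."""

    def refine_1d(fm, f0, fp):
        denom = fm - 2 * f0 + fp
        if denom >= 0:  # not a maximum; keep integer location
            return 0.0
        return float(np.clip(0.5 * (fm - fp) / denom, -0.5, 0.5))

    dr = dc = 0.0
    if 0 < r < surface.shape[0] - 1:
        dr = refine_1d(surface[r - 1, c], surface[r, c], surface[r + 1, c])
    if 0 < c < surface.shape[1] - 1:
        dc = refine_1d(surface[r, c - 1], surface[r, c], surface[r, c + 1])
    return dr, dc


def track_frame(
    de_image: DEImage,
    bank: TemplateBank,
    expected_mm: tuple[float, float],
    cfg: SearchConfig,
    bp: BandPassParams,
    frame_index: int = 0,
):
    """Track one frame; returns a dict row for :class:`TrackResult`.

    The search window (expected position +/- search half-width, clipped
    to the image) and the template are band-pass filtered with the same
    parameters before the NCC scan; ties in the NCC peak break to the
    first occurrence in row-major order (:func:`numpy.argmax`).
    """
    entry = bank.entry_for(de_image.angle_deg if de_image.angle_deg is not None else 0.0)
    ps = entry.pixel_spacing
    img = de_image.pixels
    n_rows, n_cols = img.shape
    row_c = mm_to_px(expected_mm[1], n_rows, ps)
    col_c = mm_to_px(expected_mm[0], n_cols, ps)
    half_px = math.ceil(cfg.search_half_width / ps)
    r0 = max(int(round(row_c)) - half_px, 0)
    r1 = min(int(round(row_c)) + half_px + 1, n_rows)
    c0 = max(int(round(col_c)) - half_px, 0)
    c1 = min(int(round(col_c)) + half_px + 1, n_cols)
    th, tw = entry.pixels.shape
    miss = dict(
        frame_index=frame_index,
        angle_deg=de_image.angle_deg,
        u_mm=np.nan,
        v_mm=np.nan,
        ncc_peak=np.nan,
        missing=True,
        template_angle=entry.angle_deg,
    )
    if (r1 - r0) < th or (c1 - c0) < tw:
        return miss  # window fully or mostly out of bounds
    # filter an enlarged window and crop back so the band-pass output is
    # free of window-boundary artifacts (reflect padding only acts at
    # true detector borders)
    pad = math.ceil(4.0 * bp.sigma_high / ps)
    pr0, pr1 = max(r0 - pad, 0), min(r1 + pad, n_rows)
    pc0, pc1 = max(c0 - pad, 0), min(c1 + pad, n_cols)
    window = bandpass(img[pr0:pr1, pc0:pc1], bp, ps)[
        r0 - pr0 : (r0 - pr0) + (r1 - r0), c0 - pc0 : (c0 - pc0) + (c1 - c0)
    ]
    template = entry.filtered(bp)
    if np.ptp(template) == 0:
        return miss
    surface = ncc_map(window, template)
    flat_idx = int(np.argmax(surface))
    pr, pc = np.unravel_index(flat_idx, surface.shape)
    peak = float(surface[pr, pc])
    if peak < cfg.ncc_threshold:
        miss["ncc_peak"] = peak
        return miss
    dr = dc = 0.0
    if cfg.subpixel:
        dr, dc = _parabolic_refine(surface, pr, pc)
    row = r0 + pr + dr + entry.offset_row
    col = c0 + pc + dc + entry.offset_col
    return dict(
        frame_index=frame_index,
        angle_deg=de_image.angle_deg,
        u_mm=px_to_mm(col, n_cols, ps),
        v_mm=px_to_mm(row, n_rows, ps),
        ncc_peak=peak,
        missing=False,
        template_angle=entry.angle_deg,
    )


def track_sequence(
    frames,
    bank: TemplateBank,
    cfg: SearchConfig,
    bp: BandPassParams,
    gt_for_expected=None,
) -> TrackResult:
    """Track every frame; expected position per ``cfg.expected_position_source``.

    ``static_reference`` centers the search on the template's reference
    position (the planning position projected at the frame's angle);
    ``previous_frame`` follows the last successful track;
    ``ground_truth`` uses ``gt_for_expected`` (testing aid).
    """
    rows = []
    last_pos: tuple[float, float] | None = None
    for i, frame in enumerate(frames):
        entry = bank.entry_for(frame.angle_deg if frame.angle_deg is not None else 0.0)
        if cfg.expected_position_source == "ground_truth":
            if gt_for_expected is None:
                raise ValueError("ground_truth expected-position source needs a trajectory")
            expected = (float(gt_for_expected.u_mm[i]), float(gt_for_expected.v_mm[i]))
        elif cfg.expected_position_source == "previous_frame" and last_pos is not None:
            expected = last_pos
        else:
            expected = (entry.ref_u_mm, entry.ref_v_mm)
        row = track_frame(frame, bank, expected, cfg, bp, frame_index=i)
        if not row["missing"]:
            last_pos = (row["u_mm"], row["v_mm"])
        rows.append(row)
    return TrackResult(
        frame_index=np.array([r["frame_index"] for r in rows]),
        angle_deg=np.array([r["angle_deg"] for r in rows], dtype=float),
        u_mm=np.array([r["u_mm"] for r in rows]),
        v_mm=np.array([r["v_mm"] for r in rows]),
        ncc_peak=np.array([r["ncc_peak"] for r in rows]),
        missing=np.array([r["missing"] for r in rows], dtype=bool),
        template_angle=np.array([r["template_angle"] for r in rows]),
    )
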
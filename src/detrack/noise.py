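"""Noise-reduction variants for dual-energy (DE) images.

Four techniques operating on a high/low-energy projection pair or on
the subtracted DE images:

* **SS** (simple smoothing): 3x3 median filter on the high-energy image
  before weighted log subtraction; most DE noise originates in the
  high-energy component while the unfiltered low-energy frame keeps the
  high-frequency detail.
* **ACNR** (anticorrelated noise reduction): the Poisson noise carried
  into the soft-tissue and bone DE images by ``ln I_H`` has opposite
  signs, so adding a weighted high-pass (image minus 20x20 box filter)
  of the complementary bone image cancels part of it:
  ``I_ACNR = I_DEST + w_n * HPF(I_DEB)`` with ``w_n = 0.35``.
* **NC** (noise clipping): with the background estimated by a 17x17
  median filter in both frames, any pixel whose high-energy contrast
  exceeds its low-energy contrast is attributed to noise and clipped to
  the low-energy contrast.  Real structures attenuate more at low
  energy, so genuine contrast always survives.  Signed and one-sided.
* **NC-ACNR**: noise clipping of the high-energy frame, then WLS of the
  clipped pair into soft-tissue and bone images, then ACNR.

All filters use reflect (mirrored-edge) boundary handling so borders
are not darkened, which would bias template matching near image edges.
The 20x20 averaging kernel is even-sized; its origin sits at
``floor(k/2)``, i.e. the window extends one extra pixel toward the
top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .subtraction import DEImage, DESubtractionParams, wls_bone, wls_soft_tissue

__all__ = [
    "NoiseReductionParams",
    "simple_smoothing",
    "acnr",
    "noise_clip",
    "nc_acnr",
    "TECHNIQUES",
    "apply_technique",
]

_BOUNDARY = "reflect"  # scipy.ndimage 'reflect': (c b a | a b c), no edge darkening

TECHNIQUES = ("unprocessed", "SS", "ACNR", "NC", "NC-ACNR")


@dataclass
class NoiseReductionParams:
    ss_kernel: int = 3        # median size for simple smoothing, odd
    acnr_kernel: int = 20     # averaging size for the ACNR high-pass
    w_n: float = 0.35         # ACNR noise-cancellation weight
    nc_kernel: int = 17       # median size for NC background estimation, odd

    def __post_init__(self) -> None:
        for name in ("ss_kernel", "nc_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {k}")
        if self.acnr_kernel < 1:
            raise ValueError("acnr_kernel must be >= 1")
        if self.w_n < 0:
            raise ValueError("w_n must be >= 0")


def _median(image: np.ndarray, size: int) -> np.ndarray:
    return ndimage.median_filter(np.asarray(image, float), size=size, mode=_BOUNDARY)


def _boxfilter(image: np.ndarray, size: int) -> np.ndarray:
    # origin -(size is even) places an even kernel's center at floor(k/2)
    return ndimage.uniform_filter(np.asarray(image, float), size=size, mode=_BOUNDARY)


def simple_smoothing(
    i_h: np.ndarray,
    i_l: np.ndarray,
    de_params: DESubtractionParams | None = None,
    nr_params: NoiseReductionParams | None = None,
    **meta,
) -> DEImage:
    """Median-filter I_H, then weighted log subtraction."""
    nr_params = nr_params or NoiseReductionParams()
    out = wls_soft_tissue(_median(i_h, nr_params.ss_kernel), i_l, de_params, **meta)
    out.technique = "SS"
    return out


def acnr(
    i_dest: DEImage,
    i_deb: DEImage,
    nr_params: NoiseReductionParams | None = None,
    w_n: float | None = None,
) -> DEImage:
    """Add the weighted high-pass of the bone image to the soft-tissue image."""
    nr_params = nr_params or NoiseReductionParams()
    if i_dest.kind != "soft_tissue" or i_deb.kind != "bone":
        raise ValueError("acnr expects (soft_tissue, bone) DE images")
    if i_dest.pixels.shape != i_deb.pixels.shape:
        raise ValueError("shape mismatch between DE images")
    w = nr_params.w_n if w_n is None else w_n
    high_pass = i_deb.pixels - _boxfilter(i_deb.pixels, nr_params.acnr_kernel)
    return DEImage(
        i_dest.pixels + w * high_pass,
        kind="soft_tissue",
        technique="ACNR",
        angle_deg=i_dest.angle_deg,
        time_s=i_dest.time_s,
    )


def noise_clip(
    i_h: np.ndarray,
    i_l: np.ndarray,
    nr_params: NoiseReductionParams | None = None,
    backgrounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Clip high-energy contrast that exceeds the low-energy contrast.

    Per pixel: ``Th = I_L - median(I_L)``; where
    ``I_H - median(I_H) > Th`` the pixel is replaced by
    ``Th + median(I_H)``.  The comparison is signed and one-sided.

    ``backgrounds`` optionally fixes the (high, low) background
    estimates instead of recomputing the median filters; with fixed
    backgrounds the operation is exactly idempotent.
    """
    nr_params = nr_params or NoiseReductionParams()
    i_h = np.asarray(i_h, dtype=float)
    i_l = np.asarray(i_l, dtype=float)
    if i_h.shape != i_l.shape:
        raise ValueError(f"shape mismatch: {i_h.shape} vs {i_l.shape}")
    if backgrounds is None:
        bg_h = _median(i_h, nr_params.nc_kernel)
        bg_l = _median(i_l, nr_params.nc_kernel)
    else:
        bg_h, bg_l = backgrounds
    th = i_l - bg_l
    return np.where(i_h - bg_h > th, th + bg_h, i_h)


def nc_acnr(
    i_h: np.ndarray,
    i_l: np.ndarray,
    de_params: DESubtractionParams | None = None,
    nr_params: NoiseReductionParams | None = None,
    **meta,
) -> DEImage:
    """Noise clipping, then WLS into both DE images, then ACNR."""
    nr_params = nr_params or NoiseReductionParams()
    clipped = noise_clip(i_h, i_l, nr_params)
    i_dest = wls_soft_tissue(clipped, i_l, de_params, **meta)
    i_deb = wls_bone(clipped, i_l, de_params, **meta)
    out = acnr(i_dest, i_deb, nr_params)
    out.technique = "NC-ACNR"
    return out


def apply_technique(
    technique: str,
    i_h: np.ndarray,
    i_l: np.ndarray,
    de_params: DESubtractionParams | None = None,
    nr_params: NoiseReductionParams | None = None,
    **meta,
) -> DEImage:
    """Produce the soft-tissue DE image for one named technique."""
    if technique == "unprocessed":
        return wls_soft_tissue(i_h, i_l, de_params, **meta)
    if technique == "SS":
        return simple_smoothing(i_h, i_l, de_params, nr_params, **meta)
    if technique == "ACNR":
        out = acnr(
            wls_soft_tissue(i_h, i_l, de_params, **meta),
            wls_bone(i_h, i_l, de_params, **meta),
            nr_params,
        )
    elif technique == "NC":
        clipped = noise_clip(i_h, i_l, nr_params)
        out = wls_soft_tissue(clipped, i_l, de_params, **meta)
        out.technique = "NC"
    elif technique == "NC-ACNR":
        out = nc_acnr(i_h, i_l, de_params, nr_params, **meta)
    else:
        raise ValueError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")
    for key, value in meta.items():
        setattr(out, key, value)
    return out
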
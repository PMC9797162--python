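"""Synthetic dual-energy thorax phantom and projection simulator.

Generates paired high/low-kVp projection sequences of a simple
three-material thorax (soft tissue, bone, tumor) with exactly known
tumor motion, standing in for clinical kV projections acquired during a
gantry arc.  The model is deliberately minimal:

* parallel-beam geometry, so mm at the tracking plane are unambiguous;
* monoenergetic attenuation per material and energy label;
* analytic primitives (ellipsoids, finite cylinders) projected with
  closed-form ray-primitive intersections;
* Poisson photon noise only — the minimal noise model that produces the
  anticorrelated noise structure between the dual-energy soft-tissue
  and bone images;
* respiratory motion applied to the tumor only; bones stay static.

Coordinate conventions (used by every module downstream)
--------------------------------------------------------
World axes: x (patient left-right), y (anterior-posterior),
z (superior-inferior).  At gantry angle ``theta`` (degrees) the ray
direction is ``d = (cos t, sin t, 0)`` and the detector axes are
``u_hat = (-sin t, cos t, 0)`` (lateral) and ``v_hat = z_hat``.
Detector pixels are 0-based ``(row, col)`` with
``u = (col - (n_cols - 1)/2) * pixel_spacing`` and
``v = (row - (n_rows - 1)/2) * pixel_spacing`` — mm measured from the
detector center.  Tumor motion is specified in detector coordinates
(u, v) and lifted into 3D along the current frame's ``u_hat`` and
``z_hat``, so the projected motion amplitude equals the specified
amplitude at every gantry angle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "Ellipsoid",
    "Cylinder",
    "PhantomSpec",
    "MotionModel",
    "AcquisitionSpec",
    "ProjectionPair",
    "GroundTruthTrajectory",
    "ray_basis",
    "detector_grid",
    "path_length",
    "project",
    "add_noise",
    "simulate_sequence",
    "true_cancellation_weight",
    "default_phantom",
    "default_motion",
    "default_acquisition",
]

MaterialLabel = Literal["soft_tissue", "bone", "tumor"]

#: material precedence along a ray segment: higher wins where primitives overlap
_PRECEDENCE = {"soft_tissue": 0, "bone": 1, "tumor": 2}


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: ``sum(((p - center)/semi_axes)**2) <= 1``."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    material: MaterialLabel

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError(f"degenerate ellipsoid semi-axes {self.semi_axes}")

    def intervals(self, origins: np.ndarray, direction: np.ndarray):
        """Entry/exit ray parameters; ``t0 == t1`` where the ray misses."""
        a = np.asarray(self.semi_axes, dtype=float)
        q = (origins - np.asarray(self.center, dtype=float)) / a
        dd = np.asarray(direction, dtype=float) / a
        A = float(dd @ dd)
        B = 2.0 * (q @ dd)
        C = np.einsum("...i,...i->...", q, q) - 1.0
        disc = B * B - 4.0 * A * C
        hit = disc > 0
        sq = np.sqrt(np.where(hit, disc, 0.0))
        t0 = np.where(hit, (-B - sq) / (2 * A), 0.0)
        t1 = np.where(hit, (-B + sq) / (2 * A), 0.0)
        return t0, t1

    def bounding_radius(self) -> float:
        return float(max(self.semi_axes))

    def aabb_halfwidths(self) -> np.ndarray:
        return np.asarray(self.semi_axes, dtype=float)


@dataclass(frozen=True)
class Cylinder:
    """Finite circular cylinder around ``axis`` through ``center``."""

    center: tuple[float, float, float]
    radius: float
    length: float
    axis: tuple[float, float, float]
    material: MaterialLabel

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.length <= 0:
            raise ValueError("degenerate cylinder (radius and length must be > 0)")
        n = float(np.linalg.norm(self.axis))
        if n == 0:
            raise ValueError("cylinder axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(np.asarray(self.axis, float) / n))

    def intervals(self, origins: np.ndarray, direction: np.ndarray):
        w = np.asarray(self.axis, dtype=float)
        d = np.asarray(direction, dtype=float)
        o = origins - np.asarray(self.center, dtype=float)
        h = self.length / 2.0

        dw = float(d @ w)
        ow = o @ w
        d_perp = d - dw * w
        o_perp = o - ow[..., None] * w
        A = float(d_perp @ d_perp)
        big = 1e30
        # slab |t*dw + ow| <= h
        if abs(dw) > 1e-12:
            sa = (-h - ow) / dw
            sb = (h - ow) / dw
            s0, s1 = np.minimum(sa, sb), np.maximum(sa, sb)
        else:
            inside = np.abs(ow) <= h
            s0 = np.where(inside, -big, 0.0)
            s1 = np.where(inside, big, 0.0)
        # infinite-cylinder radial constraint
        if A > 1e-16:
            B = 2.0 * np.einsum("...i,i->...", o_perp, d_perp)
            C = np.einsum("...i,...i->...", o_perp, o_perp) - self.radius**2
            disc = B * B - 4.0 * A * C
            hit = disc > 0
            sq = np.sqrt(np.where(hit, disc, 0.0))
            r0 = np.where(hit, (-B - sq) / (2 * A), 0.0)
            r1 = np.where(hit, (-B + sq) / (2 * A), 0.0)
        else:  # ray parallel to the axis
            inside_r = np.einsum("...i,...i->...", o_perp, o_perp) < self.radius**2
            r0 = np.where(inside_r, -big, 0.0)
            r1 = np.where(inside_r, big, 0.0)
        t0 = np.maximum(s0, r0)
        t1 = np.maximum(np.minimum(s1, r1), t0)
        return t0, t1

    def bounding_radius(self) -> float:
        return float(np.hypot(self.radius, self.length / 2.0))

    def aabb_halfwidths(self) -> np.ndarray:
        w = np.asarray(self.axis, dtype=float)
        return (self.length / 2.0) * np.abs(w) + self.radius * np.sqrt(
            np.clip(1.0 - w * w, 0.0, 1.0)
        )


Primitive = Ellipsoid | Cylinder


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Geometry plus linear attenuation coefficients (per mm).

    ``mu`` maps ``(material, energy_label)`` to the linear attenuation
    coefficient in 1/mm; attenuation must be positive and strictly
    larger at the low energy for every material.
    """

    volume_extent: tuple[float, float, float]
    primitives: list[Primitive]
    mu: dict[tuple[str, str], float]
    background_material: MaterialLabel = "soft_tissue"
    energy_high: str = "high"
    energy_low: str = "low"

    def validate(self) -> None:
        half = np.asarray(self.volume_extent, float) / 2.0
        for p in self.primitives:
            c = np.abs(np.asarray(p.center, float))
            if np.any(c + p.aabb_halfwidths() > half + 1e-9):
                raise ValueError(f"primitive {p} lies outside volume_extent")
            if p.material not in _PRECEDENCE:
                raise ValueError(f"unknown material {p.material!r}")
        materials = {p.material for p in self.primitives}
        for m in materials:
            for e in (self.energy_high, self.energy_low):
                if (m, e) not in self.mu:
                    raise ValueError(f"mu missing for ({m}, {e})")
        for (m, e), value in self.mu.items():
            if value <= 0:
                raise ValueError(f"mu({m}, {e}) must be > 0")
        for m in materials:
            if self.mu[(m, self.energy_low)] <= self.mu[(m, self.energy_high)]:
                raise ValueError(
                    f"mu({m}) must be larger at the low energy than at the high energy"
                )

    def tumor_primitives(self) -> list[Primitive]:
        return [p for p in self.primitives if p.material == "tumor"]


@dataclass
class MotionModel:
    """Periodic tumor displacement in detector coordinates (u, v).

    ``cos`` is ``A * cos(2*pi*t/period + phase)``; ``cos4`` is the
    one-sided breathing waveform ``A * cos(pi*t/period + phase)**4``
    (period ``period``, displacement in [0, A]).  ``baseline_drift``
    adds ``drift * t``.  The reference state (used for template
    generation) is zero displacement.
    """

    amplitude: tuple[float, float] = (0.0, 10.0)
    period: float = 4.0
    phase: float = 0.0
    waveform: Literal["cos", "cos4"] = "cos"
    baseline_drift: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if min(self.amplitude) < 0:
            raise ValueError("amplitude must be >= 0")

    def displacement(self, t: float | np.ndarray) -> np.ndarray:
        """Displacement (du, dv) in mm at time(s) ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        amp = np.asarray(self.amplitude, float)
        drift = np.asarray(self.baseline_drift, float)
        if self.waveform == "cos":
            w = np.cos(2.0 * np.pi * t / self.period + self.phase)
        elif self.waveform == "cos4":
            w = np.cos(np.pi * t / self.period + self.phase) ** 4
        else:
            raise ValueError(f"unknown waveform {self.waveform!r}")
        return amp * w[..., None] + drift * t[..., None]


@dataclass
class AcquisitionSpec:
    """Arc acquisition: 15 pair/s, 450 pairs over a 180 degree arc by default."""

    frame_rate: float = 15.0
    arc_start: float = 0.0
    arc_stop: float = 180.0
    n_pairs: int = 450
    fluence_high: float = 1.0e5
    fluence_low: float = 1.0e5
    pixel_spacing: float = 0.5
    detector_shape: tuple[int, int] = (256, 256)
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.fluence_high <= 0 or self.fluence_low <= 0:
            raise ValueError("fluences must be > 0")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.frame_rate

    def angles(self) -> np.ndarray:
        return np.linspace(self.arc_start, self.arc_stop, self.n_pairs)

    def times(self) -> np.ndarray:
        return np.arange(self.n_pairs) * self.dt


@dataclass
class ProjectionPair:
    """One high/low-energy frame pair sharing a gantry angle and motion state."""

    index: int
    time_s: float
    angle_deg: float
    high: np.ndarray
    low: np.ndarray


@dataclass
class GroundTruthTrajectory:
    """Per-frame true (or estimated) 2D tumor center in detector mm."""

    time_s: np.ndarray
    angle_deg: np.ndarray
    u_mm: np.ndarray
    v_mm: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("angle_deg", "u_mm", "v_mm"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory fields must have equal length")

    def __len__(self) -> int:
        return len(self.time_s)

    def positions(self) -> np.ndarray:
        """(n, 2) array of (u, v) positions in mm."""
        return np.column_stack([self.u_mm, self.v_mm])


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def ray_basis(angle_deg: float):
    """Ray direction and detector (u_hat, v_hat) basis at a gantry angle."""
    t = np.deg2rad(angle_deg)
    d = np.array([np.cos(t), np.sin(t), 0.0])
    u_hat = np.array([-np.sin(t), np.cos(t), 0.0])
    v_hat = np.array([0.0, 0.0, 1.0])
    return d, u_hat, v_hat


def detector_grid(acq: AcquisitionSpec):
    """(u, v) coordinate vectors in mm for detector columns and rows."""
    n_rows, n_cols = acq.detector_shape
    u = (np.arange(n_cols) - (n_cols - 1) / 2.0) * acq.pixel_spacing
    v = (np.arange(n_rows) - (n_rows - 1) / 2.0) * acq.pixel_spacing
    return u, v


def mm_to_px(coord_mm: float, n: int, pixel_spacing: float) -> float:
    """Detector mm coordinate to fractional 0-based pixel index."""
    return coord_mm / pixel_spacing + (n - 1) / 2.0


def px_to_mm(index: float, n: int, pixel_spacing: float) -> float:
    return (index - (n - 1) / 2.0) * pixel_spacing


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def path_length(primitive: Primitive, origin, direction) -> float:
    """Chord length of a ray through a primitive (0 if it misses).

    ``direction`` must be a unit vector; closed form for ellipsoids and
    finite cylinders.
    """
    direction = np.asarray(direction, dtype=float)
    n = np.linalg.norm(direction)
    if not np.isclose(n, 1.0, atol=1e-9):
        raise ValueError("ray direction must be a unit vector")
    origin = np.asarray(origin, dtype=float)
    t0, t1 = primitive.intervals(origin[None, :], direction)
    return float(t1[0] - t0[0])


def _shifted(primitive: Primitive, offset: np.ndarray) -> Primitive:
    if not np.any(offset):
        return primitive
    center = tuple(np.asarray(primitive.center, float) + offset)
    return replace(primitive, center=center)


def _line_integrals(
    primitives: Sequence[Primitive],
    mu_by_class: np.ndarray,
    origins: np.ndarray,
    direction: np.ndarray,
) -> np.ndarray:
    """Precedence-resolved attenuation line integral for each ray.

    Every ray is partitioned at all primitive entry/exit events; within
    each segment the attenuating material is the highest-precedence
    primitive covering it (tumor > bone > soft tissue), so overlapping
    primitives never double-attenuate.
    """
    shape = origins.shape[:-1]
    total = np.zeros(shape)
    if not primitives:
        return total
    ts, cls, delta = [], [], []
    for p in primitives:
        t0, t1 = p.intervals(origins, direction)
        c = _PRECEDENCE[p.material]
        ts.extend([t0, t1])
        cls.extend([c, c])
        delta.extend([1, -1])
    ts = np.stack(ts)                       # (2N, ...)
    order = np.argsort(ts, axis=0, kind="stable")
    ts_sorted = np.take_along_axis(ts, order, axis=0)
    cls = np.asarray(cls)[order]            # (2N, ...) per-ray event class
    delta = np.asarray(delta)[order]
    counts = np.zeros((3,) + shape, dtype=np.int32)
    n_events = ts.shape[0]
    for j in range(n_events - 1):
        for k in range(3):
            counts[k] += delta[j] * (cls[j] == k)
        seg = ts_sorted[j + 1] - ts_sorted[j]
        mu_seg = np.where(
            counts[2] > 0,
            mu_by_class[2],
            np.where(counts[1] > 0, mu_by_class[1], np.where(counts[0] > 0, mu_by_class[0], 0.0)),
        )
        total += mu_seg * seg
    return total


def _project_grid(
    spec: PhantomSpec,
    angle_deg: float,
    energy: str,
    fluence: float,
    u: np.ndarray,
    v: np.ndarray,
    tumor_offset_uv: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    d, u_hat, v_hat = ray_basis(angle_deg)
    uu, vv = np.meshgrid(u, v)                      # (rows, cols)
    origins = uu[..., None] * u_hat + vv[..., None] * v_hat
    offset3d = tumor_offset_uv[0] * u_hat + tumor_offset_uv[1] * v_hat
    prims = [
        _shifted(p, offset3d) if p.material == "tumor" else p for p in spec.primitives
    ]
    mu_by_class = np.zeros(3)
    for m, c in _PRECEDENCE.items():
        mu_by_class[c] = spec.mu.get((m, energy), 0.0)
    integral = _line_integrals(prims, mu_by_class, origins, d)
    return fluence * np.exp(-integral)


def project(
    spec: PhantomSpec,
    angle_deg: float,
    energy: str,
    acq: AcquisitionSpec | None = None,
    tumor_offset: tuple[float, float] = (0.0, 0.0),
    fluence: float | None = None,
) -> np.ndarray:
    """Noise-free parallel-beam projection at one gantry angle.

    ``tumor_offset`` is the tumor displacement (du, dv) in detector mm;
    only tumor primitives move.  Returns expected photon counts per
    pixel, ``fluence * exp(-integral mu dl)``.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    acq = acq or AcquisitionSpec()
    if spec.primitives:
        materials = {p.material for p in spec.primitives}
        for m in materials:
            if (m, energy) not in spec.mu:
                raise ValueError(f"energy label {energy!r} missing from spec.mu for {m}")
    if fluence is None:
        fluence = acq.fluence_high if energy == spec.energy_high else acq.fluence_low
    u, v = detector_grid(acq)
    return _project_grid(spec, angle_deg, energy, fluence, u, v, tumor_offset)


def add_noise(image: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Poisson photon noise: each pixel ~ Poisson(noise-free value)."""
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("expected counts must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.poisson(image).astype(float)


def simulate_sequence(
    spec: PhantomSpec,
    motion: MotionModel,
    acq: AcquisitionSpec,
    noise: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[list[ProjectionPair], GroundTruthTrajectory]:
    """Simulate an arc of alternating high/low-energy pairs.

    Both frames of a pair share one gantry angle and one motion state
    (fast kV switching).  The ground truth records the exact projected
    tumor-center position per pair.
    """
    spec.validate()
    acq.validate()
    tumors = spec.tumor_primitives()
    angles = acq.angles()
    times = acq.times()
    disp = motion.displacement(times)               # (n, 2) in (u, v) mm
    if rng is None and noise:
        rng = np.random.default_rng(acq.seed)
    u, v = detector_grid(acq)
    pairs: list[ProjectionPair] = []
    gt_u = np.zeros(acq.n_pairs)
    gt_v = np.zeros(acq.n_pairs)
    for i in range(acq.n_pairs):
        off = (float(disp[i, 0]), float(disp[i, 1]))
        hi = _project_grid(spec, angles[i], spec.energy_high, acq.fluence_high, u, v, off)
        lo = _project_grid(spec, angles[i], spec.energy_low, acq.fluence_low, u, v, off)
        if noise:
            hi = add_noise(hi, rng)
            lo = add_noise(lo, rng)
        pairs.append(ProjectionPair(i, float(times[i]), float(angles[i]), hi, lo))
        if tumors:
            _, u_hat, v_hat = ray_basis(angles[i])
            center = np.asarray(tumors[0].center, float)
            gt_u[i] = center @ u_hat + off[0]
            gt_v[i] = center @ v_hat + off[1]
    gt = GroundTruthTrajectory(times.copy(), angles.copy(), gt_u, gt_v)
    return pairs, gt


def true_cancellation_weight(
    spec: PhantomSpec,
    material: str,
    energy_high: str | None = None,
    energy_low: str | None = None,
    embedded_in: str | None = "auto",
) -> float:
    """Subtraction weight that exactly cancels material ``m``'s contrast
    in the noise-free weighted log subtraction.

    A structure embedded in the background displaces it along the ray,
    so its log-contrast per mm is ``mu_m - mu_bg`` at each energy and
    the exact cancellation weight is the contrast ratio
    ``(mu_m,H - mu_bg,H) / (mu_m,L - mu_bg,L)``.  For the background
    material itself (its "contrast" is against air, e.g. body-outline
    thickness variation) — or with ``embedded_in=None`` — this reduces
    to the plain attenuation ratio ``mu_H / mu_L``.
    """
    eh = energy_high or spec.energy_high
    el = energy_low or spec.energy_low
    if embedded_in == "auto":
        embedded_in = None if material == spec.background_material else spec.background_material
    mh, ml = spec.mu[(material, eh)], spec.mu[(material, el)]
    if embedded_in is None:
        return mh / ml
    return (mh - spec.mu[(embedded_in, eh)]) / (ml - spec.mu[(embedded_in, el)])


# ---------------------------------------------------------------------------
# defaults
# ---------------------------------------------------------------------------

def default_phantom() -> PhantomSpec:
    """Thorax ellipsoid of soft tissue, spine plus five rib cylinders of
    bone crossing the tumor's projected path over part of the arc, and
    one 10 mm-semi-axis tumor ellipsoid in the upper lobe.

    Attenuation coefficients (1/mm) are chosen at kV-effective energies
    so that the canonical empirical subtraction weights are exact in
    this simulator: the bone-embedded-in-tissue contrast ratio is 0.42
    and the soft-tissue attenuation ratio is 0.70.
    """
    prims: list[Primitive] = [
        Ellipsoid(center=(0.0, 0.0, 0.0), semi_axes=(120.0, 90.0, 160.0), material="soft_tissue"),
        Ellipsoid(center=(40.0, 20.0, 30.0), semi_axes=(10.0, 10.0, 10.0), material="tumor"),
        Cylinder(center=(0.0, -60.0, 0.0), radius=10.0, length=180.0, axis=(0, 0, 1), material="bone"),
    ]
    # anterior "ribs" crossing the tumor's projected path for part of the arc;
    # kept short enough to stay fully embedded in the thorax ellipsoid, so
    # bone always displaces soft tissue (never air) along any ray
    for z in (-10.0, 10.0, 30.0, 50.0, 70.0):
        prims.append(
            Cylinder(center=(0.0, 60.0, z), radius=4.0, length=120.0, axis=(1, 0, 0), material="bone")
        )
    mu = {
        ("soft_tissue", "high"): 0.0189,
        ("soft_tissue", "low"): 0.0270,
        ("bone", "high"): 0.03276,
        ("bone", "low"): 0.0600,
        ("tumor", "high"): 0.0220,
        ("tumor", "low"): 0.0300,
    }
    return PhantomSpec(volume_extent=(260.0, 200.0, 340.0), primitives=prims, mu=mu)


def default_motion() -> MotionModel:
    """10 mm superior-inferior cosine breathing with a 4 s period."""
    return MotionModel(amplitude=(0.0, 10.0), period=4.0, phase=0.0, waveform="cos")


def default_acquisition(**overrides) -> AcquisitionSpec:
    return replace(AcquisitionSpec(), **overrides) if overrides else AcquisitionSpec()
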
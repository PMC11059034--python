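"""Fan-beam forward projection and its exact adjoint.

The acquisition model is the linear system g = A f + eps: f is the 2-D
attenuation map (converted from HU to linear attenuation mu in 1/mm), A the
fan-beam line-integral operator and eps additive Gaussian noise on the line
integrals.  A is realized matrix-free by sampled bilinear interpolation
along source->detector rays; the adjoint scatters the same interpolation
weights back, so <A x, y> == <x, A^T y> holds to floating precision — the
property SART relies on.

Geometry convention: angles in degrees, 0 along +x, counterclockwise; the
view angle is the source position on its circle.  Detector is flat,
equispaced, centered on the ray through the isocenter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MU_WATER",
    "FanBeamGeometry",
    "Sinogram",
    "hu_to_mu",
    "mu_to_hu",
    "forward_project",
    "backproject",
    "restrict_angles",
    "nominal_temporal_resolution",
]

MU_WATER = 0.02  # linear attenuation of water, 1/mm


def hu_to_mu(hu: np.ndarray) -> np.ndarray:
    """HU -> linear attenuation: mu = mu_water * (1 + HU/1000); air maps to 0."""
    return MU_WATER * (1.0 + np.asarray(hu, dtype=np.float64) / 1000.0)


def mu_to_hu(mu: np.ndarray) -> np.ndarray:
    return 1000.0 * (np.asarray(mu, dtype=np.float64) / MU_WATER - 1.0)


@dataclass(frozen=True)
class FanBeamGeometry:
    """Fan-beam scan description; P views per 360 deg rotation, D detector cells."""

    n_views: int = 360
    n_detectors: int = 512
    source_to_iso_mm: float = 540.0
    source_to_detector_mm: float = 950.0
    detector_spacing_mm: float = 2.0
    rotation_time_ms: float = 350.0
    fov_mm: float = 220.0
    angles_deg: tuple[float, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.angles_deg is None:
            object.__setattr__(
                self,
                "angles_deg",
                tuple(np.arange(self.n_views) * 360.0 / self.n_views),
            )
        else:
            object.__setattr__(self, "angles_deg", tuple(float(a) for a in self.angles_deg))
            object.__setattr__(self, "n_views", len(self.angles_deg))
        a = np.asarray(self.angles_deg)
        if a.size == 0 or np.any(a < 0) or np.any(a >= 360) or np.any(np.diff(a) <= 0):
            raise ValueError("angles must be strictly increasing within [0, 360)")
        r_fov = self.fov_mm * np.sqrt(2.0) / 2.0
        if not (self.source_to_detector_mm > self.source_to_iso_mm > r_fov):
            raise ValueError("need source_to_detector > source_to_iso > field diagonal / 2")
        # every ray of the fan must clear the FOV circle: the half-fan angle
        # subtended by the detector must exceed the FOV half-angle seen from
        # the source
        half_fan = np.arctan(
            0.5 * self.n_detectors * self.detector_spacing_mm / self.source_to_detector_mm
        )
        needed = np.arcsin(min(1.0, (self.fov_mm / 2.0) / self.source_to_iso_mm))
        if half_fan < needed:
            raise ValueError(
                f"detector fan ({np.rad2deg(half_fan):.2f} deg half-angle) does not "
                f"cover the field of view (needs {np.rad2deg(needed):.2f} deg)"
            )

    @property
    def detector_coords_mm(self) -> np.ndarray:
        """Cell-center offsets along the detector, mm."""
        d = self.n_detectors
        return (np.arange(d) - (d - 1) / 2.0) * self.detector_spacing_mm

    def view_times_ms(self) -> np.ndarray:
        """Acquisition time of each view within the rotation."""
        return np.asarray(self.angles_deg) / 360.0 * self.rotation_time_ms


@dataclass
class Sinogram:
    """P x D line integrals with a per-view validity mask."""

    values: np.ndarray
    geometry: FanBeamGeometry
    angle_mask: np.ndarray = None  # type: ignore[assignment]
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.angle_mask is None:
            self.angle_mask = np.ones(self.values.shape[0], dtype=bool)
        self.angle_mask = np.asarray(self.angle_mask, dtype=bool)
        P, D = self.values.shape
        if P != self.geometry.n_views or D != self.geometry.n_detectors:
            raise ValueError("sinogram shape does not match geometry")
        if not np.all(np.isfinite(self.values[self.angle_mask])):
            raise ValueError("non-finite values in valid views")

    @property
    def is_full_scan(self) -> bool:
        return bool(np.all(self.angle_mask))


def _ray_samples(geom: FanBeamGeometry, angle_deg: float, H: int, W: int, spacing_mm: float):
    """Sample coordinates (row, col) along every ray of one view.

    Returns (coords[2, D, S], step_mm).  Sampling step is half a pixel;
    samples run across the reconstruction circle centered at the isocenter.
    """
    beta = np.deg2rad(angle_deg)
    src = geom.source_to_iso_mm * np.array([np.cos(beta), np.sin(beta)])
    # detector center sits opposite the source; cells spread along the
    # tangential direction
    e_t = np.array([-np.sin(beta), np.cos(beta)])
    det_center = -(geom.source_to_detector_mm - geom.source_to_iso_mm) * np.array(
        [np.cos(beta), np.sin(beta)]
    )
    det = det_center[None, :] + geom.detector_coords_mm[:, None] * e_t[None, :]  # (D, 2)

    dirs = det - src[None, :]
    ray_len = np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs = dirs / ray_len

    step = 0.5 * spacing_mm
    # restrict sampling to the segment of each ray within the FOV circle
    r = geom.fov_mm * np.sqrt(2.0) / 2.0
    t0 = geom.source_to_iso_mm - r
    t1 = geom.source_to_iso_mm + r
    n_s = int(np.ceil((t1 - t0) / step))
    ts = t0 + (np.arange(n_s) + 0.5) * step
    pts = src[None, None, :] + dirs[:, None, :] * ts[None, :, None]  # (D, S, 2)

    # physical xy (mm, y up) -> array (row, col) index coordinates
    cx = (W - 1) / 2.0
    cy = (H - 1) / 2.0
    cols = pts[..., 0] / spacing_mm + cx
    rows = cy - pts[..., 1] / spacing_mm
    return np.stack([rows, cols]), step


def forward_project(
    object_at_time,
    geom: FanBeamGeometry,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Sinogram:
    """Project an object (possibly moving during the scan) into a sinogram.

    ``object_at_time`` is either a single ImageHU / 2-D HU array (static
    object) or a callable ``t_ms -> ImageHU`` evaluated once per view at
    that view's acquisition time (piecewise-constant motion in time).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")

    def at(t_ms: float) -> np.ndarray:
        obj = object_at_time(t_ms) if callable(object_at_time) else object_at_time
        px = obj.pixels if hasattr(obj, "pixels") else np.asarray(obj, dtype=np.float64)
        if not np.all(np.isfinite(px)):
            raise ValueError("object has non-finite pixels")
        return px

    first = at(geom.view_times_ms()[0])
    H, W = first.shape
    spacing = geom.fov_mm / max(H, W)

    static = not callable(object_at_time)
    mu_static = hu_to_mu(first) if static else None

    P = geom.n_views
    sino = np.empty((P, geom.n_detectors))
    times = geom.view_times_ms()
    for p, ang in enumerate(geom.angles_deg):
        mu = mu_static if static else hu_to_mu(at(times[p]))
        coords, step = _ray_samples(geom, ang, H, W, spacing)
        vals = ndimage.map_coordinates(mu, coords.reshape(2, -1), order=1, mode="constant")
        sino[p] = vals.reshape(coords.shape[1:]).sum(axis=1) * step

    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng()
        sino = sino + rng.normal(0.0, noise_sigma, size=sino.shape)
    return Sinogram(values=sino, geometry=geom, noise_sigma=noise_sigma)


def backproject(sino: Sinogram, H: int, W: int) -> np.ndarray:
    """Exact adjoint A^T of ``forward_project``'s sampled line integrals.

    Scatters each ray sample's sinogram value back through the bilinear
    interpolation weights.  Returns a mu-domain image (1/mm); invalid views
    contribute nothing.
    """
    geom = sino.geometry
    spacing = geom.fov_mm / max(H, W)
    out = np.zeros((H, W))
    for p, ang in enumerate(geom.angles_deg):
        if not sino.angle_mask[p]:
            continue
        coords, step = _ray_samples(geom, ang, H, W, spacing)
        rows, cols = coords[0].ravel(), coords[1].ravel()
        vals = np.repeat(sino.values[p] * step, coords.shape[2])
        # the gather side interpolates only inside [0, N-1]; match it exactly
        inside = (rows >= 0) & (rows <= H - 1) & (cols >= 0) & (cols <= W - 1)
        rows, cols, vals = rows[inside], cols[inside], vals[inside]
        r0 = np.floor(rows).astype(int)
        c0 = np.floor(cols).astype(int)
        fr, fc = rows - r0, cols - c0
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr, cc = r0 + dr, c0 + dc
            ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            np.add.at(out, (rr[ok], cc[ok]), vals[ok] * w[ok])
    return out


def restrict_angles(sino: Sinogram, start_deg: float, range_deg: float) -> Sinogram:
    """Mark valid only the views with angle in [start, start+range) mod 360.

    Values are retained; only the mask changes.  range 360 is the identity.
    """
    if not (0 < range_deg <= 360):
        raise ValueError("range_deg must lie in (0, 360]")
    angles = np.asarray(sino.geometry.angles_deg)
    rel = np.mod(angles - start_deg, 360.0)
    new_mask = rel < range_deg if range_deg < 360 else np.ones_like(rel, dtype=bool)
    return Sinogram(
        values=sino.values.copy(),
        geometry=sino.geometry,
        angle_mask=sino.angle_mask & new_mask,
        noise_sigma=sino.noise_sigma,
    )


def nominal_temporal_resolution(range_deg: float, rotation_time_ms: float) -> int:
    """Time window of data in one reconstruction: rotation_time * range/360, ms.

    Rounded half-up to an integer millisecond; a 120 deg window of a 350 ms
    rotation is 117 ms.
    """
    if not (0 < range_deg <= 360):
        raise ValueError("range_deg must lie in (0, 360]")
    if rotation_time_ms <= 0:
        raise ValueError("rotation_time_ms must be positive")
    return int(np.floor(rotation_time_ms * range_deg / 360.0 + 0.5))
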
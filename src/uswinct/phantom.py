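"""Dynamic 2-D cardiac-like attenuation phantoms.

A phantom is a superposition of ellipse primitives on an air background
(-1000 HU).  A "beating" phantom modulates each ellipse's semi-axes
sinusoidally over the cardiac cycle, so rendering the same spec at two
phases yields two snapshots of a moving object.  Several numerical
"patients" with per-patient geometry perturbations, a cardiac-phase
schedule and per-slice jitters together stand in for a 4-D anthropomorphic
phantom at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "ImageHU",
    "sample_phase_schedule",
    "render_phantom",
    "enumerate_dataset",
    "cardiac_spec",
    "make_patients",
    "slice_variant",
]

HU_AIR = -1000.0
HU_MIN, HU_MAX = -1000.0, 3000.0


@dataclass(frozen=True)
class Ellipse:
    """One piecewise-constant component of a phantom.

    Geometry is expressed in fractions of the field of view: ``center``
    in [0, 1]^2 with (0.5, 0.5) the image center, ``semi_axes`` as
    fractions of the FOV.  ``motion_amplitude`` scales the semi-axes by
    ``1 + a * sin(2*pi*(phase + offset))`` so amplitude 0 means static.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0
    attenuation_hu: float = 0.0
    motion_amplitude: float = 0.0
    motion_phase_offset: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    components: tuple[Ellipse, ...]
    heart_period_s: float = 1.0
    field_of_view_mm: float = 220.0
    patient_id: str = "p00"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("phantom needs at least one component")
        for e in self.components:
            if not (HU_MIN <= e.attenuation_hu <= HU_MAX):
                raise ValueError(
                    f"attenuation {e.attenuation_hu} HU outside [{HU_MIN}, {HU_MAX}]"
                )
            if e.motion_amplitude < 0:
                raise ValueError("motion_amplitude must be >= 0")

    @property
    def is_static(self) -> bool:
        return all(e.motion_amplitude == 0 for e in self.components)


@dataclass
class ImageHU:
    """A 2-D attenuation image in Hounsfield units with provenance tags."""

    pixels: np.ndarray
    pixel_spacing_mm: float
    patient_id: str = ""
    phase_pct: float = 0.0
    slice_idx: int = 0
    role: str = "ground_truth"  # ground_truth | limited_angle_input | restored

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 8:
            raise ValueError("image must be 2-D with H, W >= 8")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def sample_phase_schedule(start_pct: float, end_pct: float, step_pct: float) -> list[float]:
    """Inclusive arithmetic sequence of cardiac phases in percent.

    ``(20, 80, 3)`` gives the 21 phases 20, 23, ..., 80.
    """
    if step_pct <= 0:
        raise ValueError("step_pct must be positive")
    if start_pct > end_pct:
        raise ValueError("start_pct must not exceed end_pct")
    n = int(np.floor((end_pct - start_pct) / step_pct + 1e-9)) + 1
    return [start_pct + i * step_pct for i in range(n)]


def render_phantom(spec: PhantomSpec, phase: float, H: int, W: int) -> ImageHU:
    """Rasterize a phantom at a cardiac phase (fraction of cycle, in [0, 1)).

    Components are painted in order over an air background: later ellipses
    overwrite earlier ones, giving a piecewise-constant organ map.  Pure
    function of (spec, phase, H, W).
    """
    if H < 8 or W < 8:
        raise ValueError("H and W must be >= 8")
    if not (0.0 <= phase < 1.0):
        raise ValueError("phase must lie in [0, 1)")

    # pixel centers in FOV fractions: x right, y up, origin at image center
    ys = (np.arange(H)[::-1] + 0.5) / H - 0.5
    xs = (np.arange(W) + 0.5) / W - 0.5
    X, Y = np.meshgrid(xs, ys)

    img = np.full((H, W), HU_AIR)
    for e in spec.components:
        scale = 1.0 + e.motion_amplitude * np.sin(2 * np.pi * (phase + e.motion_phase_offset))
        a = e.semi_axes[0] * scale
        b = e.semi_axes[1] * scale
        if a <= 0 or b <= 0:
            raise ValueError(
                f"component degenerates at phase {phase}: semi-axes ({a:.4g}, {b:.4g})"
            )
        cx, cy = e.center[0] - 0.5, e.center[1] - 0.5
        th = np.deg2rad(e.rotation_deg)
        xr = (X - cx) * np.cos(th) + (Y - cy) * np.sin(th)
        yr = -(X - cx) * np.sin(th) + (Y - cy) * np.cos(th)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        img[inside] = e.attenuation_hu

    return ImageHU(
        pixels=img,
        pixel_spacing_mm=spec.field_of_view_mm / max(H, W),
        patient_id=spec.patient_id,
        phase_pct=100.0 * phase,
    )


def enumerate_dataset(
    specs: list[PhantomSpec], schedule: list[float], slices_per_phase: int
) -> list[tuple[str, float, int]]:
    """All (patient_id, phase_pct, slice_idx) triples, patient-major order."""
    if not specs or not schedule:
        raise ValueError("specs and schedule must be non-empty")
    if slices_per_phase < 1:
        raise ValueError("slices_per_phase must be >= 1")
    return [
        (spec.patient_id, phase, s)
        for spec in specs
        for phase in schedule
        for s in range(slices_per_phase)
    ]


def cardiac_spec(patient_id: str = "p00", rng_seed: int = 0) -> PhantomSpec:
    """A thorax-like default phantom: body, lungs, spine, beating heart and a vessel.

    The heart ellipse and the small high-contrast vessel carry the motion;
    amplitudes (8% and 12% of the semi-axes) are free parameters chosen to
    produce visible motion blur over a 350 ms scan without degenerating.
    """
    rng = np.random.default_rng(rng_seed)
    j = lambda s: float(rng.normal(0.0, s))  # noqa: E731 - per-patient jitter
    comps = (
        Ellipse((0.5, 0.5), (0.42 + j(0.01), 0.33 + j(0.01)), 0.0, 40.0),  # soft tissue body
        Ellipse((0.32 + j(0.01), 0.55), (0.13, 0.18), 10.0, -750.0),  # right lung
        Ellipse((0.68 + j(0.01), 0.55), (0.13, 0.18), -10.0, -750.0),  # left lung
        Ellipse((0.5, 0.22 + j(0.005)), (0.05, 0.045), 0.0, 700.0),  # spine
        Ellipse(
            (0.46 + j(0.01), 0.47 + j(0.01)),
            (0.11, 0.09),
            25.0 + j(3.0),
            60.0,
            motion_amplitude=0.08,
        ),  # heart
        Ellipse(
            (0.55 + j(0.005), 0.40),
            (0.018, 0.018),
            0.0,
            350.0,
            motion_amplitude=0.12,
            motion_phase_offset=0.1,
        ),  # contrast-filled vessel
    )
    return PhantomSpec(components=comps, patient_id=patient_id, rng_seed=rng_seed)


def make_patients(n_patients: int, rng_seed: int = 0) -> list[PhantomSpec]:
    """Independent patients: the same anatomy template with seeded geometry jitter."""
    return [
        cardiac_spec(patient_id=f"p{i:02d}", rng_seed=rng_seed * 1009 + i)
        for i in range(n_patients)
    ]


def slice_variant(spec: PhantomSpec, slice_idx: int) -> PhantomSpec:
    """A per-slice variant of a patient: small deterministic geometry jitter.

    A 2-D pipeline has no z-axis; adjacent "slices" are emulated as seeded
    perturbations of the component centers and axes (about 0.5% of the FOV),
    keeping motion parameters untouched so slices of one phase share a phase.
    """
    if slice_idx == 0:
        return spec
    rng = np.random.default_rng((spec.rng_seed * 10007 + slice_idx) % (2**31))
    comps = []
    for e in spec.components:
        comps.append(
            replace(
                e,
                center=(
                    e.center[0] + float(rng.normal(0, 0.004)),
                    e.center[1] + float(rng.normal(0, 0.004)),
                ),
                semi_axes=(
                    e.semi_axes[0] * float(1 + rng.normal(0, 0.01)),
                    e.semi_axes[1] * float(1 + rng.normal(0, 0.01)),
                ),
            )
        )
    return replace(spec, components=tuple(comps))
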
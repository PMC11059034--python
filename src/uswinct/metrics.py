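"""Image-quality evaluation: RMSE, SSIM, noise power spectrum, line profiles.

All scalar metrics operate on [0, 1]-normalized intensities.  Two SSIM modes
are provided: ``standard`` is the conventional sliding-Gaussian-window SSIM
(delegated to scikit-image, C1=(0.01 L)^2, C2=(0.03 L)^2, L=1) and
``paper_global`` evaluates the global-moment similarity
(2 mu_x mu_y + C1)(2 sigma_xy + C2) /
((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2)) once over the whole
image — kept because some reports compute SSIM globally rather than with a
sliding window; both modes return 1 for identical images.

The noise power spectrum of a reconstruction against its reference is
NPS = log(|FFT2(img - ref)|^2), zero-frequency centered, with a small floor
inside the log; radial averaging over concentric annuli turns the 2-D map
into a frequency profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.metrics import structural_similarity

__all__ = [
    "MetricsReport",
    "rmse",
    "ssim",
    "nps_map",
    "radial_nps",
    "line_profile",
]

NPS_EPS_FLOOR = 1e-12


def _check_pair(y: np.ndarray, y_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    return y, y_hat


def rmse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Root of the mean squared elementwise difference."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def ssim(x: np.ndarray, y: np.ndarray, mode: str = "standard") -> float:
    """Structural similarity in [-1, 1]; 1 for identical images."""
    x, y = _check_pair(x, y)
    if mode == "standard":
        return float(
            structural_similarity(
                x,
                y,
                data_range=1.0,
                gaussian_weights=True,
                sigma=1.5,
                use_sample_covariance=False,
            )
        )
    if mode == "paper_global":
        # global-moment SSIM: one evaluation over the whole image using the
        # sample means, standard deviations and cross-covariance
        c1, c2 = 0.01**2, 0.03**2
        mx, my = x.mean(), y.mean()
        vx = x.var(ddof=1)
        vy = y.var(ddof=1)
        sxy = np.mean((x - mx) * (y - my)) * x.size / (x.size - 1)
        num = (2 * mx * my + c1) * (2 * sxy + c2)
        den = (mx**2 + my**2 + c1) * (vx + vy + c2)
        if den == 0:
            raise ZeroDivisionError("degenerate images with stabilizing constants disabled")
        return float(num / den)
    raise ValueError("mode must be 'standard' or 'paper_global'")


def nps_map(img: np.ndarray, ref: np.ndarray, eps_floor: float = NPS_EPS_FLOOR) -> np.ndarray:
    """log power spectrum of the difference image, zero frequency centered."""
    img, ref = _check_pair(img, ref)
    spec = np.abs(np.fft.fft2(img - ref)) ** 2
    return np.fft.fftshift(np.log(spec + eps_floor))


def radial_nps(nps: np.ndarray, n_bins: int) -> pd.DataFrame:
    """Mean NPS over concentric annuli covering [0, Nyquist].

    Returns a frame with columns ``frequency`` (annulus center, cycles per
    pixel) and ``power`` (mean map value; NaN where an annulus is empty).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    h, w = nps.shape
    yy = np.arange(h) - h // 2
    xx = np.arange(w) - w // 2
    r = np.hypot(yy[:, None], xx[None, :])
    r_nyq = min(h, w) / 2.0
    edges = np.linspace(0.0, r_nyq, n_bins + 1)
    which = np.digitize(r, edges) - 1
    inside = (which >= 0) & (which < n_bins)
    counts = np.bincount(which[inside], minlength=n_bins)
    sums = np.bincount(which[inside], weights=nps[inside], minlength=n_bins)
    power = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    centers = 0.5 * (edges[:-1] + edges[1:]) / (2.0 * r_nyq)  # cycles/pixel
    return pd.DataFrame({"frequency": centers, "power": power, "n_pixels": counts})


def line_profile(img: np.ndarray, start: tuple[float, float], end: tuple[float, float], n_samples: int = 100) -> np.ndarray:
    """Bilinear samples along a segment, endpoints inclusive; (row, col) coords."""
    img = np.asarray(img, dtype=np.float64)
    h, w = img.shape
    for r, c in (start, end):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError(f"endpoint ({r}, {c}) outside image {h}x{w}")
    ts = np.linspace(0.0, 1.0, n_samples)
    rows = start[0] + ts * (end[0] - start[0])
    cols = start[1] + ts * (end[1] - start[1])
    return ndimage.map_coordinates(img, np.stack([rows, cols]), order=1, mode="nearest")


@dataclass
class MetricsReport:
    """Per-image metric rows plus per-method aggregates and optional NPS data."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["patient_id", "phase_pct", "slice_idx", "method", "rmse", "ssim"]
        )
    )
    nps_maps: dict = field(default_factory=dict)
    nps_profiles: dict = field(default_factory=dict)

    def add_row(self, patient_id, phase_pct, slice_idx, method, rmse_val, ssim_val) -> None:
        if rmse_val < 0 or not (-1.0 - 1e-12 <= ssim_val <= 1.0 + 1e-12):
            raise ValueError("metric out of range")
        self.rows.loc[len(self.rows)] = [
            patient_id,
            phase_pct,
            slice_idx,
            method,
            float(rmse_val),
            float(ssim_val),
        ]

    def aggregates(self) -> pd.DataFrame:
        """Arithmetic mean of rmse/ssim per method."""
        return self.rows.groupby("method")[["rmse", "ssim"]].mean()

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def aggregates_json(self) -> dict:
        agg = self.aggregates()
        return {m: {"rmse": float(r.rmse), "ssim": float(r.ssim)} for m, r in agg.iterrows()}
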
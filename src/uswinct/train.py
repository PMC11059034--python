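"""Dataset assembly, network training and evaluation.

A training example pairs the artifact-ridden input — FBP of an
angle-restricted sinogram of the *moving* phantom — with its label, FBP of
the full-view sinogram of the *frozen* phantom at the same cardiac phase.
Both are intensity-normalized to [0, 1].  Training minimizes the mean
square loss (1/N) ||I_out - I_FV||_F^2 with Adam, batch size 1, shuffling
each epoch under the run seed; cross-validation splits are patient-wise so
no numerical patient leaks between train and test.

The trainable model is exposed both as a scikit-learn style estimator
(:class:`USwinRestorer`, fit/predict) and as the thin functional wrappers
:func:`train_model` / :func:`evaluate` around it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .autodiff import Adam
from .metrics import MetricsReport, rmse, ssim
from .model import ModelConfig, PRESETS, USwin, normalize_hu
from .phantom import PhantomSpec, render_phantom, slice_variant
from .projection import FanBeamGeometry, forward_project, restrict_angles
from .recon import fbp

__all__ = [
    "TrainConfig",
    "Pair",
    "simulate_pair",
    "build_pairs",
    "mse_loss",
    "patient_kfold_split",
    "train_model",
    "evaluate",
    "USwinRestorer",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 1
    epochs: int = 100
    learning_rate: float = 1e-5
    optimizer: str = "adam"
    rng_seed: int = 0
    k_folds: int = 10
    angular_range_deg: float = 120.0
    start_angle_deg: float = 120.0
    checkpoint_every: int = 0  # epochs; 0 disables
    max_steps: int = 0  # 0 = unlimited; caps total optimizer steps

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")


@dataclass
class Pair:
    """One training example, [0, 1] normalized, with provenance tags."""

    input: np.ndarray
    label: np.ndarray
    patient_id: str
    phase_pct: float
    slice_idx: int


def simulate_pair(
    spec: PhantomSpec,
    phase_pct: float,
    slice_idx: int,
    geom: FanBeamGeometry,
    angular_range_deg: float = 120.0,
    start_angle_deg: float = 120.0,
    H: int = 64,
    W: int = 64,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """One (input, label) pair plus its sinograms.

    The phantom beats during the scan: at view time t the rendered phase is
    ``phase + t / heart_period``.  The label freezes the phantom at the
    nominal phase and uses every view.  Returns (Pair, dynamic limited-angle
    Sinogram, static full-view Sinogram).
    """
    sspec = slice_variant(spec, slice_idx)
    phase0 = (phase_pct / 100.0) % 1.0

    def moving(t_ms: float):
        ph = (phase0 + t_ms / 1000.0 / sspec.heart_period_s) % 1.0
        return render_phantom(sspec, ph, H, W)

    dyn_sino = forward_project(moving, geom, noise_sigma=noise_sigma, rng=rng)
    la_sino = restrict_angles(dyn_sino, start_angle_deg, angular_range_deg)
    inp = fbp(la_sino, H, W)

    static = render_phantom(sspec, phase0, H, W)
    static_sino = forward_project(static, geom)
    label = fbp(static_sino, H, W)

    pair = Pair(
        input=normalize_hu(inp.pixels),
        label=normalize_hu(label.pixels),
        patient_id=spec.patient_id,
        phase_pct=phase_pct,
        slice_idx=slice_idx,
    )
    return pair, la_sino, static_sino


def build_pairs(
    specs: list[PhantomSpec],
    schedule: list[float],
    slices_per_phase: int,
    geom: FanBeamGeometry,
    angular_range_deg: float = 120.0,
    start_angle_deg: float = 120.0,
    H: int = 64,
    W: int = 64,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[Pair]:
    """Simulate (limited-angle dynamic input, full-view static label) pairs
    for every (patient, phase, slice) triple, patient-major order."""
    return [
        simulate_pair(
            spec, phase_pct, s, geom, angular_range_deg, start_angle_deg, H, W,
            noise_sigma=noise_sigma, rng=rng,
        )[0]
        for spec in specs
        for phase_pct in schedule
        for s in range(slices_per_phase)
    ]


def mse_loss(i_out: np.ndarray, i_fv: np.ndarray) -> float:
    """(1/N) ||I_out - I_FV||_F^2 over the N pixels."""
    i_out = np.asarray(i_out, dtype=np.float64)
    i_fv = np.asarray(i_fv, dtype=np.float64)
    if i_out.shape != i_fv.shape:
        raise ValueError("shape mismatch")
    return float(np.mean((i_out - i_fv) ** 2))


def patient_kfold_split(
    patient_ids: list[str], k: int, rng_seed: int = 0
) -> list[tuple[list[str], list[str]]]:
    """k folds of (train_ids, test_ids): a seeded partition of the patients.

    Test sets are pairwise disjoint and together exhaust the patient list.
    """
    unique = list(dict.fromkeys(patient_ids))
    if k > len(unique):
        raise ValueError(f"k={k} exceeds the {len(unique)} distinct patients")
    order = list(np.random.default_rng(rng_seed).permutation(unique))
    folds = [list(order[i::k]) for i in range(k)]
    return [
        (sorted(set(unique) - set(test)), sorted(test))
        for test in (sorted(f) for f in folds)
    ]


class USwinRestorer(BaseEstimator, RegressorMixin):
    """Scikit-learn style wrapper around U-Swin training.

    Parameters
    ----------
    config : ModelConfig | str
        Full configuration or a preset name ("uswin1", "light", "small",
        "large").
    epochs, learning_rate, batch_size, max_steps, rng_seed
        Optimization settings; ``max_steps`` (if > 0) caps the total number
        of per-image Adam steps, which is how desk-scale runs stay small.

    Fitted attributes: ``model_`` (the trained network), ``loss_history_``
    (per-epoch mean training loss) and ``n_parameters_``.
    """

    def __init__(
        self,
        config: ModelConfig | str = "uswin1",
        epochs: int = 100,
        learning_rate: float = 1e-5,
        batch_size: int = 1,
        max_steps: int = 0,
        rng_seed: int = 0,
        checkpoint_every: int = 0,
        checkpoint_dir=None,
    ):
        self.config = config
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_steps = max_steps
        self.rng_seed = rng_seed
        self.checkpoint_every = checkpoint_every
        self.checkpoint_dir = checkpoint_dir

    def _resolve_config(self) -> ModelConfig:
        return PRESETS[self.config] if isinstance(self.config, str) else self.config

    def fit(self, X: np.ndarray, y: np.ndarray) -> "USwinRestorer":
        """Train on stacks of [0, 1] images, X and y of shape (n, H, W)."""
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 3 or X.shape != y.shape or len(X) == 0:
            raise ValueError("X and y must be non-empty (n, H, W) stacks of equal shape")

        cfg = self._resolve_config()
        model = USwin(cfg)
        opt = Adam(model.parameters(), lr=self.learning_rate)
        rng = np.random.default_rng(self.rng_seed)

        history: list[float] = []
        steps = 0
        for epoch in range(self.epochs):
            order = rng.permutation(len(X))
            losses = []
            for start in range(0, len(order), self.batch_size):
                idx = order[start : start + self.batch_size]
                out = model.forward(X[idx])
                diff = out - y[idx]
                loss = (diff * diff).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
                steps += 1
                if self.max_steps and steps >= self.max_steps:
                    break
            history.append(float(np.mean(losses)))
            if (
                self.checkpoint_every
                and self.checkpoint_dir is not None
                and (epoch + 1) % self.checkpoint_every == 0
            ):
                from .model import save_checkpoint

                save_checkpoint(
                    f"{self.checkpoint_dir}/checkpoint_epoch{epoch + 1:04d}.npz", model
                )
            if self.max_steps and steps >= self.max_steps:
                break

        self.model_ = model
        self.loss_history_ = history
        self.n_parameters_ = model.n_parameters()
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        X = np.asarray(X, dtype=np.float64)
        squeeze = X.ndim == 2
        out = self.model_.predict(X[None] if squeeze else X)
        return out[0] if squeeze else out


def train_model(
    pairs: list[Pair], model_config: ModelConfig | str, train_config: TrainConfig,
    checkpoint_dir=None,
) -> tuple[USwin, list[float]]:
    """Functional wrapper: train on a pair list, return (model, loss history)."""
    if not pairs:
        raise ValueError("no training pairs")
    est = USwinRestorer(
        config=model_config,
        epochs=train_config.epochs,
        learning_rate=train_config.learning_rate,
        batch_size=train_config.batch_size,
        max_steps=train_config.max_steps,
        rng_seed=train_config.rng_seed,
        checkpoint_every=train_config.checkpoint_every,
        checkpoint_dir=checkpoint_dir,
    )
    X = np.stack([p.input for p in pairs])
    y = np.stack([p.label for p in pairs])
    est.fit(X, y)
    return est.model_, est.loss_history_


def evaluate(model: USwin | None, pairs: list[Pair]) -> MetricsReport:
    """Per-pair RMSE/SSIM of the restored image and of the raw input baseline.

    Methods reported: ``limited_angle_fbp`` (input vs label) and, when a
    model is given, ``uswin`` (restored vs label).
    """
    report = MetricsReport()
    for p in pairs:
        report.add_row(
            p.patient_id, p.phase_pct, p.slice_idx, "limited_angle_fbp",
            rmse(p.label, p.input), ssim(p.input, p.label),
        )
        if model is not None:
            restored = model.predict(p.input)
            report.add_row(
                p.patient_id, p.phase_pct, p.slice_idx, "uswin",
                rmse(p.label, restored), ssim(np.clip(restored, 0, 1), p.label),
            )
    return report
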
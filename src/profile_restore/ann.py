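"""Sliding-window shallow network for penumbra restoration.

A three-layer network maps a fixed-length window of the Makima-upsampled
measurement to the volume-averaging-free dose at the window center:

    O = w_out . tanh(W_hidden^T s + b_hidden) + b_out

(tangent-sigmoid hidden layer, linear output).  Sliding the window one grid
point at a time across the profile yields the reconstructed continuous
profile.  Training is batch Levenberg-Marquardt backpropagation: each epoch
solves the damped normal equations (J^T J + mu I) delta = J^T r with the
analytic Jacobian, lowering the damping on accepted steps and raising it on
rejected ones.  Because the loss surface has local minima, training restarts
from several random initializations and keeps the restart with the lowest
validation MSE.

The module follows the Model/Results convention: :class:`SlidingWindowANN`
holds the data and architecture, ``fit()`` returns an :class:`ANNFitResults`
with the trained weights, per-restart histories and a ``summary()`` table;
``fit_sweep()`` scans the hidden-node count.  The functional surface
(:func:`forward`, :func:`extract_pairs`, :func:`train_lm`,
:func:`sweep_hidden_nodes`, :func:`reconstruct`) wraps the same machinery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.linalg import cho_factor, cho_solve

from .simulate import Profile

__all__ = [
    "ANNModel",
    "DataPairSet",
    "TrainingConfig",
    "SlidingWindowANN",
    "ANNFitResults",
    "SweepResults",
    "forward",
    "extract_pairs",
    "train_lm",
    "sweep_hidden_nodes",
    "reconstruct",
    "load_model",
]


@dataclass(frozen=True)
class ANNModel:
    """Weights of the three-layer window-to-center network."""

    w_hidden: np.ndarray  # (L_sw, N_hn)
    b_hidden: np.ndarray  # (N_hn,)
    w_out: np.ndarray  # (N_hn,)
    b_out: float
    grid_step_mm: float = 0.5

    def __post_init__(self):
        w = np.asarray(self.w_hidden, dtype=float)
        object.__setattr__(self, "w_hidden", w)
        object.__setattr__(self, "b_hidden", np.asarray(self.b_hidden, dtype=float))
        object.__setattr__(self, "w_out", np.asarray(self.w_out, dtype=float))
        if w.ndim != 2:
            raise ValueError("w_hidden must be (L_sw, N_hn)")
        if self.window_taps % 2 != 1:
            raise ValueError("window length must be odd (the window has a center tap)")
        for arr in (self.w_hidden, self.b_hidden, self.w_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")

    @property
    def window_taps(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def n_params(self) -> int:
        return self.w_hidden.size + self.b_hidden.size + self.w_out.size + 1

    def predict(self, windows: np.ndarray) -> np.ndarray:
        """Vectorized forward pass over rows of windows (M, L_sw)."""
        s = np.atleast_2d(np.asarray(windows, dtype=float))
        if s.shape[1] != self.window_taps:
            raise ValueError(f"window length {s.shape[1]} != model L_sw {self.window_taps}")
        a = np.tanh(s @ self.w_hidden + self.b_hidden)
        return a @ self.w_out + self.b_out

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "architecture": {
                "window_taps": self.window_taps,
                "n_hidden": self.n_hidden,
                "activation_hidden": "tanh",
                "activation_out": "identity",
            },
            "grid_step_mm": self.grid_step_mm,
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": float(self.b_out),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ANNModel":
        return cls(
            np.asarray(d["w_hidden"], dtype=float),
            np.asarray(d["b_hidden"], dtype=float),
            np.asarray(d["w_out"], dtype=float),
            float(d["b_out"]),
            float(d.get("grid_step_mm", 0.5)),
        )


def forward(model: ANNModel, window: np.ndarray) -> float:
    """Scalar network output for one window of L_sw samples."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 1 or window.size != model.window_taps:
        raise ValueError(f"expected a window of length {model.window_taps}")
    return float(model.predict(window[None, :])[0])


_PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class DataPairSet:
    """Window/target training pairs with an optional train/val/test split."""

    inputs: np.ndarray  # (N, L_sw)
    targets: np.ndarray  # (N,)
    labels: np.ndarray | None = None  # int codes into _PARTITIONS

    def __post_init__(self):
        x = np.asarray(self.inputs, dtype=float)
        t = np.asarray(self.targets, dtype=float)
        if x.ndim != 2 or t.ndim != 1 or x.shape[0] != t.shape[0]:
            raise ValueError("inputs must be (N, L_sw) and targets (N,)")
        object.__setattr__(self, "inputs", x)
        object.__setattr__(self, "targets", t)
        if self.labels is not None:
            lab = np.asarray(self.labels, dtype=int)
            if lab.shape != t.shape:
                raise ValueError("labels must align with targets")
            object.__setattr__(self, "labels", lab)

    def __len__(self) -> int:
        return self.targets.size

    @property
    def window_taps(self) -> int:
        return self.inputs.shape[1]

    def split(self, fractions: tuple[float, float, float], seed: int) -> "DataPairSet":
        """Random train/validation/test partition of the pairs (seeded)."""
        if abs(sum(fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        n = len(self)
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        lab = np.empty(n, dtype=int)
        lab[order[:n_train]] = 0
        lab[order[n_train : n_train + n_val]] = 1
        lab[order[n_train + n_val :]] = 2
        return replace(self, labels=lab)

    def partition(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        if self.labels is None:
            raise ValueError("pair set has not been split")
        code = _PARTITIONS.index(name)
        sel = self.labels == code
        return self.inputs[sel], self.targets[sel]

    @classmethod
    def concat(cls, sets: list["DataPairSet"]) -> "DataPairSet":
        return cls(
            np.vstack([s.inputs for s in sets]),
            np.concatenate([s.targets for s in sets]),
        )


def extract_pairs(
    input_profile: Profile, reference_profile: Profile, window_mm: float = 15.0
) -> DataPairSet:
    """Slide a window over the upsampled measurement; pair each window with
    the reference dose at its center.  One pair per grid index where the
    full window fits: N_grid - L_sw + 1 pairs."""
    if input_profile.positions_mm.shape != reference_profile.positions_mm.shape or not np.allclose(
        input_profile.positions_mm, reference_profile.positions_mm, atol=1e-9
    ):
        raise ValueError("input and reference profiles must share an identical grid")
    step = input_profile.grid_step_mm
    taps = int(round(window_mm / step)) + 1
    if taps % 2 != 1:
        raise ValueError(f"window of {window_mm} mm at {step} mm step gives even tap count {taps}")
    windows = sliding_window_view(input_profile.values, taps)
    half = (taps - 1) // 2
    targets = reference_profile.values[half : reference_profile.values.size - half]
    return DataPairSet(windows.copy(), targets.copy())


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the LM training protocol."""

    epochs: int = 400
    restarts: int = 10
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    sweep_range: tuple[int, ...] = tuple(range(2, 21, 2))
    window_mm: float = 15.0
    seed: int = 0
    mu_init: float = 1e-3
    mu_raise: float = 10.0
    mu_lower: float = 0.1
    mu_max: float = 1e10
    patience: int = 6
    grad_tol: float = 1e-10

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.epochs < 1 or self.restarts < 1:
            raise ValueError("epochs and restarts must be positive")


def _unpack(theta: np.ndarray, taps: int, nh: int):
    i = taps * nh
    w_h = theta[:i].reshape(taps, nh)
    b_h = theta[i : i + nh]
    w_o = theta[i + nh : i + 2 * nh]
    b_o = theta[i + 2 * nh]
    return w_h, b_h, w_o, b_o


def _model_from_theta(theta, taps, nh, grid_step_mm) -> ANNModel:
    w_h, b_h, w_o, b_o = _unpack(theta, taps, nh)
    return ANNModel(w_h.copy(), b_h.copy(), w_o.copy(), float(b_o), grid_step_mm)


def _forward_theta(theta, X, taps, nh):
    w_h, b_h, w_o, b_o = _unpack(theta, taps, nh)
    a = np.tanh(X @ w_h + b_h)
    return a @ w_o + b_o, a


def _init_theta(taps: int, nh: int, rng: np.random.Generator) -> np.ndarray:
    w_h = rng.normal(0.0, 1.0 / np.sqrt(taps), (taps, nh))
    b_h = rng.uniform(-1.0, 1.0, nh)
    w_o = rng.normal(0.0, 1.0 / np.sqrt(nh), nh)
    b_o = rng.normal(0.0, 0.1)
    return np.concatenate([w_h.ravel(), b_h, w_o, [b_o]])


def _fit_single_restart(Xtr, ttr, Xval, tval, taps, nh, config: TrainingConfig, rng):
    """One LM run; returns (theta best-by-validation, history rows)."""
    theta = _init_theta(taps, nh, rng)
    n = Xtr.shape[0]
    n_params = theta.size
    mu = config.mu_init
    pred, a = _forward_theta(theta, Xtr, taps, nh)
    r = pred - ttr
    loss = float(np.mean(r * r))
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss at initialization")

    def val_mse(th):
        p, _ = _forward_theta(th, Xval, taps, nh)
        return float(np.mean((p - tval) ** 2))

    best_val = val_mse(theta)
    best_theta = theta.copy()
    fails = 0
    history = []
    eye = np.eye(n_params)
    for epoch in range(config.epochs):
        w_h, b_h, w_o, b_o = _unpack(theta, taps, nh)
        g = (1.0 - a * a) * w_o  # (n, nh)
        J = np.empty((n, n_params))
        J[:, : taps * nh] = (Xtr[:, :, None] * g[:, None, :]).reshape(n, taps * nh)
        J[:, taps * nh : taps * nh + nh] = g
        J[:, taps * nh + nh : taps * nh + 2 * nh] = a
        J[:, -1] = 1.0
        JtJ = J.T @ J
        Jtr = J.T @ r
        if np.max(np.abs(Jtr)) * 2.0 / n < config.grad_tol:
            break
        accepted = False
        while mu <= config.mu_max:
            try:
                c = cho_factor(JtJ + mu * eye, lower=True)
                delta = cho_solve(c, Jtr)
            except np.linalg.LinAlgError:
                mu *= config.mu_raise
                continue
            cand = theta - delta
            pred_c, a_c = _forward_theta(cand, Xtr, taps, nh)
            r_c = pred_c - ttr
            loss_c = float(np.mean(r_c * r_c))
            if np.isfinite(loss_c) and loss_c < loss:
                theta, r, a, loss = cand, r_c, a_c, loss_c
                mu = max(mu * config.mu_lower, 1e-20)
                accepted = True
                break
            mu *= config.mu_raise
        if not accepted:
            break  # damping exhausted: no downhill step exists at mu_max
        v = val_mse(theta)
        history.append({"epoch": epoch, "mu": mu, "train_mse": loss, "val_mse": v})
        if v < best_val - 1e-18:
            best_val = v
            best_theta = theta.copy()
            fails = 0
        else:
            fails += 1
            if fails > config.patience:
                break
    return best_theta, best_val, history


class SlidingWindowANN:
    """Model object: pair data plus architecture, ready to fit.

    Parameters
    ----------
    pairs : DataPairSet
        Window/target pairs; split into train/validation/test partitions
        using ``config.split`` if not already labeled.
    n_hidden : int
        Hidden-node count (default 18, the value selected by the sweep).
    config : TrainingConfig
        LM protocol settings; ``config.seed`` drives the partition and the
        per-restart initializations.
    """

    def __init__(
        self,
        pairs: DataPairSet,
        n_hidden: int = 18,
        config: TrainingConfig | None = None,
        grid_step_mm: float = 0.5,
    ):
        self.config = config or TrainingConfig()
        if pairs.labels is None:
            pairs = pairs.split(self.config.split, seed=self.config.seed)
        self.pairs = pairs
        self.n_hidden = int(n_hidden)
        self.grid_step_mm = float(grid_step_mm)

    def _check_capacity(self):
        taps = self.pairs.window_taps
        n_params = taps * self.n_hidden + 2 * self.n_hidden + 1
        n_train = self.pairs.partition("train")[0].shape[0]
        if n_train < 10 * n_params:
            warnings.warn(
                f"only {n_train} training pairs for {n_params} free parameters "
                "(< 10x); the fit may be under-determined",
                stacklevel=3,
            )

    def fit(self) -> "ANNFitResults":
        """Run ``config.restarts`` LM trainings; keep the best by validation MSE."""
        self._check_capacity()
        cfg = self.config
        taps = self.pairs.window_taps
        Xtr, ttr = self.pairs.partition("train")
        Xval, tval = self.pairs.partition("val")
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.restarts)
        best = None
        restart_rows = []
        histories = []
        for i, ss in enumerate(seeds):
            rng = np.random.default_rng(ss)
            try:
                theta, vmse, hist = _fit_single_restart(
                    Xtr, ttr, Xval, tval, taps, self.n_hidden, cfg, rng
                )
            except FloatingPointError as exc:
                warnings.warn(f"restart {i} aborted: {exc}", stacklevel=2)
                continue
            tmse = float(np.mean((_forward_theta(theta, Xtr, taps, self.n_hidden)[0] - ttr) ** 2))
            restart_rows.append(
                {"restart": i, "train_mse": tmse, "val_mse": vmse, "epochs": len(hist)}
            )
            histories.append(hist)
            if best is None or vmse < best[1]:
                best = (theta, vmse, i)
        if best is None:
            raise RuntimeError("all training restarts failed")
        theta, _, selected = best
        model = _model_from_theta(theta, taps, self.n_hidden, self.grid_step_mm)
        return ANNFitResults(
            model=model,
            pairs=self.pairs,
            config=cfg,
            restarts=restart_rows,
            histories=histories,
            selected_restart=selected,
        )

    def fit_sweep(self, sweep_range: tuple[int, ...] | None = None) -> "SweepResults":
        """Repeat the restart protocol for each hidden-node count in the sweep."""
        rng_range = tuple(sweep_range or self.config.sweep_range)
        entries = []
        for nh in rng_range:
            res = SlidingWindowANN(self.pairs, nh, self.config, self.grid_step_mm).fit()
            entries.append((nh, res))
        curve = [(nh, min(r["val_mse"] for r in res.restarts)) for nh, res in entries]
        best_nh = min(curve, key=lambda t: t[1])[0]
        selected = dict(entries)[best_nh]
        return SweepResults(curve=curve, results={nh: r for nh, r in entries}, selected=selected)


@dataclass
class ANNFitResults:
    """Trained network plus training diagnostics."""

    model: ANNModel
    pairs: DataPairSet
    config: TrainingConfig
    restarts: list[dict]
    histories: list[list[dict]]
    selected_restart: int

    def mse(self, partition: str = "test") -> float:
        X, t = self.pairs.partition(partition)
        return float(np.mean((self.model.predict(X) - t) ** 2))

    def reconstruct(self, profile: Profile) -> Profile:
        return reconstruct(self.model, profile)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Sliding-window ANN (Levenberg-Marquardt) fit",
            "=" * 52,
            f"window taps        {self.model.window_taps}  ({(self.model.window_taps - 1) * self.model.grid_step_mm:.1f} mm)",
            f"hidden nodes       {self.model.n_hidden}",
            f"free parameters    {self.model.n_params}",
            f"pairs (tr/va/te)   "
            + "/".join(str(self.pairs.partition(p)[1].size) for p in _PARTITIONS),
            f"restarts           {cfg.restarts} (selected #{self.selected_restart} by validation MSE)",
            f"MSE train          {self.mse('train'):.3e}",
            f"MSE validation     {self.mse('val'):.3e}",
            f"MSE test           {self.mse('test'):.3e}",
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        doc = self.model.to_dict()
        doc["training"] = {
            "config": {
                "epochs": self.config.epochs,
                "restarts": self.config.restarts,
                "split": list(self.config.split),
                "window_mm": self.config.window_mm,
                "seed": self.config.seed,
            },
            "selected_restart": self.selected_restart,
            "restarts": self.restarts,
            "mse": {p: self.mse(p) for p in _PARTITIONS},
        }
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass
class SweepResults:
    """Hidden-node sweep outcome: (N_hn, min recorded MSE) curve."""

    curve: list[tuple[int, float]]
    results: dict[int, ANNFitResults]
    selected: ANNFitResults

    def summary(self) -> str:
        lines = ["hidden-node sweep (min validation MSE per N_hn)", "-" * 48]
        for nh, m in self.curve:
            tag = "  <- selected" if self.results[nh] is self.selected else ""
            lines.append(f"  N_hn={nh:3d}   MSE={m:.3e}{tag}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        nh, m = zip(*self.curve)
        ax.semilogy(nh, m, "o-")
        ax.set_xlabel("hidden nodes")
        ax.set_ylabel("min MSE")
        return ax


def load_model(path: str | Path) -> ANNModel:
    return ANNModel.from_dict(json.loads(Path(path).read_text()))


def train_lm(
    pairs: DataPairSet, n_hidden: int = 18, config: TrainingConfig | None = None
) -> ANNFitResults:
    """Functional wrapper: LM training with restarts, best-by-validation."""
    return SlidingWindowANN(pairs, n_hidden, config).fit()


def sweep_hidden_nodes(pairs: DataPairSet, config: TrainingConfig | None = None) -> SweepResults:
    """Functional wrapper for the hidden-node parametric sweep."""
    return SlidingWindowANN(pairs, 2, config).fit_sweep()


def reconstruct(model: ANNModel, profile: Profile) -> Profile:
    """Slide the trained window across a profile, one grid step at a time.

    The half-window margins at each end, where the window does not fit, copy
    the input values; the result is renormalized to 1.0 on the central axis.
    """
    if abs(profile.grid_step_mm - model.grid_step_mm) > 1e-9:
        raise ValueError(
            f"profile grid step {profile.grid_step_mm} mm does not match "
            f"model grid step {model.grid_step_mm} mm"
        )
    taps = model.window_taps
    half = (taps - 1) // 2
    windows = sliding_window_view(profile.values, taps)
    out = profile.values.copy()
    out[half : out.size - half] = model.predict(windows)
    prof = Profile(profile.positions_mm, out, geometry=profile.geometry)
    return prof.normalized()
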
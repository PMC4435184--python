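"""Inversion engine: a small feed-forward network trained by Levenberg-
Marquardt (LMA) or Scaled Conjugate Gradient (SCGA), both implemented here.

The network maps the three deformation features to the three inclusion
parameters (d, h, E).  Default architecture: three weighted layers of 3, 4
and 3 neurons with sigmoid, sigmoid and linear activations.  Inputs and
targets are min-max scaled to [0, 1]; training minimizes the sum of squared
residuals E(x) = sum_i e_i(x)^2 in scaled space over the flattened parameter
vector x (weights then biases, layer by layer).

Both trainers operate on the residual/gradient closures produced by
backpropagation:

* LMA iterates ``dx = (J^T J + mu I)^{-1} J^T e`` with the classic damping
  schedule — mu multiplied by beta on a step that would increase E(x),
  divided by beta on an accepted step.  Large mu turns the step into scaled
  gradient descent, small mu into Gauss-Newton.
* SCGA is Moller's scaled conjugate gradient: curvature information via a
  finite-difference Hessian-vector product, a Levenberg-style lambda that
  repairs negative curvature, a quadratic-model comparison parameter that
  accepts or rejects the step and adapts lambda (halved when the model is
  trustworthy, quadrupled when poor), and a restart to the steepest-descent
  direction every N iterations (N = number of parameters).  Memory use is
  O(N): no Hessian is ever materialized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .fem import FeatureTriple

__all__ = [
    "AffineScaler",
    "NetworkWeights",
    "TrainConfig",
    "Dataset",
    "init_network",
    "forward_pass",
    "error_and_jacobian",
    "fit_scalers",
    "train_lma",
    "train_scga",
    "lma_least_squares",
    "scg_minimize",
    "predict_parameters",
    "save_network",
    "load_network",
]

_DEF_SIZES = (3, 3, 4, 3)
_DEF_ACTS = ("sigmoid", "sigmoid", "linear")


# ---------------------------------------------------------------------------
# scalers


@dataclass
class AffineScaler:
    """Per-channel affine map to the unit interval: (x - lo) / (hi - lo)."""

    lo: np.ndarray
    hi: np.ndarray
    fitted: bool = True

    def __post_init__(self) -> None:
        self.lo = np.atleast_1d(np.asarray(self.lo, dtype=float))
        self.hi = np.atleast_1d(np.asarray(self.hi, dtype=float))
        if np.any(self.hi == self.lo):
            raise ValueError("zero-range channel: scaler not invertible")

    @classmethod
    def identity(cls, dim: int) -> "AffineScaler":
        return cls(lo=np.zeros(dim), hi=np.ones(dim), fitted=False)

    def scale(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo)

    def unscale(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * (self.hi - self.lo) + self.lo


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _act(name: str, z: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return _sigmoid(z)
    if name == "linear":
        return z
    raise ValueError(f"unknown activation {name!r}")


def _act_deriv(name: str, a: np.ndarray) -> np.ndarray:
    """Derivative expressed through the activation value ``a``."""
    if name == "sigmoid":
        return a * (1.0 - a)
    if name == "linear":
        return np.ones_like(a)
    raise ValueError(f"unknown activation {name!r}")


# ---------------------------------------------------------------------------
# network container


@dataclass
class NetworkWeights:
    """Weights, biases, activations and the fitted input/output scalers."""

    sizes: tuple[int, ...]
    activations: tuple[str, ...]
    weights: list[np.ndarray]  # weights[l] has shape (sizes[l+1], sizes[l])
    biases: list[np.ndarray]
    input_scaler: AffineScaler = dc_field(default_factory=lambda: AffineScaler.identity(3))
    output_scaler: AffineScaler = dc_field(default_factory=lambda: AffineScaler.identity(3))

    def __post_init__(self) -> None:
        if len(self.activations) != len(self.sizes) - 1:
            raise ValueError("need one activation per weighted layer")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (self.sizes[l + 1], self.sizes[l]) or b.shape != (self.sizes[l + 1],):
                raise ValueError(f"layer {l} shape mismatch")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError("non-finite weights")

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def to_vector(self) -> np.ndarray:
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(w.ravel())
            parts.append(b)
        return np.concatenate(parts)

    def from_vector(self, x: np.ndarray) -> "NetworkWeights":
        ws, bs, off = [], [], 0
        for l in range(len(self.sizes) - 1):
            wn = self.sizes[l + 1] * self.sizes[l]
            ws.append(x[off : off + wn].reshape(self.sizes[l + 1], self.sizes[l]).copy())
            off += wn
            bs.append(x[off : off + self.sizes[l + 1]].copy())
            off += self.sizes[l + 1]
        return NetworkWeights(
            sizes=self.sizes,
            activations=self.activations,
            weights=ws,
            biases=bs,
            input_scaler=self.input_scaler,
            output_scaler=self.output_scaler,
        )


def init_network(
    seed: int = 0,
    sizes: tuple[int, ...] = _DEF_SIZES,
    activations: tuple[str, ...] = _DEF_ACTS,
) -> NetworkWeights:
    """Seeded random initialization: U(-1, 1)/sqrt(fan_in) weights, zero biases."""
    rng = np.random.default_rng(seed)
    ws, bs = [], []
    for l in range(len(sizes) - 1):
        ws.append(rng.uniform(-1, 1, size=(sizes[l + 1], sizes[l])) / np.sqrt(sizes[l]))
        bs.append(np.zeros(sizes[l + 1]))
    return NetworkWeights(
        sizes=tuple(sizes),
        activations=tuple(activations),
        weights=ws,
        biases=bs,
        input_scaler=AffineScaler.identity(sizes[0]),
        output_scaler=AffineScaler.identity(sizes[-1]),
    )


# ---------------------------------------------------------------------------
# forward / backward


def _forward_scaled(w: NetworkWeights, Xs: np.ndarray) -> list[np.ndarray]:
    """Layer activations [A0=Xs, A1, ..., AL] in scaled space."""
    A = [np.atleast_2d(Xs)]
    for name, W, b in zip(w.activations, w.weights, w.biases):
        A.append(_act(name, A[-1] @ W.T + b))
    return A


def forward_pass(w: NetworkWeights, x) -> np.ndarray:
    """Physical-unit prediction: scale input, run the net, unscale output.

    Accepts a FeatureTriple, a length-3 vector, or an (n, 3) matrix.
    """
    if isinstance(x, FeatureTriple):
        x = x.as_array()
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    Xs = w.input_scaler.scale(np.atleast_2d(x))
    Ys = _forward_scaled(w, Xs)[-1]
    Y = w.output_scaler.unscale(Ys)
    return Y[0] if single else Y


def residuals(w: NetworkWeights, data: "Dataset", x: np.ndarray | None = None) -> np.ndarray:
    """Scaled residual vector only (no Jacobian); record-major stacking."""
    net = w if x is None else w.from_vector(np.asarray(x, dtype=float))
    Xs = w.input_scaler.scale(data.X)
    Ts = w.output_scaler.scale(data.Y)
    Ys = _forward_scaled(net, Xs)[-1]
    if not np.all(np.isfinite(Ys)):
        raise FloatingPointError("non-finite residuals in forward pass")
    return (Ys - Ts).ravel()


def error_and_jacobian(
    w: NetworkWeights, data: "Dataset", x: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Residual vector e and Jacobian J = de/dx in scaled space.

    Residuals are stacked record-major: (record 0, outputs 0..K-1), then
    record 1, and so on.  J has one column per entry of the flattened
    parameter vector (weights then biases, layer by layer).
    """
    net = w if x is None else w.from_vector(np.asarray(x, dtype=float))
    Xs = w.input_scaler.scale(data.X)
    Ts = w.output_scaler.scale(data.Y)
    A = _forward_scaled(net, Xs)
    Ys = A[-1]
    if not np.all(np.isfinite(Ys)):
        raise FloatingPointError("non-finite residuals in forward pass")
    n, K = Ys.shape
    L = len(net.weights)

    # sensitivities S_l = d y_k / d z_l, shape (n, K, width_l), built backward
    S = _act_deriv(net.activations[-1], A[-1])[:, None, :] * np.eye(K)[None, :, :]
    sens = [None] * L
    sens[L - 1] = S
    for l in range(L - 1, 0, -1):
        S = np.einsum("nki,ij->nkj", S, net.weights[l]) * _act_deriv(
            net.activations[l - 1], A[l]
        )[:, None, :]
        sens[l - 1] = S

    blocks = []
    for l in range(L):
        jw = np.einsum("nki,nj->nkij", sens[l], A[l]).reshape(n, K, -1)
        blocks.append(jw)
        blocks.append(sens[l])
    J = np.concatenate(blocks, axis=2).reshape(n * K, -1)
    e = (Ys - Ts).reshape(n * K)
    return e, J


# ---------------------------------------------------------------------------
# datasets and scalers


@dataclass
class Dataset:
    """Paired feature inputs (FEM units) and (d, h, E) targets."""

    X: np.ndarray  # (n, 3) features
    Y: np.ndarray  # (n, 3) parameters
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        self.ids = np.asarray(self.ids)
        if len(self.X) != len(self.Y) or len(self.X) != len(self.ids):
            raise ValueError("inputs, targets and ids must have equal length")
        if len(self.X) == 0:
            raise ValueError("empty dataset")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("non-finite dataset entries")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, mask_or_idx) -> "Dataset":
        return Dataset(X=self.X[mask_or_idx], Y=self.Y[mask_or_idx], ids=self.ids[mask_or_idx])

    @classmethod
    def from_features(cls, features: Sequence[FeatureTriple], params: np.ndarray, ids=None) -> "Dataset":
        X = np.array([f.as_array() for f in features])
        ids = np.arange(len(X)) if ids is None else np.asarray(ids)
        return cls(X=X, Y=np.asarray(params, dtype=float), ids=ids)

    def to_csv(self, path_or_buf) -> None:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "ofem1": self.X[:, 0],
                "ofem2": self.X[:, 1],
                "ofem3": self.X[:, 2],
                "d_mm": self.Y[:, 0],
                "h_mm": self.Y[:, 1],
                "E_kPa": self.Y[:, 2],
            }
        )
        df.to_csv(path_or_buf, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path_or_buf) -> "Dataset":
        df = pd.read_csv(path_or_buf, float_precision="round_trip")
        return cls(
            X=df[["ofem1", "ofem2", "ofem3"]].to_numpy(),
            Y=df[["d_mm", "h_mm", "E_kPa"]].to_numpy(),
            ids=df["id"].to_numpy(),
        )


def fit_scalers(data: Dataset) -> tuple[AffineScaler, AffineScaler]:
    """Min-max scalers for inputs and targets; errors on a zero-range channel."""
    for name, M in (("input", data.X), ("target", data.Y)):
        if np.any(M.max(axis=0) == M.min(axis=0)):
            ch = int(np.argmax(M.max(axis=0) == M.min(axis=0)))
            raise ValueError(f"zero-range {name} channel {ch}: min-max scaling undefined")
    return (
        AffineScaler(lo=data.X.min(axis=0), hi=data.X.max(axis=0)),
        AffineScaler(lo=data.Y.min(axis=0), hi=data.Y.max(axis=0)),
    )


# ---------------------------------------------------------------------------
# training configuration


@dataclass(frozen=True)
class TrainConfig:
    """Trainer selection and hyperparameters.

    LMA: initial damping ``mu0`` and factor ``beta``.
    SCGA: finite-difference scale ``sigma`` and initial ``lam``.
    ``tol`` stops training when the error change on an accepted step falls
    below it (0 disables, running the full iteration budget).
    """

    algorithm: str = "SCGA"
    max_iter: int = 100
    tol: float = 0.0
    mu0: float = 1e-3
    beta: float = 10.0
    sigma: float = 1e-4
    lam0: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("LMA", "SCGA"):
            raise ValueError("algorithm must be 'LMA' or 'SCGA'")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if min(self.mu0, self.beta, self.sigma, self.lam0) <= 0:
            raise ValueError("mu0, beta, sigma, lam0 must be positive")


# ---------------------------------------------------------------------------
# generic optimizers


def lma_least_squares(
    residual_jac: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
    x0: np.ndarray,
    mu0: float = 1e-3,
    beta: float = 10.0,
    max_iter: int = 100,
    tol: float = 0.0,
    mu_max: float = 1e12,
) -> tuple[np.ndarray, list[float]]:
    """Damped Gauss-Newton on a residual function; returns (x, error history).

    The history records E(x) = sum e^2 after every accepted step and is
    nonincreasing by construction (rejected steps restore the previous x and
    raise mu).
    """
    x = np.asarray(x0, dtype=float).copy()
    e, J = residual_jac(x)
    E = float(e @ e)
    mu = mu0
    hist = [E]
    I = np.eye(len(x))
    for _ in range(max_iter):
        g = J.T @ e
        H = J.T @ J
        accepted = False
        while mu <= mu_max:
            try:
                dx = np.linalg.solve(H + mu * I, g)
            except np.linalg.LinAlgError:
                mu *= beta
                continue
            x_try = x - dx
            try:
                e_try, J_try = residual_jac(x_try)
            except FloatingPointError:
                mu *= beta
                continue
            E_try = float(e_try @ e_try)
            if E_try < E:
                x, e, J, E = x_try, e_try, J_try, E_try
                mu /= beta
                accepted = True
                break
            mu *= beta
        if not accepted:
            break
        hist.append(E)
        if tol > 0 and abs(hist[-2] - hist[-1]) < tol:
            break
    return x, hist


def scg_minimize(
    f: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    sigma: float = 1e-4,
    lam: float = 1e-6,
    max_iter: int = 100,
    tol: float = 0.0,
) -> tuple[np.ndarray, list[float]]:
    """Moller's scaled conjugate gradient; returns (x, accepted-error history).

    Curvature is probed with a forward-difference Hessian-vector product along
    the search direction; lambda regularizes indefiniteness and adapts from
    the comparison parameter Delta (the ratio of actual to predicted
    reduction): accepted steps with Delta >= 0.75 halve lambda, any step with
    Delta < 0.25 quadruples it.  The direction restarts to steepest descent
    every N iterations (N = dimension).  Only O(N) vectors are stored.
    """
    x = np.asarray(x0, dtype=float).copy()
    N = len(x)
    E = float(f(x))
    r = -grad(x)
    p = r.copy()
    lam_bar = 0.0
    success = True
    hist = [E]
    s = np.zeros_like(x)
    delta = 0.0
    pnorm2 = float(p @ p)
    k = 1
    while k <= max_iter:
        if np.sqrt(r @ r) == 0.0:
            break
        if success:
            pnorm2 = float(p @ p)
            if pnorm2 == 0.0:
                break
            sigma_k = sigma / np.sqrt(pnorm2)
            s = (grad(x + sigma_k * p) + r) / sigma_k  # grad(x) == -r
            delta = float(p @ s)
        # scale s, repair indefiniteness
        s = s + (lam - lam_bar) * p
        delta = delta + (lam - lam_bar) * pnorm2
        if delta <= 0.0:
            s = s + (lam - 2.0 * delta / pnorm2) * p
            lam_bar = 2.0 * (lam - delta / pnorm2)
            delta = -delta + lam * pnorm2
            lam = lam_bar
        mu = float(p @ r)
        if delta == 0.0 or not np.isfinite(delta):
            lam_bar = lam
            lam *= 4.0
            success = False
            k += 1
            if not np.isfinite(lam):
                raise RuntimeError(f"SCGA lambda diverged (lam={lam}, iter={k})")
            continue
        alpha = mu / delta
        E_try = float(f(x + alpha * p))
        Delta = 2.0 * delta * (E - E_try) / mu**2
        if Delta >= 0.0:
            x = x + alpha * p
            E = E_try
            r_new = -grad(x)
            lam_bar = 0.0
            success = True
            if k % N == 0:
                p_new = r_new.copy()
            else:
                beta_k = float(r_new @ r_new - r_new @ r) / mu
                p_new = r_new + beta_k * p
            if Delta >= 0.75:
                lam *= 0.5
            r, p = r_new, p_new
            hist.append(E)
            if tol > 0 and abs(hist[-2] - hist[-1]) < tol:
                break
        else:
            lam_bar = lam
            success = False
        if Delta < 0.25:
            lam *= 4.0
        if not np.isfinite(lam) or lam > 1e300:
            raise RuntimeError(
                f"SCGA lambda diverged (lam={lam}, iter={k}, E={E}, |r|={np.linalg.norm(r)})"
            )
        k += 1
    return x, hist


# ---------------------------------------------------------------------------
# trainers


def _require_scalers(w: NetworkWeights, data: Dataset) -> NetworkWeights:
    if not (w.input_scaler.fitted and w.output_scaler.fitted):
        xin, xout = fit_scalers(data)
        w = dataclasses.replace(w, input_scaler=xin, output_scaler=xout)
    return w


def train_lma(
    w: NetworkWeights, data: Dataset, cfg: TrainConfig | None = None
) -> tuple[NetworkWeights, list[float]]:
    """Levenberg-Marquardt training; returns trained weights and E(x) history."""
    cfg = cfg or TrainConfig(algorithm="LMA")
    if cfg.algorithm != "LMA":
        raise ValueError("train_lma requires cfg.algorithm == 'LMA'")
    w = _require_scalers(w, data)
    x, hist = lma_least_squares(
        lambda x: error_and_jacobian(w, data, x),
        w.to_vector(),
        mu0=cfg.mu0,
        beta=cfg.beta,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
    )
    return w.from_vector(x), hist


def train_scga(
    w: NetworkWeights, data: Dataset, cfg: TrainConfig | None = None
) -> tuple[NetworkWeights, list[float]]:
    """Scaled-conjugate-gradient training; returns trained weights and history."""
    cfg = cfg or TrainConfig(algorithm="SCGA")
    if cfg.algorithm != "SCGA":
        raise ValueError("train_scga requires cfg.algorithm == 'SCGA'")
    w = _require_scalers(w, data)

    def f(x: np.ndarray) -> float:
        e = residuals(w, data, x)
        return float(e @ e)

    def g(x: np.ndarray) -> np.ndarray:
        e, J = error_and_jacobian(w, data, x)
        return 2.0 * (J.T @ e)

    x, hist = scg_minimize(
        f, g, w.to_vector(), sigma=cfg.sigma, lam=cfg.lam0, max_iter=cfg.max_iter, tol=cfg.tol
    )
    return w.from_vector(x), hist


def train(w: NetworkWeights, data: Dataset, cfg: TrainConfig) -> tuple[NetworkWeights, list[float]]:
    """Dispatch to the configured trainer."""
    return (train_lma if cfg.algorithm == "LMA" else train_scga)(w, data, cfg)


def predict_parameters(w: NetworkWeights, features) -> np.ndarray:
    """Estimate (d mm, h mm, E kPa) from a FEM-unit feature triple.

    Raw network output: no clamping to physical bounds.
    """
    if not (w.input_scaler.fitted and w.output_scaler.fitted):
        raise ValueError("scalers not fitted: train the network (or fit_scalers) first")
    return forward_pass(w, features)


# ---------------------------------------------------------------------------
# serialization


def save_network(w: NetworkWeights, path) -> None:
    with open(path, "w") as f:
        f.write("palpinv-network 1\n")
        f.write("sizes " + " ".join(map(str, w.sizes)) + "\n")
        f.write("activations " + " ".join(w.activations) + "\n")
        f.write("params " + " ".join(repr(float(v)) for v in w.to_vector()) + "\n")
        for tag, sc in (("input_scaler", w.input_scaler), ("output_scaler", w.output_scaler)):
            f.write(
                f"{tag} {int(sc.fitted)} "
                + " ".join(repr(float(v)) for v in sc.lo)
                + " | "
                + " ".join(repr(float(v)) for v in sc.hi)
                + "\n"
            )


def load_network(path) -> NetworkWeights:
    with open(path) as f:
        if not f.readline().startswith("palpinv-network"):
            raise ValueError("not a palpinv network file")
        sizes = tuple(int(v) for v in f.readline().split()[1:])
        acts = tuple(f.readline().split()[1:])
        params = np.array([float(v) for v in f.readline().split()[1:]])
        scalers = []
        for _ in range(2):
            parts = f.readline().split()
            fitted = bool(int(parts[1]))
            bar = parts.index("|")
            lo = np.array([float(v) for v in parts[2:bar]])
            hi = np.array([float(v) for v in parts[bar + 1 :]])
            scalers.append(AffineScaler(lo=lo, hi=hi, fitted=fitted))
    w = init_network(0, sizes, acts)
    w = dataclasses.replace(w, input_scaler=scalers[0], output_scaler=scalers[1])
    return w.from_vector(params)
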
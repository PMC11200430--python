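"""Feed-forward neural surrogate for the four extraction responses.

The network maps the 4 coded factors through H tanh hidden units to 4 linear
outputs (a 4-H-4 multilayer perceptron).  Targets are min-max scaled to
[-1, 1] per response before training; coded factors are used directly as
inputs.  Training minimizes mean squared error on the training partition with
either a damped least-squares (Levenberg-Marquardt family) solver on the
residual vector or BFGS on the scalar MSE.  Weight initialization is uniform
in [-0.5, 0.5] from the run's seed, so a fixed (data, seed, config) triple
yields bit-identical weights.

Data are split train/test/validation by largest-remainder apportionment of
the requested fractions; the hidden-layer sweep selects the neuron count with
the lowest validation MSE.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize as sp_opt

from .design import DesignTable

__all__ = [
    "SplitPlan",
    "AnnSurrogate",
    "split_data",
    "train_ann",
    "sweep_hidden_neurons",
    "predict_ann",
    "save_surrogate",
    "load_surrogate",
]

DEFAULT_FRACTIONS = (0.65, 0.20, 0.15)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test/validation index sets covering all runs."""

    train_idx: tuple[int, ...]
    test_idx: tuple[int, ...]
    val_idx: tuple[int, ...]
    fractions: tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        all_idx = self.train_idx + self.test_idx + self.val_idx
        if len(set(all_idx)) != len(all_idx):
            raise ValueError("split partitions overlap")

    @property
    def n(self) -> int:
        return len(self.train_idx) + len(self.test_idx) + len(self.val_idx)


def _largest_remainder(n: int, fractions: tuple[float, ...]) -> list[int]:
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    short = n - sum(sizes)
    order = np.argsort([-(q - s) for q, s in zip(quotas, sizes)], kind="stable")
    for i in range(short):
        sizes[order[i]] += 1
    return sizes


def split_data(
    n_runs: int,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
) -> SplitPlan:
    """Random reproducible split with largest-remainder partition sizes."""
    if n_runs < 5:
        raise ValueError("need at least 5 runs to split")
    if any(f <= 0 for f in fractions):
        raise ValueError("all fractions must be positive")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    sizes = _largest_remainder(n_runs, tuple(fractions))
    perm = np.random.default_rng(seed).permutation(n_runs)
    a, b = sizes[0], sizes[0] + sizes[1]
    return SplitPlan(
        train_idx=tuple(int(i) for i in np.sort(perm[:a])),
        test_idx=tuple(int(i) for i in np.sort(perm[a:b])),
        val_idx=tuple(int(i) for i in np.sort(perm[b:])),
        fractions=tuple(fractions),
        seed=seed,
    )


@dataclass
class AnnSurrogate:
    """Trained 4-H-4 network with its scaling and training history."""

    n_hidden: int
    w1: np.ndarray  # (H, n_in)
    b1: np.ndarray  # (H,)
    w2: np.ndarray  # (n_out, H)
    b2: np.ndarray  # (n_out,)
    w3: np.ndarray | None  # (n_out, n_in) cascade skip weights, or None
    y_min: np.ndarray  # per-response scaling
    y_max: np.ndarray
    response_names: tuple[str, ...]
    algorithm: str
    seed: int
    mse_history: pd.DataFrame = field(repr=False)  # columns train, val

    @property
    def n_params(self) -> int:
        n = self.w1.size + self.b1.size + self.w2.size + self.b2.size
        return n + (self.w3.size if self.w3 is not None else 0)

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        return 2.0 * (y - self.y_min) / (self.y_max - self.y_min) - 1.0

    def inverse_scale_y(self, s: np.ndarray) -> np.ndarray:
        return (s + 1.0) / 2.0 * (self.y_max - self.y_min) + self.y_min

    def forward_scaled(self, x_coded: np.ndarray) -> np.ndarray:
        h = np.tanh(x_coded @ self.w1.T + self.b1)
        out = h @ self.w2.T + self.b2
        if self.w3 is not None:
            out = out + x_coded @ self.w3.T
        return out


def _unpack(theta: np.ndarray, n_in: int, H: int, n_out: int, cascade: bool = False):
    i = 0
    w1 = theta[i : i + H * n_in].reshape(H, n_in); i += H * n_in
    b1 = theta[i : i + H]; i += H
    w2 = theta[i : i + n_out * H].reshape(n_out, H); i += n_out * H
    b2 = theta[i : i + n_out]; i += n_out
    w3 = theta[i : i + n_out * n_in].reshape(n_out, n_in) if cascade else None
    return w1, b1, w2, b2, w3


def _forward(theta, X, n_in, H, n_out, cascade=False):
    w1, b1, w2, b2, w3 = _unpack(theta, n_in, H, n_out, cascade)
    hid = np.tanh(X @ w1.T + b1)
    out = hid @ w2.T + b2
    if w3 is not None:
        out = out + X @ w3.T
    return out, hid, (w1, b1, w2, b2, w3)


def _jacobian(theta, X, n_in, H, n_out, cascade=False):
    """Analytic Jacobian of the flattened residual vector w.r.t. theta."""
    n = X.shape[0]
    _, hid, (w1, b1, w2, b2, w3) = _forward(theta, X, n_in, H, n_out, cascade)
    dhid = 1.0 - hid**2  # (n, H)
    J = np.zeros((n * n_out, theta.size))
    base = H * n_in + H + n_out * H
    # residual r[s, o] laid out row-major: index s * n_out + o
    for o in range(n_out):
        rows = np.arange(n) * n_out + o
        # d out_o / d w1[h, i] = w2[o, h] * dhid[:, h] * X[:, i]
        block = (w2[o][None, :] * dhid)[:, :, None] * X[:, None, :]  # (n, H, n_in)
        J[rows, : H * n_in] = block.reshape(n, H * n_in)
        J[rows, H * n_in : H * n_in + H] = w2[o][None, :] * dhid
        J[rows, H * n_in + H + o * H : H * n_in + H + (o + 1) * H] = hid
        J[rows, base + o] = 1.0
        if cascade:
            J[rows, base + n_out + o * n_in : base + n_out + (o + 1) * n_in] = X
    return J


def train_ann(
    design: DesignTable,
    responses: pd.DataFrame,
    n_hidden: int = 10,
    algorithm: str = "lm",
    split: SplitPlan | None = None,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    n_restarts: int = 1,
    cascade: bool = False,
) -> AnnSurrogate:
    """Train the surrogate on the training partition of a split.

    ``algorithm='lm'`` uses a damped least-squares solver on the per-sample
    residuals (the Levenberg-Marquardt family); ``'bfgs'`` minimizes the MSE
    with BFGS.  ``n_restarts > 1`` repeats training from fresh seeded
    initializations and keeps the weights with the lowest validation MSE
    (falling back to training MSE when the validation partition is empty).
    """
    if not 1 <= n_hidden <= 20:
        raise ValueError("n_hidden must be in [1, 20]")
    if algorithm not in ("lm", "bfgs"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    X = design.coded().values
    Y = responses.loc[design.actual.index].values.astype(float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite inputs")
    n, n_in = X.shape
    n_out = Y.shape[1]
    if split is None:
        split = split_data(n, seed=seed)

    y_min, y_max = Y.min(axis=0), Y.max(axis=0)
    if np.any(y_max == y_min):
        raise ValueError("constant response column cannot be min-max scaled")
    S = 2.0 * (Y - y_min) / (y_max - y_min) - 1.0

    tr = np.asarray(split.train_idx)
    va = np.asarray(split.val_idx)
    Xtr, Str = X[tr], S[tr]
    Xva, Sva = (X[va], S[va]) if len(va) else (None, None)

    n_theta = (n_in + 1) * n_hidden + (n_hidden + 1) * n_out
    if cascade:
        n_theta += n_out * n_in
    best = None
    for restart in range(n_restarts):
        rng = np.random.default_rng((seed, restart))
        theta0 = rng.uniform(-0.5, 0.5, size=n_theta)
        theta, hist = _fit_once(
            theta0, Xtr, Str, Xva, Sva, n_in, n_hidden, n_out, algorithm,
            max_iter, tol, cascade,
        )
        sel = hist["val"].iloc[-1] if Xva is not None else hist["train"].iloc[-1]
        if best is None or sel < best[0]:
            best = (sel, theta, hist)

    _, theta, hist = best
    w1, b1, w2, b2, w3 = _unpack(theta, n_in, n_hidden, n_out, cascade)
    return AnnSurrogate(
        n_hidden=n_hidden,
        w1=w1, b1=b1, w2=w2, b2=b2, w3=w3,
        y_min=y_min, y_max=y_max,
        response_names=tuple(responses.columns),
        algorithm=algorithm,
        seed=seed,
        mse_history=hist,
    )


def _fit_once(theta0, Xtr, Str, Xva, Sva, n_in, H, n_out, algorithm, max_iter, tol,
              cascade=False):
    history = []

    def record(theta):
        out_tr, _, _ = _forward(theta, Xtr, n_in, H, n_out, cascade)
        mse_tr = float(np.mean((out_tr - Str) ** 2))
        if Xva is not None:
            out_va, _, _ = _forward(theta, Xva, n_in, H, n_out, cascade)
            mse_va = float(np.mean((out_va - Sva) ** 2))
        else:
            mse_va = np.nan
        history.append((mse_tr, mse_va))

    record(theta0)
    if algorithm == "lm":
        # damped least-squares on the residual vector; 'trf' handles the
        # under-determined case (fewer residuals than weights) that plain LM
        # rejects, with the same Gauss-Newton-with-damping character
        def resid(theta):
            out, _, _ = _forward(theta, Xtr, n_in, H, n_out, cascade)
            return (out - Str).ravel()

        def jac(theta):
            return _jacobian(theta, Xtr, n_in, H, n_out, cascade)

        res = sp_opt.least_squares(
            resid, theta0, jac=jac, method="trf",
            max_nfev=max_iter, ftol=tol, xtol=tol, gtol=tol,
        )
        theta = res.x
    else:
        scale = 1.0 / (Str.size)

        def mse(theta):
            out, _, _ = _forward(theta, Xtr, n_in, H, n_out, cascade)
            return float(np.sum((out - Str) ** 2)) * scale

        def grad(theta):
            r = (_forward(theta, Xtr, n_in, H, n_out, cascade)[0] - Str).ravel()
            return 2.0 * scale * (_jacobian(theta, Xtr, n_in, H, n_out, cascade).T @ r)

        res = sp_opt.minimize(
            mse, theta0, jac=grad, method="BFGS",
            options={"maxiter": max_iter, "gtol": tol},
        )
        theta = res.x
    record(theta)
    hist = pd.DataFrame(history, columns=["train", "val"])
    # training must never end worse than it started
    if hist["train"].iloc[-1] > hist["train"].iloc[0]:
        theta = theta0  # pathological solver step; keep the initialization
        hist = hist.iloc[[0, 0]].reset_index(drop=True)
    return theta, hist


def sweep_hidden_neurons(
    design: DesignTable,
    responses: pd.DataFrame,
    h_range=range(1, 21),
    algorithm: str = "lm",
    split: SplitPlan | None = None,
    seed: int = 0,
    max_iter: int = 500,
    n_restarts: int = 1,
) -> tuple[int, pd.DataFrame]:
    """Train one surrogate per hidden-layer size; pick the lowest val MSE.

    Returns the selected H and the per-H MSE table (train and validation).
    Ties break toward the smaller network.  Individual training failures are
    recorded as NaN rows and skipped unless every size fails.
    """
    h_list = list(h_range)
    if not h_list:
        raise ValueError("empty h_range")
    if split is None:
        split = split_data(design.n_runs, seed=seed)
    rows = []
    for H in h_list:
        try:
            m = train_ann(
                design, responses, n_hidden=H, algorithm=algorithm,
                split=split, seed=seed, max_iter=max_iter, n_restarts=n_restarts,
            )
            rows.append(
                (H, m.mse_history["train"].iloc[-1], m.mse_history["val"].iloc[-1])
            )
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            warnings.warn(f"H={H}: training failed ({exc})", stacklevel=2)
            rows.append((H, np.nan, np.nan))
    table = pd.DataFrame(rows, columns=["n_hidden", "train_mse", "val_mse"]).set_index(
        "n_hidden"
    )
    crit = table["val_mse"] if table["val_mse"].notna().any() else table["train_mse"]
    if crit.isna().all():
        raise RuntimeError("training failed for every hidden-layer size")
    selected = int(crit.idxmin())  # idxmin takes the first (smallest H) on ties
    return selected, table


def predict_ann(model: AnnSurrogate, design_or_coded, warn_off_box: bool = True) -> pd.DataFrame:
    """Forward pass at the given points; outputs on the original response scale.

    Accepts a :class:`DesignTable` or an array/frame of already-coded factor
    values.  Points outside the coded [-1, 1] box are evaluated (the network
    extrapolates smoothly) with a warning.
    """
    if isinstance(design_or_coded, DesignTable):
        Xc = design_or_coded.coded().values
        index = design_or_coded.actual.index
    else:
        Xc = np.atleast_2d(np.asarray(design_or_coded, dtype=float))
        index = pd.RangeIndex(len(Xc))
    if warn_off_box and np.any(np.abs(Xc) > 1.0 + 1e-9):
        warnings.warn("evaluating the surrogate outside the coded design box", stacklevel=2)
    out = model.inverse_scale_y(model.forward_scaled(Xc))
    return pd.DataFrame(out, index=index, columns=model.response_names)


def save_surrogate(model: AnnSurrogate, path) -> None:
    """Serialize to portable JSON; re-loadable bit-exactly via binary hex."""
    payload = {
        "n_hidden": model.n_hidden,
        "algorithm": model.algorithm,
        "seed": model.seed,
        "response_names": list(model.response_names),
        "arrays": {
            name: {"shape": list(arr.shape), "hex": arr.astype("<f8").tobytes().hex()}
            for name, arr in [
                ("w1", model.w1), ("b1", model.b1), ("w2", model.w2),
                ("b2", model.b2), ("y_min", model.y_min), ("y_max", model.y_max),
            ] + ([("w3", model.w3)] if model.w3 is not None else [])
        },
        "mse_history": model.mse_history.to_dict(orient="list"),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_surrogate(path) -> AnnSurrogate:
    with open(path) as fh:
        payload = json.load(fh)
    arrays = {
        name: np.frombuffer(bytes.fromhex(spec["hex"]), dtype="<f8").reshape(spec["shape"])
        for name, spec in payload["arrays"].items()
    }
    return AnnSurrogate(
        n_hidden=payload["n_hidden"],
        w1=arrays["w1"], b1=arrays["b1"], w2=arrays["w2"], b2=arrays["b2"],
        w3=arrays.get("w3"),
        y_min=arrays["y_min"], y_max=arrays["y_max"],
        response_names=tuple(payload["response_names"]),
        algorithm=payload["algorithm"],
        seed=payload["seed"],
        mse_history=pd.DataFrame(payload["mse_history"]),
    )
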
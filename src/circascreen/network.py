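"""1-D convolutional network regressing (onset time, peak phase) in ZT hours.

The network maps one min-max-normalized 25-point curve to two real outputs.
Architecture (valid convolutions; lengths 25 -> 20 -> 17 -> 14 -> 7 -> 3):

    conv(16 filters, kernel 6, ReLU)
    conv(32 filters, kernel 4, ReLU)
    conv(64 filters, kernel 4, ReLU)
    max-pool(window 2, stride 2) x 2
    fully connected 1024 (ReLU, dropout keep 0.5)
    fully connected 1024 (ReLU)
    linear output (2 units: onset, peak)

Training minimizes the mean absolute deviation between labels and
predictions with Adam at learning rate 1e-4.  Everything is plain numpy:
forward, backprop, and the optimizer are implemented here so training is
deterministic under a fixed seed on a single thread.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .errors import TrainingDivergedError
from .ic_data import CANONICAL_ZT

GRID_SPAN = (float(CANONICAL_ZT[0]), float(CANONICAL_ZT[-1]))


@dataclass(frozen=True)
class NetworkSpec:
    """Layer hyper-parameters; the defaults are the screening architecture."""

    input_len: int = 25
    conv_filters: tuple[int, ...] = (16, 32, 64)
    conv_kernels: tuple[int, ...] = (6, 4, 4)
    n_pool: int = 2
    pool_window: int = 2
    fc_units: tuple[int, ...] = (1024, 1024)
    dropout_keep: float = 0.5
    n_outputs: int = 2

    def conv_lengths(self) -> list[int]:
        """Sequence lengths after each conv, then after each pool."""
        lengths = []
        L = self.input_len
        for k in self.conv_kernels:
            L = L - k + 1
            if L <= 0:
                raise ValueError("kernel arithmetic leaves no output positions")
            lengths.append(L)
        for _ in range(self.n_pool):
            L = L // self.pool_window
            if L <= 0:
                raise ValueError("pooling leaves no output positions")
            lengths.append(L)
        return lengths

    def flat_features(self) -> int:
        return self.conv_lengths()[-1] * self.conv_filters[-1]

    def __post_init__(self):
        if len(self.conv_filters) != len(self.conv_kernels):
            raise ValueError("one kernel length per conv layer required")
        if not 0 < self.dropout_keep <= 1:
            raise ValueError("dropout keep-probability must be in (0, 1]")
        self.conv_lengths()  # validate arithmetic eagerly


@dataclass
class TrainingConfig:
    """Optimization settings; loss is mean absolute deviation (hours)."""

    learning_rate: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("validation fraction must be in (0, 1)")


@dataclass
class PhasePrediction:
    """CNN estimate for one curve, clipped to the grid span (ZT hours)."""

    curve_id: str
    onset: float
    peak: float


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, L, C) -> (B, L-k+1, k*C) sliding windows for valid convolution."""
    b, L, c = x.shape
    lo = L - k + 1
    cols = np.empty((b, lo, k, c), dtype=x.dtype)
    for j in range(k):
        cols[:, :, j, :] = x[:, j:j + lo, :]
    return cols.reshape(b, lo, k * c)


def _col2im(dcols: np.ndarray, L: int, k: int, c: int) -> np.ndarray:
    b, lo, _ = dcols.shape
    d = dcols.reshape(b, lo, k, c)
    dx = np.zeros((b, L, c), dtype=dcols.dtype)
    for j in range(k):
        dx[:, j:j + lo, :] += d[:, :, j, :]
    return dx


class PhaseNet:
    """The phase-regression CNN with explicit forward/backward passes."""

    def __init__(self, spec: NetworkSpec = NetworkSpec(), seed: int = 0,
                 dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        c_in = 1
        for i, (f, k) in enumerate(zip(spec.conv_filters, spec.conv_kernels)):
            fan_in = k * c_in
            p[f"c{i}W"] = (rng.standard_normal((fan_in, f)) *
                           np.sqrt(2.0 / fan_in)).astype(dtype)
            p[f"c{i}b"] = np.zeros(f, dtype=dtype)
            c_in = f
        n_in = spec.flat_features()
        for i, units in enumerate(spec.fc_units):
            p[f"f{i}W"] = (rng.standard_normal((n_in, units)) *
                           np.sqrt(2.0 / n_in)).astype(dtype)
            p[f"f{i}b"] = np.zeros(units, dtype=dtype)
            n_in = units
        p["oW"] = (rng.standard_normal((n_in, spec.n_outputs)) *
                   np.sqrt(1.0 / n_in)).astype(dtype)
        p["ob"] = np.zeros(spec.n_outputs, dtype=dtype)
        self.params = p

    # -- forward -----------------------------------------------------------

    def forward(self, X: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None):
        """Return (predictions (B, 2), cache for backprop)."""
        spec = self.spec
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != spec.input_len:
            raise ValueError(
                f"expected curves of length {spec.input_len}, got {X.shape[1]}"
            )
        cache: dict = {"input_shape": X.shape}
        a = X[:, :, None]  # (B, L, 1)
        for i, k in enumerate(spec.conv_kernels):
            cols = _im2col(a, k)
            z = cols @ self.params[f"c{i}W"] + self.params[f"c{i}b"]
            cache[f"c{i}cols"] = cols
            cache[f"c{i}mask"] = z > 0
            cache[f"c{i}in_len"] = a.shape[1]
            cache[f"c{i}in_ch"] = a.shape[2]
            a = np.maximum(z, 0)
        for i in range(spec.n_pool):
            b, L, c = a.shape
            lo = L // spec.pool_window
            trimmed = a[:, : lo * spec.pool_window, :]
            windows = trimmed.reshape(b, lo, spec.pool_window, c)
            arg = windows.argmax(axis=2)
            cache[f"p{i}arg"] = arg
            cache[f"p{i}in_len"] = L
            a = np.take_along_axis(windows, arg[:, :, None, :], axis=2)[:, :, 0, :]
        flat = a.reshape(a.shape[0], -1)
        cache["flat_shape"] = a.shape
        h = flat
        for i in range(len(spec.fc_units)):
            z = h @ self.params[f"f{i}W"] + self.params[f"f{i}b"]
            cache[f"f{i}in"] = h
            cache[f"f{i}mask"] = z > 0
            h = np.maximum(z, 0)
            if i == 0 and train and spec.dropout_keep < 1:
                if dropout_rng is None:
                    dropout_rng = np.random.default_rng()
                keep = spec.dropout_keep
                mask = (dropout_rng.random(h.shape) < keep).astype(self.dtype) / keep
                cache["drop"] = mask
                h = h * mask
        cache["o_in"] = h
        out = h @ self.params["oW"] + self.params["ob"]
        return out, cache

    def predict(self, X: np.ndarray, clip: tuple[float, float] = GRID_SPAN) -> np.ndarray:
        out, _ = self.forward(X, train=False)
        return np.clip(out.astype(float), clip[0], clip[1])

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       dropout_rng: np.random.Generator | None = None):
        """Mean-absolute-deviation loss and gradients for one batch."""
        spec = self.spec
        y = np.asarray(y, dtype=self.dtype)
        out, cache = self.forward(X, train=True, dropout_rng=dropout_rng)
        diff = out - y
        loss = float(np.mean(np.abs(diff)))
        grads: dict[str, np.ndarray] = {}

        dout = (np.sign(diff) / diff.size).astype(self.dtype)
        h = cache["o_in"]
        grads["oW"] = h.T @ dout
        grads["ob"] = dout.sum(axis=0)
        dh = dout @ self.params["oW"].T
        for i in reversed(range(len(spec.fc_units))):
            if i == 0 and "drop" in cache:
                dh = dh * cache["drop"]
            dz = dh * cache[f"f{i}mask"]
            grads[f"f{i}W"] = cache[f"f{i}in"].T @ dz
            grads[f"f{i}b"] = dz.sum(axis=0)
            dh = dz @ self.params[f"f{i}W"].T
        da = dh.reshape(cache["flat_shape"])
        for i in reversed(range(spec.n_pool)):
            L = cache[f"p{i}in_len"]
            arg = cache[f"p{i}arg"]
            b, lo, c = da.shape
            dwin = np.zeros((b, lo, spec.pool_window, c), dtype=self.dtype)
            np.put_along_axis(dwin, arg[:, :, None, :], da[:, :, None, :], axis=2)
            dtrim = dwin.reshape(b, lo * spec.pool_window, c)
            if lo * spec.pool_window < L:
                pad = np.zeros((b, L - lo * spec.pool_window, c), dtype=self.dtype)
                da = np.concatenate([dtrim, pad], axis=1)
            else:
                da = dtrim
        for i in reversed(range(len(spec.conv_kernels))):
            dz = da * cache[f"c{i}mask"]
            cols = cache[f"c{i}cols"]
            b, lo, kc = cols.shape
            grads[f"c{i}W"] = cols.reshape(-1, kc).T @ dz.reshape(-1, dz.shape[-1])
            grads[f"c{i}b"] = dz.sum(axis=(0, 1))
            dcols = dz @ self.params[f"c{i}W"].T
            da = _col2im(dcols, cache[f"c{i}in_len"], spec.conv_kernels[i],
                         cache[f"c{i}in_ch"])
        return loss, grads

    # -- persistence -------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=self.dtype)


class Adam:
    """Adam optimizer (beta1 = 0.9, beta2 = 0.999, eps = 1e-8)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            params[k] -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                params[k].dtype
            )


def build_network(spec: NetworkSpec = NetworkSpec(), rng_seed: int = 0,
                  dtype=np.float32) -> PhaseNet:
    """Deterministically initialized network (He init, seeded)."""
    return PhaseNet(spec, seed=rng_seed, dtype=dtype)


def _epoch_mae(model: PhaseNet, X: np.ndarray, y: np.ndarray,
               batch: int = 1024) -> np.ndarray:
    """Per-target MAE without dropout, batched to bound memory."""
    errs = np.zeros(2)
    for i in range(0, len(X), batch):
        out, _ = model.forward(X[i:i + batch], train=False)
        errs += np.abs(out - y[i:i + batch]).sum(axis=0)
    return errs / len(X)


def train_model(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainingConfig = TrainingConfig(),
    spec: NetworkSpec = NetworkSpec(),
    model: PhaseNet | None = None,
    verbose: bool = False,
):
    """Train on labelled curves; returns (model, history).

    X: n x 25 normalized curves; y: n x 2 labels (onset, peak) in ZT hours.
    The data are split 1 - val_fraction / val_fraction; training stops
    early when validation MAE has not improved for `patience` epochs and
    the best-validation weights are restored.  The output bias starts at
    the training-label mean so the regression heads begin unbiased.
    """
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if len(X) == 0:
        raise ValueError("empty training set")
    if len(X) != len(y):
        raise ValueError("curves and labels must align")

    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(cfg.val_fraction * len(X))))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        train_idx = val_idx
    Xt, yt = X[train_idx], y[train_idx]
    Xv, yv = X[val_idx], y[val_idx]

    if model is None:
        model = build_network(spec, rng_seed=cfg.seed)
    model.params["ob"] = yt.mean(axis=0).astype(model.dtype)
    opt = Adam(model.params, lr=cfg.learning_rate)
    drop_rng = np.random.default_rng(cfg.seed + 1)

    history = {"train_loss": [], "val_mae_onset": [], "val_mae_peak": []}
    best = {"val": np.inf, "state": model.state_dict(), "epoch": -1}

    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(Xt))
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, len(Xt), cfg.batch_size):
            sel = perm[i:i + cfg.batch_size]
            loss, grads = model.loss_and_grads(Xt[sel], yt[sel], dropout_rng=drop_rng)
            if not np.isfinite(loss):
                model.load_state_dict(best["state"])
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}", model=model, history=history
                )
            opt.step(model.params, grads)
            epoch_loss += loss
            n_batches += 1
        val_mae = _epoch_mae(model, Xv, yv)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_mae_onset"].append(float(val_mae[0]))
        history["val_mae_peak"].append(float(val_mae[1]))
        score = float(val_mae.mean())
        if verbose:
            print(f"epoch {epoch:3d}  train {history['train_loss'][-1]:.4f}  "
                  f"val onset {val_mae[0]:.4f}  val peak {val_mae[1]:.4f}")
        if score < best["val"] - 1e-6:
            best = {"val": score, "state": model.state_dict(), "epoch": epoch}
        elif epoch - best["epoch"] >= cfg.patience:
            break
    model.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    return model, history


def predict_phases(model: PhaseNet, curves: np.ndarray,
                   curve_ids: list[str] | None = None) -> list[PhasePrediction]:
    """One clipped (onset, peak) prediction per normalized 25-point curve."""
    curves = np.atleast_2d(np.asarray(curves, dtype=np.float32))
    out = model.predict(curves)
    if curve_ids is None:
        curve_ids = [str(i) for i in range(len(curves))]
    if len(curve_ids) != len(curves):
        raise ValueError("one id per curve required")
    return [
        PhasePrediction(curve_id=cid, onset=float(o), peak=float(p))
        for cid, (o, p) in zip(curve_ids, out)
    ]


def error_summary(pred: np.ndarray, labels: np.ndarray) -> dict:
    """Per-target MAE, bias (mean signed error) and error s.d."""
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels, dtype=float)
    err = pred - labels
    out = {}
    for j, name in enumerate(("onset", "peak")):
        e = err[:, j]
        out[name] = {
            "mae": float(np.mean(np.abs(e))),
            "bias": float(np.mean(e)),
            "sd": float(np.std(e, ddof=1)) if len(e) > 1 else 0.0,
        }
    out["errors"] = err
    return out


def evaluate_model(model: PhaseNet, X: np.ndarray, y: np.ndarray) -> dict:
    """Error summaries of a model on a labelled set (exposes error vectors)."""
    return error_summary(model.predict(np.asarray(X, dtype=np.float32)), y)


def save_model(model: PhaseNet, path, cfg: TrainingConfig | None = None,
               **meta) -> None:
    """Weights to `<path>` (.npz) plus a JSON sidecar `<path>.json`."""
    path = Path(path)
    np.savez_compressed(path, **model.params)
    sidecar = {
        "spec": asdict(model.spec),
        "training": asdict(cfg) if cfg is not None else None,
        **meta,
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=str)
    )


def load_model(path) -> PhaseNet:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    spec = NetworkSpec()
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        if raw.get("spec"):
            s = raw["spec"]
            for key in ("conv_filters", "conv_kernels", "fc_units"):
                if key in s:
                    s[key] = tuple(s[key])
            spec = NetworkSpec(**s)
    model = PhaseNet(spec, seed=0)
    with np.load(path) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model
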
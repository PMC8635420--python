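"""Neural factorization machine (NFM).

The NFM scores an n-dimensional instance x as

    y_hat(x) = w0 + sum_i w_i x_i + p^T z_L,

where z_L is the output of a stack of fully connected layers applied to the
Bi-Interaction pooling of the scaled feature embeddings

    f_BI(V_x) = sum_{i<j} (x_i v_i) (*) (x_j v_j)          ((*) elementwise),

computed via the O(nk) identity 0.5 * [ (sum_i x_i v_i)^2 - sum_i (x_i v_i)^2 ].
The model therefore combines the linearity of a factorization machine with
the non-linearity of a neural network on the pairwise interaction summary.

Classification uses a logistic link on y_hat with binary cross-entropy.
Training is Adam over seeded mini-batches with inverted dropout after the
Bi-Interaction layer; identical config + seed gives identical parameters.
Forward/backward passes are plain numpy; a finite-difference gradient check
in the test suite guards the backprop.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import (
    DimensionError,
    TrainingDivergedError,
    TrainingSetupError,
)

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, a: (z > 0).astype(float)),
    "tanh": (np.tanh, lambda z, a: 1.0 - a * a),
    "identity": (lambda z: z, lambda z, a: np.ones_like(z)),
}


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


@dataclass
class FieldSpec:
    """Named contiguous blocks of an instance vector (offsets into x)."""

    blocks: list[tuple[str, int]]  # (name, width) in order

    @property
    def width(self) -> int:
        return sum(w for _, w in self.blocks)

    def offsets(self) -> dict[str, tuple[int, int]]:
        out, pos = {}, 0
        for name, w in self.blocks:
            out[name] = (pos, pos + w)
            pos += w
        return out


@dataclass
class InstanceVector:
    """A per-pair input vector with named field boundaries."""

    values: np.ndarray
    field_spec: FieldSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (self.field_spec.width,):
            raise DimensionError(
                f"instance has length {self.values.shape}, field spec wants {self.field_spec.width}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite instance values")


def embed_features(x: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Scaled feature embeddings V_x = {x_1 v_1, ..., x_n v_n} as an (n, k) array."""
    x = np.asarray(x, float)
    V = np.asarray(V, float)
    if V.ndim != 2 or V.shape[0] != x.shape[0]:
        raise DimensionError(f"V has shape {V.shape}, x has length {x.shape}")
    return x[:, None] * V


def bi_interaction(V_x: np.ndarray) -> np.ndarray:
    """Bi-Interaction pooling: sum of elementwise products over all pairs.

    Computed as 0.5 * [(sum_i u_i)^2 - sum_i u_i^2] with u_i the scaled
    embeddings, which is O(nk) instead of the O(n^2 k) double sum.
    """
    V_x = np.asarray(V_x, float)
    if V_x.ndim != 2 or V_x.shape[0] == 0:
        raise ValueError("bi_interaction needs a nonempty (n, k) array")
    s = V_x.sum(axis=0)
    return 0.5 * (s * s - (V_x * V_x).sum(axis=0))


@dataclass
class NFMParams:
    """All NFM parameters: w0, w, V, hidden stack (W_l, b_l, sigma_l), p."""

    w0: float
    w: np.ndarray            # (n,)
    V: np.ndarray            # (n, k)
    layers: list[tuple[np.ndarray, np.ndarray, str]]  # (W_l, b_l, activation)
    p: np.ndarray            # (width of z_L,)
    field_spec: FieldSpec | None = None

    def __post_init__(self) -> None:
        width = self.V.shape[1]
        for i, (W, b, act) in enumerate(self.layers):
            if W.shape[1] != width or b.shape != (W.shape[0],):
                raise DimensionError(f"layer {i} shapes do not chain (W {W.shape}, b {b.shape})")
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")
            width = W.shape[0]
        if self.p.shape != (width,):
            raise DimensionError(f"prediction weights have shape {self.p.shape}, want ({width},)")

    @property
    def n_features(self) -> int:
        return self.V.shape[0]

    def flat(self) -> list[np.ndarray]:
        out = [np.array([self.w0]), self.w, self.V]
        for W, b, _ in self.layers:
            out.extend([W, b])
        out.append(self.p)
        return out


def init_nfm(
    n: int,
    k: int = 64,
    hidden: tuple[int, ...] = (64,),
    activation: str = "relu",
    seed: int = 0,
    field_spec: FieldSpec | None = None,
) -> NFMParams:
    """Seeded Glorot-style initialization; linear part starts at zero."""
    rng = np.random.default_rng(seed)
    V = rng.normal(0.0, 1.0 / np.sqrt(k), size=(n, k))
    layers = []
    width = k
    for h in hidden:
        limit = np.sqrt(6.0 / (width + h))
        layers.append((rng.uniform(-limit, limit, (h, width)), np.zeros(h), activation))
        width = h
    p = rng.normal(0.0, 1.0 / np.sqrt(width), size=width)
    return NFMParams(w0=0.0, w=np.zeros(n), V=V, layers=layers, p=p, field_spec=field_spec)


def nfm_forward(
    x: np.ndarray | InstanceVector, params: NFMParams
) -> tuple[float, float]:
    """Raw score y_hat and logistic probability for a single instance."""
    if isinstance(x, InstanceVector):
        x = x.values
    scores = _forward_batch(np.asarray(x, float)[None, :], params)[0]
    return float(scores[0]), float(_sigmoid(scores)[0])


def _forward_batch(
    X: np.ndarray, params: NFMParams, dropout_mask: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Vectorized forward pass; returns raw scores and a cache for backprop."""
    if X.shape[1] != params.n_features:
        raise DimensionError(f"instances have width {X.shape[1]}, model wants {params.n_features}")
    V = params.V
    s1 = X @ V                       # sum_i x_i v_i
    s2 = (X * X) @ (V * V)           # sum_i (x_i v_i)^2
    z = 0.5 * (s1 * s1 - s2)
    cache: dict = {"X": X, "s1": s1, "z0": z, "acts": []}
    if dropout_mask is not None:
        z = z * dropout_mask
    cache["z_in"] = z
    a = z
    for W, b, act in params.layers:
        pre = a @ W.T + b
        a_new = _ACTIVATIONS[act][0](pre)
        cache["acts"].append((a, pre, a_new))
        a = a_new
    if not np.all(np.isfinite(a)):
        bad = next(
            (i for i, (_, pre, out) in enumerate(cache["acts"]) if not np.all(np.isfinite(out))),
            "bi-interaction",
        )
        raise TrainingDivergedError(f"non-finite activation at layer {bad!r}")
    cache["zL"] = a
    scores = params.w0 + X @ params.w + a @ params.p
    return scores, cache


def _backward_batch(
    params: NFMParams, cache: dict, dscore: np.ndarray, dropout_mask: np.ndarray | None
) -> list[np.ndarray]:
    """Gradients in the order of :meth:`NFMParams.flat` given d loss / d score."""
    X, s1, zL = cache["X"], cache["s1"], cache["zL"]
    gw0 = np.array([dscore.sum()])
    gw = X.T @ dscore
    gp = zL.T @ dscore
    # back through the hidden stack
    ga = dscore[:, None] * params.p[None, :]
    glayers: list[tuple[np.ndarray, np.ndarray]] = []
    for (W, b, act), (a_in, pre, a_out) in zip(reversed(params.layers), reversed(cache["acts"])):
        gpre = ga * _ACTIVATIONS[act][1](pre, a_out)
        glayers.append((gpre.T @ a_in, gpre.sum(axis=0)))
        ga = gpre @ W
    glayers.reverse()
    # through dropout into the bi-interaction output
    gz0 = ga * dropout_mask if dropout_mask is not None else ga
    # z0 = 0.5*(s1^2 - (X^2)(V^2)):  dV = X^T(gz0*s1) - ((X^2)^T gz0) * V
    gV = X.T @ (gz0 * s1) - ((X * X).T @ gz0) * params.V
    grads = [gw0, gw, gV]
    for gW, gb in glayers:
        grads.extend([gW, gb])
    grads.append(gp)
    return grads


def nfm_loss_and_grads(
    params: NFMParams,
    X: np.ndarray,
    y: np.ndarray,
    l2: float = 0.0,
    dropout_mask: np.ndarray | None = None,
) -> tuple[float, list[np.ndarray]]:
    """Mean binary cross-entropy and gradients w.r.t. all parameters."""
    scores, cache = _forward_batch(X, params, dropout_mask)
    p = _sigmoid(scores)
    loss = float(np.mean(np.logaddexp(0.0, -scores) + (1 - y) * scores))
    dscore = (p - y) / len(y)
    grads = _backward_batch(params, cache, dscore, dropout_mask)
    if l2 > 0.0:
        flat = params.flat()
        loss += l2 * sum(float(np.sum(f * f)) for f in flat[1:])  # bias excluded
        for g, f in zip(grads[1:], flat[1:]):
            g += 2.0 * l2 * f
    return loss, grads


@dataclass
class NFMTrainConfig:
    k: int = 64
    hidden: tuple[int, ...] = (64,)
    activation: str = "relu"
    epochs: int = 30
    learning_rate: float = 0.01
    batch_size: int = 256
    dropout: float = 0.2
    l2: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1 or self.epochs < 0 or self.learning_rate <= 0 or not 0 <= self.dropout < 1:
            raise ValueError(f"invalid NFM config: {self}")


def train_nfm(
    X: np.ndarray,
    y: np.ndarray,
    cfg: NFMTrainConfig,
    field_spec: FieldSpec | None = None,
    loss_history: list[float] | None = None,
) -> NFMParams:
    """Fit an NFM by Adam on binary cross-entropy.

    Requires both classes present; epochs = 0 returns the seeded
    initialization unchanged.  Dropout (inverted, rate ``cfg.dropout``) is
    applied to the Bi-Interaction output during training only.
    """
    from .kge import _Adam  # shared optimizer

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.ndim != 2 or len(X) != len(y):
        raise DimensionError(f"X {X.shape} and y {y.shape} do not align")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        raise TrainingSetupError(f"need both classes among labels, got {classes}")
    params = init_nfm(X.shape[1], cfg.k, cfg.hidden, cfg.activation, cfg.seed, field_spec)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    flat = params.flat()
    opt = _Adam([f.shape for f in flat], cfg.learning_rate)
    n = len(X)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            mask = None
            if cfg.dropout > 0:
                keep = rng.random((len(idx), cfg.k)) >= cfg.dropout
                mask = keep / (1.0 - cfg.dropout)
            loss, grads = nfm_loss_and_grads(params, X[idx], y[idx], cfg.l2, mask)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            opt.step(flat, grads)
            params.w0 = float(flat[0][0])
            total += loss * len(idx)
        if loss_history is not None:
            loss_history.append(total / n)
    return params


def predict_proba(params: NFMParams, X: np.ndarray) -> np.ndarray:
    """Probabilities for a batch of instances (no dropout)."""
    scores, _ = _forward_batch(np.asarray(X, float), params)
    return _sigmoid(scores)


def save_nfm(params: NFMParams, path: str | Path, seed: int | None = None) -> None:
    """Serialize to a zip archive with a JSON manifest; byte-deterministic."""
    arrays: dict[str, np.ndarray] = {"w": params.w, "V": params.V, "p": params.p}
    manifest = {
        "w0": params.w0,
        "layers": [],
        "seed": seed,
        "field_spec": params.field_spec.blocks if params.field_spec else None,
    }
    for i, (W, b, act) in enumerate(params.layers):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
        manifest["layers"].append(act)
    _write_archive(path, manifest, arrays)


def load_nfm(path: str | Path) -> NFMParams:
    manifest, arrays = _read_archive(path)
    layers = [
        (arrays[f"W{i}"], arrays[f"b{i}"], act)
        for i, act in enumerate(manifest["layers"])
    ]
    fs = manifest.get("field_spec")
    return NFMParams(
        w0=manifest["w0"],
        w=arrays["w"],
        V=arrays["V"],
        layers=layers,
        p=arrays["p"],
        field_spec=FieldSpec([tuple(b) for b in fs]) if fs else None,
    )


def _write_archive(path: str | Path, manifest: dict, arrays: dict[str, np.ndarray]) -> None:
    """Zip writer with pinned timestamps so identical content is identical bytes."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        info = zipfile.ZipInfo("manifest.json", date_time=(1980, 1, 1, 0, 0, 0))
        zf.writestr(info, json.dumps(manifest, sort_keys=True, indent=1))
        for name in sorted(arrays):
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arrays[name]))
            info = zipfile.ZipInfo(f"{name}.npy", date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, buf.getvalue())


def _read_archive(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    arrays: dict[str, np.ndarray] = {}
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        for name in zf.namelist():
            if name.endswith(".npy"):
                arrays[name[:-4]] = np.load(io.BytesIO(zf.read(name)))
    return manifest, arrays
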
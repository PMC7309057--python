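"""Area-normalised bird counting with a small BP regression network.

Counting is anchored on a per-day *reference area* ``s`` — the mean
top-view pixel area of a single bird on that day.  Because broilers
roughly triple their silhouette between d18 and d35, every day's frames
are normalised by that day's own reference; a region of raw area
``s_i`` becomes the dimensionless ``s_bar_i = s_i / s``.

Normalised areas are mapped to integer bird counts either by plain
rounding (the arithmetic fallback, ``round(s_i / s)``) or — the primary
path — by a 1-input feedforward network trained by backpropagation on
(normalised area, true count) pairs.  The network absorbs the
systematic area loss of touching birds (a merged pair covers less than
twice a single silhouette), which plain rounding cannot.

Training uses a seeded 0.70 / 0.15 / 0.15 train / validation / test
split, full-batch Adam on the squared error, and early stopping on the
validation loss (patience 20, max 500 epochs).  Models serialise to a
JSON document (architecture + weights + training metadata).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from broilervision.util import round_half_away


class CountingError(ValueError):
    pass


class TrainingDivergence(RuntimeError):
    pass


@dataclass(frozen=True)
class ReferenceArea:
    """Mean single-bird area for one rearing day."""

    day: int
    s: float
    n_samples: int
    sd: float

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise CountingError(f"reference area must be positive, got {self.s}")
        if self.n_samples < 1:
            raise CountingError("reference area needs at least one sample")


@dataclass(frozen=True)
class AreaRecord:
    region_id: int
    s_i: float
    s_bar_i: float
    flagged: bool = False


def estimate_reference_area(
    single_bird_areas: Sequence[float], day: int
) -> ReferenceArea:
    """Arithmetic mean (and sd) of manually/synthetically selected
    single-bird areas for one day."""
    areas = np.asarray(single_bird_areas, dtype=np.float64)
    if areas.size == 0:
        raise CountingError("no single-bird areas supplied")
    if (areas <= 0).any():
        raise CountingError("single-bird areas must all be positive")
    sd = float(areas.std(ddof=1)) if areas.size > 1 else 0.0
    return ReferenceArea(day=day, s=float(areas.mean()), n_samples=int(areas.size), sd=sd)


def normalize_area(s_i: float, ref: ReferenceArea, region_id: int = 0) -> AreaRecord:
    """``s_bar_i = s_i / s``; non-positive inputs are flagged, not raised."""
    if s_i <= 0:
        return AreaRecord(region_id=region_id, s_i=s_i, s_bar_i=0.0, flagged=True)
    return AreaRecord(region_id=region_id, s_i=s_i, s_bar_i=s_i / ref.s)


# ---------------------------------------------------------------------------
# BP network


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


@dataclass
class BPModel:
    """1-input feedforward regression network (sigmoid hidden, linear out)."""

    hidden_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    input_scale: float = 1.0
    training_meta: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray | float) -> np.ndarray:
        a = np.atleast_1d(np.asarray(x, dtype=np.float64)).reshape(-1, 1)
        a = a / self.input_scale
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _sigmoid(a @ w + b)
        out = a @ self.weights[-1] + self.biases[-1]
        return out.ravel()

    def predict_count(self, s_bar: float) -> int:
        return round_half_away(float(self.predict(s_bar)[0]))

    # -- serialisation ----------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "architecture": {
                "input_dim": 1,
                "hidden_sizes": list(self.hidden_sizes),
                "activation": "sigmoid",
                "output": "linear",
            },
            "input_scale": self.input_scale,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "training_meta": self.training_meta,
        }
        return json.dumps(doc, indent=2)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "BPModel":
        doc = json.loads(text)
        return cls(
            hidden_sizes=tuple(doc["architecture"]["hidden_sizes"]),
            weights=[np.asarray(w, dtype=np.float64) for w in doc["weights"]],
            biases=[np.asarray(b, dtype=np.float64) for b in doc["biases"]],
            input_scale=float(doc.get("input_scale", 1.0)),
            training_meta=doc.get("training_meta", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "BPModel":
        return cls.from_json(Path(path).read_text())


def _init_layers(
    sizes: Sequence[int], rng: np.random.Generator
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        limit = math.sqrt(6.0 / (n_in + n_out))
        weights.append(rng.uniform(-limit, limit, size=(n_in, n_out)))
        biases.append(np.zeros((1, n_out)))
    return weights, biases


def split_indices(
    n: int, seed: int, ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seeded shuffle split into train / validation / test index arrays."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def train_bp(
    pairs: Sequence[tuple[float, float]],
    hidden_sizes: Sequence[int] = (10,),
    seed: int = 0,
    epochs: int = 500,
    patience: int = 20,
    restarts: int = 5,
):
    """Train the BP counting network on (normalised area, count) pairs.

    Returns ``(model, fit)`` where ``fit`` holds R / MSE / MAE on the
    held-out 15% test split.  Deterministic under ``seed`` (which drives
    the split shuffle and the weight initialisation of each of the
    ``restarts`` seeded runs).
    """
    from broilervision.evaluation import FitSeries, fit_metrics

    if len(pairs) < 30:
        raise CountingError(
            f"need at least 30 (area, count) pairs to train, got {len(pairs)}"
        )
    arr = np.asarray(pairs, dtype=np.float64)
    x, y = arr[:, 0], arr[:, 1]
    if (y <= 0).any() or (np.rint(y) != y).any():
        raise CountingError("true counts must be positive integers")

    idx_train, idx_val, idx_test = split_indices(len(x), seed)
    scale = max(float(np.abs(x[idx_train]).max()), 1e-9)
    xt, yt = x[idx_train] / scale, y[idx_train]
    xv, yv = x[idx_val] / scale, y[idx_val]

    sizes = [1, *hidden_sizes, 1]
    weights, biases = _init_layers(sizes, np.random.default_rng(seed))
    shapes = [w.shape for w in weights] + [b.shape for b in biases]

    def pack(ws, bs):
        return np.concatenate([a.ravel() for a in (*ws, *bs)])

    def unpack(theta):
        out, pos = [], 0
        for shp in shapes:
            size = int(np.prod(shp))
            out.append(theta[pos : pos + size].reshape(shp))
            pos += size
        k = len(weights)
        return out[:k], out[k:]

    def forward(ws, bs, xs: np.ndarray):
        acts = [xs.reshape(-1, 1)]
        for li, (w, b) in enumerate(zip(ws, bs)):
            z = acts[-1] @ w + b
            acts.append(z if li == len(ws) - 1 else _sigmoid(z))
        return acts

    def residuals(theta):
        ws, bs = unpack(theta)
        res = (forward(ws, bs, xt)[-1].ravel() - yt)
        if not np.all(np.isfinite(res)):
            raise TrainingDivergence("non-finite training residuals")
        return res

    def jacobian(theta):
        # per-sample gradient of the network output w.r.t. every parameter
        ws, bs = unpack(theta)
        acts = forward(ws, bs, xt)
        n = len(xt)
        delta = np.ones((n, 1))
        cols_w = [None] * len(ws)
        cols_b = [None] * len(ws)
        for li in range(len(ws) - 1, -1, -1):
            # d out / d W_li = a_li (outer) delta ; d out / d b_li = delta
            cols_w[li] = (acts[li][:, :, None] * delta[:, None, :]).reshape(n, -1)
            cols_b[li] = delta.copy()
            if li > 0:
                a_prev = acts[li]
                delta = (delta @ ws[li].T) * a_prev * (1.0 - a_prev)
        return np.hstack(cols_w + cols_b)

    def val_loss(theta) -> float:
        ws, bs = unpack(theta)
        pred = forward(ws, bs, xv)[-1].ravel()
        return float(np.mean((pred - yv) ** 2))

    # Levenberg-Marquardt epochs with validation-based early stopping:
    # every `patience` accepted steps the validation error must have
    # improved, else the run stops and its best weights are restored.
    # Several seeded restarts guard against the occasional stall in a
    # smooth local optimum; the restart with the lowest validation
    # error wins.  The damped Gauss-Newton loop is written out in numpy
    # so that training is bit-reproducible under a fixed seed.
    def one_run(run_seed: int):
        ws, bs = _init_layers(sizes, np.random.default_rng(run_seed))
        theta = pack(ws, bs)
        res = residuals(theta)
        cost = float(res @ res)
        lam = 1e-3
        best_vl = val_loss(theta)
        best_theta = theta.copy()
        stale = 0
        for _epoch in range(epochs):
            jac = jacobian(theta)
            a_mat = jac.T @ jac
            grad = jac.T @ res
            diag = np.maximum(np.diag(a_mat), 1e-12)
            accepted = False
            for _try in range(40):
                try:
                    step = np.linalg.solve(
                        a_mat + lam * np.diag(diag), -grad
                    )
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = theta + step
                res_cand = residuals(cand)
                cost_cand = float(res_cand @ res_cand)
                if cost_cand < cost:
                    theta, res, cost = cand, res_cand, cost_cand
                    lam = max(lam * 0.3, 1e-12)
                    accepted = True
                    break
                lam *= 3.0
            if not accepted:
                break
            vl = val_loss(theta)
            if vl < best_vl * (1.0 - 1e-9):
                best_vl = vl
                best_theta = theta.copy()
                stale = 0
            else:
                stale += 1
                if stale > patience:
                    break
        return best_vl, best_theta, _epoch + 1

    runs = [one_run(seed + r) for r in range(max(restarts, 1))]
    best_vl, best_theta, _ = min(runs, key=lambda t: t[0])
    nfev_total = sum(r[2] for r in runs)
    weights, biases = unpack(best_theta)
    model = BPModel(
        hidden_sizes=tuple(hidden_sizes),
        weights=weights,
        biases=biases,
        input_scale=scale,
        training_meta={
            "split_ratios": [0.70, 0.15, 0.15],
            "seed": seed,
            "restarts": max(restarts, 1),
            "epochs_run": nfev_total,
            "patience": patience,
            "n_pairs": len(x),
            "best_val_mse": best_vl,
        },
    )
    y_hat_test = model.predict(x[idx_test])
    fit = fit_metrics(FitSeries(y=y[idx_test], y_hat=y_hat_test))
    return model, fit


def count_region(region, ref: ReferenceArea, model: BPModel | None = None) -> int:
    """Bird count for one region: BP model if given, else plain rounding.

    Any region that survived the min-area filter represents at least one
    bird, so counts are clamped to >= 1.
    """
    area = float(region.area) if hasattr(region, "area") else float(region)
    record = normalize_area(area, ref)
    if model is not None:
        count = model.predict_count(record.s_bar_i)
    else:
        count = round_half_away(record.s_bar_i)
    return max(count, 1)


def write_pairs_csv(pairs: Sequence[tuple[float, int]], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(pairs, columns=["area", "count"]).to_csv(path, index=False)


def read_pairs_csv(path: str | Path) -> list[tuple[float, int]]:
    import pandas as pd

    df = pd.read_csv(path)
    return [(float(a), int(c)) for a, c in zip(df["area"], df["count"])]
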
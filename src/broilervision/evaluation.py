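"""Detection-rate and model-fit metrics.

Zone detection is scored with three rates, each normalised by the true
number of birds in the zone over the evaluation set:

* accuracy  ``R_accuracy = T_num / T_truenum``
* missed    ``R_miss     = T_miss / T_truenum``
* false     ``R_false    = T_false / T_truenum``

Missed detections carry a cause breakdown (crowding / occlusion /
others).  The tallies satisfy the bookkeeping identity
``T_num = T_truenum - T_miss + T_false``, which is asserted on every
synthetic evaluation run.

Model fit is scored with three criteria: R defined as
``1 - SS_res / SS_tot`` (the coefficient-of-determination form; a plain
Pearson correlation is exposed separately as ``pearson_r``),
``MSE = sum((y - y_hat)^2) / n``, and
``MAE = (1/n) * sum(|y - y_hat| / y)`` — note the division by ``y_i``:
despite its name this is a *relative* error, and it is undefined when
any ``y_i`` is zero.

Reported rates are rounded half-away-from-zero to 4 decimals; the raw
ratios are retained alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from broilervision import zones as zmod
from broilervision.util import round_decimals_half_away

MISS_CAUSES = ("crowding", "occlusion", "others")


class EvaluationError(ValueError):
    pass


@dataclass
class DetectionTally:
    """Accumulated detection bookkeeping for one zone."""

    zone: str
    t_truenum: int
    t_num: int
    miss_crowding: int = 0
    miss_occlusion: int = 0
    miss_others: int = 0
    t_false: int = 0

    def __post_init__(self) -> None:
        for name in (
            "t_truenum",
            "t_num",
            "miss_crowding",
            "miss_occlusion",
            "miss_others",
            "t_false",
        ):
            if getattr(self, name) < 0:
                raise EvaluationError(f"{name} must be >= 0")

    @property
    def t_miss(self) -> int:
        return self.miss_crowding + self.miss_occlusion + self.miss_others

    def consistent(self) -> bool:
        """T_num = T_truenum - T_miss + T_false."""
        return self.t_num == self.t_truenum - self.t_miss + self.t_false


@dataclass(frozen=True)
class DetectionMetrics:
    r_accuracy: float
    r_miss: float
    r_false: float
    raw: tuple[float, float, float] = (0.0, 0.0, 0.0)


def detection_metrics(tally: DetectionTally) -> DetectionMetrics:
    """Accuracy / missed / false rates from a zone tally (4-decimal report)."""
    if tally.t_truenum <= 0:
        raise EvaluationError(
            f"detection rates are undefined for zone {tally.zone!r}: T_truenum=0"
        )
    raw = (
        tally.t_num / tally.t_truenum,
        tally.t_miss / tally.t_truenum,
        tally.t_false / tally.t_truenum,
    )
    return DetectionMetrics(
        r_accuracy=round_decimals_half_away(raw[0], 4),
        r_miss=round_decimals_half_away(raw[1], 4),
        r_false=round_decimals_half_away(raw[2], 4),
        raw=raw,
    )


@dataclass
class FitSeries:
    y: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        self.y_hat = np.asarray(self.y_hat, dtype=np.float64)
        if self.y.shape != self.y_hat.shape or self.y.ndim != 1:
            raise EvaluationError("y and y_hat must be 1-D arrays of equal length")
        if self.y.size < 1:
            raise EvaluationError("empty fit series")

    @property
    def y_bar(self) -> float:
        return float(self.y.mean())


@dataclass(frozen=True)
class FitMetrics:
    r: float
    mse: float
    mae: float


def fit_metrics(series: FitSeries) -> FitMetrics:
    """R (1 - SS_res/SS_tot), MSE, and relative MAE for a fitted series."""
    y, y_hat = series.y, series.y_hat
    if y.size < 2:
        raise EvaluationError("fit metrics need at least 2 samples")
    ss_res = float(((y - y_hat) ** 2).sum())
    ss_tot = float(((y - series.y_bar) ** 2).sum())
    if ss_tot == 0:
        raise EvaluationError("R is undefined: zero variance in the actual counts")
    if (y == 0).any():
        raise EvaluationError("relative MAE is undefined: some y_i are zero")
    n = y.size
    return FitMetrics(
        r=1.0 - ss_res / ss_tot,
        mse=ss_res / n,
        mae=float((np.abs(y - y_hat) / y).mean()),
    )


def pearson_r(series: FitSeries) -> float:
    """Conventional Pearson correlation between actual and fitted counts."""
    y, y_hat = series.y, series.y_hat
    if y.std() == 0 or y_hat.std() == 0:
        raise EvaluationError("Pearson r undefined for a constant series")
    return float(np.corrcoef(y, y_hat)[0, 1])


# ---------------------------------------------------------------------------
# run-level evaluation


@dataclass
class RunReport:
    tallies: dict[str, DetectionTally]
    metrics: dict[str, DetectionMetrics]
    fit: FitMetrics | None
    n_frames: int
    exact_frames: dict[str, int] = field(default_factory=dict)

    def to_rows(self) -> list[dict]:
        rows = []
        for zone, tally in self.tallies.items():
            m = self.metrics.get(zone)
            rows.append(
                {
                    "zone": zone,
                    "true": tally.t_truenum,
                    "detected": tally.t_num,
                    "missed_crowding": tally.miss_crowding,
                    "missed_occlusion": tally.miss_occlusion,
                    "missed_others": tally.miss_others,
                    "false": tally.t_false,
                    "R_ac": m.r_accuracy if m else float("nan"),
                    "R_miss": m.r_miss if m else float("nan"),
                    "R_false": m.r_false if m else float("nan"),
                }
            )
        return rows


def _frame_causes(truth, zone: str) -> tuple[int, int]:
    """(occludable, crowdable) miss capacities for one zone of one frame."""
    occ = sum(
        1
        for b in truth.birds
        if b.zone == zone and b.occluded_fraction > 0.5
    )
    crowd = sum(
        1
        for b in truth.birds
        if b.zone == zone and b.crowded and b.occluded_fraction <= 0.5
    )
    return occ, crowd


def evaluate_run(
    predicted: Sequence[zmod.ZoneCounts],
    truths: Sequence,
    cause_annotations: dict[str, dict[str, dict[str, int]]] | None = None,
    zones_scored: Sequence[str] = (zmod.DRINKING, zmod.FEEDING),
    fit_on_totals: bool = True,
) -> RunReport:
    """Accumulate per-zone tallies and metrics across aligned frames.

    ``truths`` may be scene ground truths (with per-bird occlusion and
    crowding flags, from which miss causes are derived) or plain
    ``ZoneCounts``.  Explicit ``cause_annotations`` — a mapping
    frame_id -> zone -> {cause: count} — take precedence.
    """
    if len(predicted) != len(truths):
        raise EvaluationError(
            f"got {len(predicted)} predicted frames but {len(truths)} truths"
        )
    tallies = {
        z: DetectionTally(zone=z, t_truenum=0, t_num=0) for z in zones_scored
    }
    exact = {z: 0 for z in zones_scored}
    y_tot, y_hat_tot = [], []
    for pred, truth in zip(predicted, truths):
        true_id = getattr(truth, "frame_id", pred.frame_id)
        if pred.frame_id and true_id and pred.frame_id != true_id:
            raise EvaluationError(
                f"frame misalignment: predicted {pred.frame_id!r} vs truth {true_id!r}"
            )
        if hasattr(truth, "per_zone_true_counts"):
            true_by_zone = truth.per_zone_true_counts
            true_total = truth.total
        else:
            true_by_zone = truth.by_zone()
            true_total = truth.total
        pred_by_zone = pred.by_zone()
        y_tot.append(true_total)
        y_hat_tot.append(pred.total)
        for zone in zones_scored:
            t_true = int(true_by_zone.get(zone, 0))
            t_pred = int(pred_by_zone.get(zone, 0))
            tally = tallies[zone]
            tally.t_truenum += t_true
            tally.t_num += t_pred
            miss = max(t_true - t_pred, 0)
            false = max(t_pred - t_true, 0)
            tally.t_false += false
            if miss == 0 and false == 0:
                exact[zone] += 1
            if miss == 0:
                continue
            if cause_annotations and pred.frame_id in cause_annotations:
                causes = cause_annotations[pred.frame_id].get(zone, {})
                c_occ = int(causes.get("occlusion", 0))
                c_crowd = int(causes.get("crowding", 0))
            elif hasattr(truth, "birds"):
                c_occ, c_crowd = _frame_causes(truth, zone)
            else:
                c_occ = c_crowd = 0
            occ = min(miss, c_occ)
            crowd = min(miss - occ, c_crowd)
            tally.miss_occlusion += occ
            tally.miss_crowding += crowd
            tally.miss_others += miss - occ - crowd
    for zone, tally in tallies.items():
        if not tally.consistent():
            raise EvaluationError(
                f"tally inconsistency in zone {zone}: "
                f"{tally.t_num} != {tally.t_truenum} - {tally.t_miss} + {tally.t_false}"
            )
    metrics = {
        z: detection_metrics(t) for z, t in tallies.items() if t.t_truenum > 0
    }
    fit = None
    if fit_on_totals:
        y = np.asarray(y_tot, dtype=np.float64)
        y_hat = np.asarray(y_hat_tot, dtype=np.float64)
        keep = y > 0
        if keep.sum() >= 2 and np.ptp(y[keep]) > 0:
            fit = fit_metrics(FitSeries(y=y[keep], y_hat=y_hat[keep]))
    return RunReport(
        tallies=tallies,
        metrics=metrics,
        fit=fit,
        n_frames=len(predicted),
        exact_frames=exact,
    )


def write_report(report: RunReport, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    import json

    import pandas as pd

    pd.DataFrame(report.to_rows()).to_csv(csv_path, index=False)
    if json_path is not None:
        doc = {
            "n_frames": report.n_frames,
            "zones": report.to_rows(),
            "exact_frames": report.exact_frames,
            "fit": (
                {"R": report.fit.r, "MSE": report.fit.mse, "MAE": report.fit.mae}
                if report.fit
                else None
            ),
        }
        Path(json_path).write_text(json.dumps(doc, indent=2) + "\n")
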
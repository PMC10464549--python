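"""Precision-recall evaluation of ranked position scores against a modification map.

Positions are ranked by score (higher = more likely modified) and compared
with the set of annotated modification sites.  Because a modification's
error signature bleeds into the 5-mer context, positions adjacent to a true
site carry genuine signal; the neighbour policy decides whether the +/-2
flanks of true sites are excluded from the negatives (default), counted as
negatives, or counted as positives.  Performance is summarised by average
precision (step-interpolated area under the precision-recall curve) and can
be stratified by modification class — pseudouridine, 2'-O-ribose
methylation (optionally split by nucleobase), and other marks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve

from .errors import InvalidArgumentError
from .outlier_detection import NEIGHBOUR_RADIUS, ModificationMap

NeighbourPolicy = Literal["exclude", "negative", "positive"]


@dataclass
class PRResult:
    """Precision-recall curve plus its area for one evaluation."""

    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    average_precision: float
    n_pos: int
    n_neg: int
    neighbour_policy: str

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": np.append(self.thresholds, np.nan),
                "precision": self.precision,
                "recall": self.recall,
            }
        )


def _neighbour_mask(positions: np.ndarray, truth_positions: np.ndarray) -> np.ndarray:
    """Positions within +/-2 of a true site but not true sites themselves."""
    if truth_positions.size == 0:
        return np.zeros(positions.size, dtype=bool)
    dist = np.abs(positions[:, None] - truth_positions[None, :]).min(axis=1)
    return (dist > 0) & (dist <= NEIGHBOUR_RADIUS)


def _trapezoid_auc(recall: np.ndarray, precision: np.ndarray) -> float:
    order = np.argsort(recall)
    return float(np.trapezoid(precision[order], recall[order]))


def average_precision(
    scores: pd.Series,
    truth: ModificationMap,
    neighbour_policy: NeighbourPolicy = "exclude",
    estimator: Literal["step", "trapezoid"] = "step",
) -> PRResult:
    """Average precision of a per-position score vector against known sites.

    `scores` is indexed by 1-based position; NaN scores are dropped.  AP is
    the step-interpolated sum ``sum_i (R_i - R_{i-1}) * P_i`` over
    descending-score thresholds (`estimator="trapezoid"` gives the
    trapezoidal variant instead).
    """
    scores = scores.dropna()
    positions = scores.index.to_numpy(dtype=int)
    y_score = scores.to_numpy(dtype=float)
    truth_pos = truth.positions
    y_true = np.isin(positions, truth_pos)

    if neighbour_policy == "exclude":
        keep = ~_neighbour_mask(positions, truth_pos)
        positions, y_score, y_true = positions[keep], y_score[keep], y_true[keep]
    elif neighbour_policy == "positive":
        y_true = y_true | _neighbour_mask(positions, truth_pos)
    elif neighbour_policy != "negative":
        raise InvalidArgumentError(f"unknown neighbour policy {neighbour_policy!r}")

    n_pos = int(y_true.sum())
    n_neg = int((~y_true).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError(
            f"need >=1 positive and >=1 negative after policy (got {n_pos}/{n_neg})"
        )
    precision, recall, thresholds = precision_recall_curve(y_true, y_score)
    if estimator == "step":
        ap = float(average_precision_score(y_true, y_score))
    else:
        ap = _trapezoid_auc(recall, precision)
    return PRResult(
        precision=precision,
        recall=recall,
        thresholds=thresholds,
        average_precision=ap,
        n_pos=n_pos,
        n_neg=n_neg,
        neighbour_policy=neighbour_policy,
    )


def _class_summary(scores: pd.Series, positions: np.ndarray) -> dict:
    vals = scores.reindex(positions).dropna().to_numpy()
    if vals.size == 0:
        return {"n": 0, "median": np.nan, "q1": np.nan, "q3": np.nan}
    q1, med, q3 = np.percentile(vals, [25, 50, 75])
    return {"n": int(vals.size), "median": float(med), "q1": float(q1), "q3": float(q3)}


def stratified_report(
    scores: pd.Series,
    truth: ModificationMap,
    ref_seq: str | None = None,
    neighbour_policy: NeighbourPolicy = "exclude",
) -> tuple[dict[str, PRResult], pd.DataFrame]:
    """Per-modification-class precision-recall evaluation.

    Strata: ``all``, ``psU``, ``Nm``, ``other`` (every class that is
    neither psU nor Nm) and, when `ref_seq` is given, Nm split by
    nucleobase (``Am``, ``Cm``, ``Gm``, ``Um``).  Within a stratum the
    positives are that stratum's sites; sites of other classes are excluded
    from the negatives.  Also returns a per-class score-distribution
    summary (n, median, quartiles).

    Empty strata are skipped with a warning.
    """
    classes = pd.Series(truth.sites)
    strata: dict[str, np.ndarray] = {"all": truth.positions}
    strata["psU"] = classes.index[classes.isin(["psU", "m1acp3psU"])].to_numpy()
    strata["Nm"] = classes.index[classes == "Nm"].to_numpy()
    strata["other"] = classes.index[~classes.isin(["psU", "m1acp3psU", "Nm"])].to_numpy()
    if ref_seq is not None:
        for base in "ACGT":
            sel = [p for p in strata["Nm"] if p <= len(ref_seq) and ref_seq[p - 1] == base]
            strata[f"{base}m".replace("Tm", "Um")] = np.array(sel, dtype=int)

    results: dict[str, PRResult] = {}
    summaries = []
    for name, pos in strata.items():
        pos = np.asarray(pos, dtype=int)
        if pos.size == 0:
            warnings.warn(f"stratum {name!r} is empty; skipped", stacklevel=2)
            continue
        other_sites = np.setdiff1d(truth.positions, pos)
        sub_scores = scores.drop(index=[p for p in other_sites if p in scores.index])
        sub_map = ModificationMap(sites={int(p): truth.sites[int(p)] for p in pos})
        try:
            results[name] = average_precision(sub_scores, sub_map, neighbour_policy)
        except InvalidArgumentError as exc:
            warnings.warn(f"stratum {name!r}: {exc}", stacklevel=2)
            continue
        summaries.append({"stratum": name, **_class_summary(scores, pos)})
    summary = pd.DataFrame(summaries)
    return results, summary
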
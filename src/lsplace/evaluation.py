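"""Scoring support quality against known truth.

Given placements with per-edge support and the edge each query truly
belongs on, this module computes:

* calibration — branches binned by support (left-inclusive 10-point bins,
  the last bin holding exactly 100%), per-bin fraction correct, and the
  mean squared error against the unity line (bin midpoint), weighted by
  bin occupancy by default;
* predictive power — recall vs. false-positive rate over integer support
  thresholds T in 0..100 (a correct branch with support s is a TP iff
  s >= T, an incorrect one an FP iff s >= T), plus an exact rank-based
  AUROC (trapezoid over the full curve, so it is invariant under strictly
  monotone transforms of the support values);
* ECDFs of top-placement support for the correct and incorrect classes;
* top-k accuracy — the fraction of queries whose true edge is among the k
  highest-support edges (ties by edge number), for k = 1..kmax.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd


@dataclass
class LabeledPlacement:
    """A query's support map together with its true attachment edge."""

    query_id: str
    support: dict
    true_edge: int

    def __post_init__(self):
        if not self.support:
            raise ValueError("empty support map")

    @property
    def ranked_edges(self) -> list:
        """Edges by descending support, ties broken by edge number."""
        return [e for e, _ in sorted(self.support.items(), key=lambda kv: (-kv[1], kv[0]))]

    @property
    def top_edge(self) -> int:
        return self.ranked_edges[0]

    @property
    def top_support(self) -> float:
        return self.support[self.top_edge]

    @property
    def correct(self) -> bool:
        return self.top_edge == self.true_edge


def label_placements(supported: Iterable, truth: dict) -> list[LabeledPlacement]:
    """Join supported placements with a truth table (query_id -> edge)."""
    out, missing = [], []
    for sp in supported:
        if sp.query_id not in truth:
            missing.append(sp.query_id)
            continue
        out.append(LabeledPlacement(sp.query_id, dict(sp.support), int(truth[sp.query_id])))
    if missing:
        raise KeyError(f"query ids missing from truth table: {missing[:10]}")
    return out


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

def default_bins() -> list[tuple[float, float]]:
    """Left-inclusive percent bins [0,10), ..., [90,100), plus {100}."""
    edges = list(range(0, 100, 10))
    bins = [(float(lo), float(lo + 10)) for lo in edges]
    bins.append((100.0, 100.0))
    return bins


@dataclass
class CalibrationResult:
    bins: list
    counts: np.ndarray
    accuracy: np.ndarray  # NaN for empty bins
    mse: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": [b[0] for b in self.bins],
                "bin_high": [b[1] for b in self.bins],
                "count": self.counts,
                "accuracy": self.accuracy,
            }
        )


def calibration(
    placements: list[LabeledPlacement],
    bins: Optional[list] = None,
    weighted: bool = True,
) -> CalibrationResult:
    """Bin top placements by support (percent) and compare per-bin accuracy
    to the bin midpoint.

    MSE is the mean over non-empty bins of (accuracy - midpoint/100)^2,
    weighted by bin occupancy when ``weighted`` (empty bins are excluded).
    """
    if not placements:
        raise ValueError("no placements to calibrate")
    bins = bins or default_bins()
    sup = np.array([lp.top_support for lp in placements]) * 100.0
    correct = np.array([lp.correct for lp in placements], dtype=float)
    counts = np.zeros(len(bins), dtype=int)
    acc = np.full(len(bins), np.nan)
    for k, (lo, hi) in enumerate(bins):
        if lo == hi:
            mask = sup == lo
        else:
            mask = (sup >= lo) & (sup < hi)
        counts[k] = mask.sum()
        if counts[k]:
            acc[k] = correct[mask].mean()
    mids = np.array([(lo + hi) / 200.0 for lo, hi in bins])
    nonempty = counts > 0
    sq = (acc[nonempty] - mids[nonempty]) ** 2
    if weighted:
        mse = float(np.average(sq, weights=counts[nonempty]))
    else:
        mse = float(sq.mean())
    return CalibrationResult(bins=bins, counts=counts, accuracy=acc, mse=mse)


# --------------------------------------------------------------------------
# ROC / AUROC
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    thresholds: np.ndarray
    recall: np.ndarray
    fpr: np.ndarray
    auroc: Optional[float]  # None when only one class is present


def _rank_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exact AUROC via the Mann–Whitney statistic (average ranks handle
    ties, equivalent to trapezoid integration of the full ROC curve)."""
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(scores.size)
    sorted_scores = scores[order]
    ranks[order] = np.arange(1, scores.size + 1)
    # average ranks within tied groups
    uniq, inv = np.unique(sorted_scores, return_inverse=True)
    sums = np.bincount(inv, weights=np.arange(1, scores.size + 1))
    cnts = np.bincount(inv)
    avg = sums / cnts
    ranks[order] = avg[inv]
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    r_pos = ranks[labels.astype(bool)].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc(placements: list[LabeledPlacement]) -> RocResult:
    """Recall vs. FPR over integer support thresholds, plus exact AUROC.

    With a single class present the curve is still reported but the AUROC
    is undefined (None).
    """
    sup = np.array([lp.top_support for lp in placements]) * 100.0
    correct = np.array([lp.correct for lp in placements], dtype=bool)
    n_pos, n_neg = int(correct.sum()), int((~correct).sum())
    thresholds = np.arange(101)
    ge = sup[None, :] >= thresholds[:, None]
    tp = (ge & correct[None, :]).sum(axis=1)
    fp = (ge & ~correct[None, :]).sum(axis=1)
    recall = tp / n_pos if n_pos else np.full(101, np.nan)
    fpr = fp / n_neg if n_neg else np.full(101, np.nan)
    auroc = _rank_auroc(sup / 100.0, correct.astype(float)) if n_pos and n_neg else None
    return RocResult(thresholds=thresholds, recall=recall, fpr=fpr, auroc=auroc)


# --------------------------------------------------------------------------
# ECDF
# --------------------------------------------------------------------------

@dataclass
class ECDF:
    """Right-continuous empirical CDF of top-placement support."""

    x: np.ndarray  # sorted unique support values
    y: np.ndarray  # cumulative fractions

    def __call__(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        idx = np.searchsorted(self.x, v, side="right")
        out = np.where(idx > 0, self.y[np.maximum(idx - 1, 0)], 0.0)
        return float(out) if out.ndim == 0 else out


def ecdf(placements: list[LabeledPlacement]) -> dict:
    """ECDFs of top-placement support, separated by correctness.  Classes
    with no members are absent from the result."""
    out = {}
    for name, keep in (("correct", True), ("incorrect", False)):
        vals = np.sort([lp.top_support for lp in placements if lp.correct == keep])
        if vals.size == 0:
            continue
        x, counts = np.unique(vals, return_counts=True)
        out[name] = ECDF(x=x, y=np.cumsum(counts) / vals.size)
    return out


# --------------------------------------------------------------------------
# top-k
# --------------------------------------------------------------------------

def topk_accuracy(placements: list[LabeledPlacement], kmax: int = 10) -> np.ndarray:
    """``acc[k-1]`` = fraction of queries whose true edge is among the k
    highest-support edges; non-decreasing in k."""
    if not placements:
        raise ValueError("no placements")
    acc = np.zeros(kmax)
    for lp in placements:
        ranked = lp.ranked_edges
        for k in range(kmax):
            if lp.true_edge in ranked[: k + 1]:
                acc[k:] += 1
                break
    return acc / len(placements)


# --------------------------------------------------------------------------
# combined summary
# --------------------------------------------------------------------------

@dataclass
class EvalSummary:
    calibration: CalibrationResult
    roc: RocResult
    ecdf: dict
    topk: np.ndarray
    n_queries: int

    def as_dict(self) -> dict:
        return {
            "n_queries": self.n_queries,
            "top1_accuracy": float(self.topk[0]),
            "topk_accuracy": [float(v) for v in self.topk],
            "calibration_mse": self.calibration.mse,
            "auroc": self.roc.auroc,
        }


def evaluate(placements: list[LabeledPlacement], kmax: int = 10) -> EvalSummary:
    """All four metrics on one labeled set."""
    return EvalSummary(
        calibration=calibration(placements),
        roc=roc(placements),
        ecdf=ecdf(placements),
        topk=topk_accuracy(placements, kmax=kmax),
        n_queries=len(placements),
    )


def read_truth_table(path) -> dict:
    """TSV with columns ``query_id`` and ``true_edge`` -> dict."""
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty truth table {path}")
    if not {"query_id", "true_edge"} <= set(df.columns):
        raise ValueError("truth table needs columns query_id, true_edge")
    return {str(r.query_id): int(r.true_edge) for r in df.itertuples()}


def write_truth_table(truth: dict, path) -> None:
    pd.DataFrame(
        {"query_id": list(truth), "true_edge": [truth[q] for q in truth]}
    ).to_csv(path, sep="\t", index=False)
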
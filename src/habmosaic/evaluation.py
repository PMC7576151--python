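"""Accuracy assessment for presence-background suitability models.

Threshold-independent measures: AUC (rank probability that a random
presence outscores a random background point, ties counted half) and the
continuous Boyce index (Spearman correlation of predicted-to-expected
presence ratios against suitability, over overlapping moving windows).
Threshold-dependent measures: sensitivity, specificity and the true skill
statistic TSS = sensitivity + specificity - 1, computed from binary maps
with background points standing in for absences. Thresholds are selected by
maximizing sensitivity + specificity over the observed scores, with
``score >= t`` mapped to habitat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .raster import Raster


@dataclass
class EvaluationReport:
    """Per-iteration accuracy measures (one row of a Table-1-like grid)."""

    auc: float
    boyce: float
    tss: float
    sensitivity: float
    specificity: float
    threshold: float
    n_presence: int
    n_background: int
    model_tag: str = ""
    fold: int = -1

    def __post_init__(self) -> None:
        assert -1e-9 <= self.auc <= 1 + 1e-9
        assert abs(self.tss - (self.sensitivity + self.specificity - 1.0)) < 1e-12


def reports_to_csv(reports: Iterable[EvaluationReport], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in reports]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Threshold-independent
# ---------------------------------------------------------------------------

def auc(scores_presence: np.ndarray, scores_background: np.ndarray) -> float:
    """Rank-based AUC with ties counted one half."""
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    if not (np.all(np.isfinite(sp)) and np.all(np.isfinite(sb))):
        raise ValueError("non-finite scores")
    ranks = rankdata(np.concatenate([sp, sb]))
    r_pos = ranks[: sp.size].sum()
    return float((r_pos - sp.size * (sp.size + 1) / 2.0) / (sp.size * sb.size))


def boyce_index(
    suitability: Raster,
    presence_points: np.ndarray,
    n_windows: int = 101,
    window_width: float | None = None,
) -> float:
    """Continuous Boyce index over overlapping suitability windows.

    Defaults mirror the conventional moving-window setup: window width =
    one tenth of the suitability range, 101 windows sliding across it.
    P/E per window is (share of presences) / (share of study-area cells);
    the index is the Spearman correlation of P/E with the window midpoint
    over windows with nonzero expected share.
    """
    vals = suitability.values[suitability.valid_mask()]
    if vals.size == 0 or vals.max() == vals.min():
        raise ValueError("constant or empty suitability raster")
    presence_points = np.asarray(presence_points, dtype=float)
    pres = suitability.sample(presence_points[:, 0], presence_points[:, 1])
    if np.any(np.isnan(pres)):
        raise ValueError("presence points fall on nodata cells")
    lo, hi = float(vals.min()), float(vals.max())
    width = (hi - lo) / 10.0 if window_width is None else window_width
    starts = np.linspace(lo, hi - width, n_windows)
    mids, ratios = [], []
    for s in starts:
        e = ((vals >= s) & (vals <= s + width)).mean()
        if e == 0:
            continue
        p = ((pres >= s) & (pres <= s + width)).mean()
        mids.append(s + width / 2.0)
        ratios.append(p / e)
    if len(mids) < 2:
        raise ValueError("fewer than two windows with nonzero expected share")
    rho, _ = spearmanr(ratios, mids)
    return float(rho)


# ---------------------------------------------------------------------------
# Threshold-dependent
# ---------------------------------------------------------------------------

def confusion_stats(
    pred_presence: np.ndarray, pred_background: np.ndarray
) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) from binary predictions at points."""
    pp = np.asarray(pred_presence)
    pb = np.asarray(pred_background)
    if pp.size == 0 or pb.size == 0:
        raise ValueError("both point sets must be non-empty")
    sens = float((pp == 1).mean())
    spec = float((pb == 0).mean())
    return sens, spec, sens + spec - 1.0


def tss_from_rates(sensitivity: float, specificity: float) -> float:
    """TSS identity: sensitivity + specificity - 1."""
    return sensitivity + specificity - 1.0


def max_sss_threshold(
    scores_presence: np.ndarray, scores_background: np.ndarray
) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the distinct observed scores; prediction rule is
    ``score >= t -> habitat``; ties resolved to the smallest maximizer.
    """
    sp = np.asarray(scores_presence, dtype=float)
    sb = np.asarray(scores_background, dtype=float)
    if sp.size == 0 or sb.size == 0:
        raise ValueError("both score sets must be non-empty")
    candidates = np.unique(np.concatenate([sp, sb]))
    best_t, best_val = candidates[0], -np.inf
    for t in candidates:
        val = (sp >= t).mean() + (sb < t).mean()
        if val > best_val + 1e-15:
            best_val, best_t = val, t
    return float(best_t)


def evaluate_fold(
    suitability: Raster,
    test_presence_xy: np.ndarray,
    background_xy: np.ndarray,
    threshold: float | None = None,
    model_tag: str = "",
    fold: int = -1,
    boyce_kwargs: dict | None = None,
) -> EvaluationReport:
    """Full five-measure report for one model iteration.

    If no threshold is supplied, the max sensitivity+specificity threshold
    from this iteration's scores is used.
    """
    test_presence_xy = np.asarray(test_presence_xy, dtype=float)
    background_xy = np.asarray(background_xy, dtype=float)
    sp = suitability.sample(test_presence_xy[:, 0], test_presence_xy[:, 1])
    sb = suitability.sample(background_xy[:, 0], background_xy[:, 1])
    ok_p, ok_b = ~np.isnan(sp), ~np.isnan(sb)
    sp, sb = sp[ok_p], sb[ok_b]
    if threshold is None:
        threshold = max_sss_threshold(sp, sb)
    sens, spec, tss = confusion_stats((sp >= threshold).astype(int),
                                      (sb >= threshold).astype(int))
    return EvaluationReport(
        auc=auc(sp, sb),
        boyce=boyce_index(suitability, test_presence_xy[ok_p],
                          **(boyce_kwargs or {})),
        tss=tss, sensitivity=sens, specificity=spec, threshold=float(threshold),
        n_presence=int(sp.size), n_background=int(sb.size),
        model_tag=model_tag, fold=fold,
    )
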
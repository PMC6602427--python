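"""Evaluation statistics: regression metrics, correlation comparison
tests and hotspot classification.

Correlations between predicted and experimental ddG are summarised by
Pearson's r, Kendall's tau-b (tie-corrected, since experimental tables
contain ties) and RMSE in kcal/mol. Two correlations measured on
independent samples are compared with the Fisher r-to-z test; Kendall
scores enter the same test through Greiner's relation r = sin(pi tau/2).
Hotspot classification binarises both vectors at a destabilisation
threshold (default 2.0 kcal/mol).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: sentinel for undefined correlations / recalls (degenerate inputs)
UNDEFINED = float("nan")


@dataclass
class EvaluationReport:
    pearson: float
    kendall: float
    rmse: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {"pearson": self.pearson, "kendall": self.kendall,
                "rmse": self.rmse, "n": self.n}


def regression_metrics(pred, obs) -> EvaluationReport:
    """Pearson r, Kendall tau-b and RMSE between two equal-length vectors.

    Zero variance in either vector leaves the correlations undefined
    (NaN) while RMSE is still reported.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("pred and obs must be equal-length 1-D vectors")
    if len(pred) < 2:
        raise ValueError("need at least 2 observations")
    if not (np.isfinite(pred).all() and np.isfinite(obs).all()):
        raise ValueError("inputs must be finite")
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        return EvaluationReport(UNDEFINED, UNDEFINED, rmse, len(pred))
    pearson = float(stats.pearsonr(pred, obs).statistic)
    kendall = float(stats.kendalltau(pred, obs, variant="b").statistic)
    return EvaluationReport(pearson, kendall, rmse, len(pred))


def fisher_r_to_z_test(r1: float, n1: int, r2: float, n2: int) -> float:
    """Two-tailed p for the difference of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    for n in (n1, n2):
        if n < 4:
            raise ValueError("need n >= 4 per sample")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    return float(2.0 * stats.norm.sf(abs(z)))


def tau_to_r(tau: float) -> float:
    """Greiner's relation r = sin(pi tau / 2) for rank correlations."""
    if abs(tau) > 1:
        raise ValueError("|tau| must be <= 1")
    return math.sin(math.pi * tau / 2.0)


@dataclass
class HotspotReport:
    hotspot_recall: float
    hotspot_precision: float
    nonhotspot_recall: float
    nonhotspot_precision: float
    n_hotspots: int
    n_nonhotspots: int

    def as_dict(self) -> dict[str, float]:
        return {
            "hotspot_recall": self.hotspot_recall,
            "hotspot_precision": self.hotspot_precision,
            "nonhotspot_recall": self.nonhotspot_recall,
            "nonhotspot_precision": self.nonhotspot_precision,
            "n_hotspots": self.n_hotspots,
            "n_nonhotspots": self.n_nonhotspots,
        }


def hotspot_metrics(pred_ddg, obs_ddg, threshold: float = 2.0,
                    destabilizing_sign: float = -1.0) -> HotspotReport:
    """Per-class precision and recall of hotspot identification.

    A residue is a hotspot when its mutation destabilises binding by at
    least ``threshold`` kcal/mol. In the package's wt - mt sign
    convention destabilising mutations have negative ddG, so the default
    ``destabilizing_sign`` of -1 classifies ddG <= -threshold as hot;
    pass +1 for tables recorded in the opposite convention.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pred = np.asarray(pred_ddg, dtype=float)
    obs = np.asarray(obs_ddg, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have equal length")
    pred_hot = destabilizing_sign * pred >= threshold
    obs_hot = destabilizing_sign * obs >= threshold

    def _recall(mask_obs, mask_pred):
        n = int(mask_obs.sum())
        return (float((mask_pred & mask_obs).sum() / n) if n else UNDEFINED)

    def _precision(mask_obs, mask_pred):
        n = int(mask_pred.sum())
        return (float((mask_pred & mask_obs).sum() / n) if n else UNDEFINED)

    return HotspotReport(
        hotspot_recall=_recall(obs_hot, pred_hot),
        hotspot_precision=_precision(obs_hot, pred_hot),
        nonhotspot_recall=_recall(~obs_hot, ~pred_hot),
        nonhotspot_precision=_precision(~obs_hot, ~pred_hot),
        n_hotspots=int(obs_hot.sum()),
        n_nonhotspots=int((~obs_hot).sum()),
    )
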
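"""Agreement statistics and the shuffled-reliability protocol.

Predicted NSAs are compared to clinician ground truth with Spearman's
rank correlation, the coefficient of determination against truth
(R^2 = 1 - SSres/SStot), mean absolute error and mean squared error.
Reliability is assessed by repeating the whole fusion experiment many
times with the patient order reshuffled, re-splitting and re-training
on each repetition, and summarising the per-repetition metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .fusion import FusionConfig, predict_fused, train_fusion

__all__ = [
    "AgreementMetrics",
    "RepetitionSummary",
    "spearman",
    "regression_metrics",
    "kruskal_wallis",
    "agreement",
    "run_reliability",
    "metrics_to_csv",
]

_METRIC_KEYS = ("spearman_rs", "r_squared", "mae", "mse")


@dataclass(frozen=True)
class AgreementMetrics:
    """Agreement between predicted and ground-truth NSAs."""

    spearman_rs: float
    p_value: float
    r_squared: float
    mae: float
    mse: float
    n: int


def spearman(x, y):
    """Spearman rank correlation and its large-sample p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def regression_metrics(predicted, truth):
    """``(r_squared, mae, mse)`` of predictions against ground truth.

    R^2 is computed against truth directly (1 - SSres/SStot), so a
    biased predictor is penalised; it is NaN for constant truth.
    """
    predicted = np.asarray(predicted, float)
    truth = np.asarray(truth, float)
    if predicted.shape != truth.shape or predicted.ndim != 1:
        raise ValueError("predicted and truth must be 1-D of equal length")
    if len(truth) < 2:
        raise ValueError("need at least 2 points")
    mae = float(mean_absolute_error(truth, predicted))
    mse = float(mean_squared_error(truth, predicted))
    if np.ptp(truth) == 0:
        import warnings

        warnings.warn("constant truth vector: R^2 undefined, returning NaN")
        return float("nan"), mae, mse
    return float(r2_score(truth, predicted)), mae, mse


def kruskal_wallis(*groups):
    """Rank-based Kruskal-Wallis H test across two or more groups.

    Returns ``(H, p)``; by convention ``(0.0, 1.0)`` when every value
    is identical (no rank variation).
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and groups[0] and \
            isinstance(groups[0][0], (list, tuple, np.ndarray)):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(g, float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def agreement(predicted, truth) -> AgreementMetrics:
    """All agreement metrics on one index set."""
    rs, p = spearman(predicted, truth)
    r2, mae, mse = regression_metrics(predicted, truth)
    return AgreementMetrics(
        spearman_rs=rs, p_value=p, r_squared=r2, mae=mae, mse=mse, n=len(truth)
    )


@dataclass
class RepetitionSummary:
    """Per-repetition metrics for the fused and CV-only (baseline) arms."""

    n_repetitions: int
    fused: list  # AgreementMetrics per repetition
    baseline: list  # AgreementMetrics for the raw AP CV estimate, same folds

    def _stats(self, metrics_list):
        out = {}
        for key in _METRIC_KEYS:
            vals = np.array([getattr(m, key) for m in metrics_list], float)
            out[key] = {"mean": float(np.mean(vals)), "std": float(np.std(vals))}
        return out

    @property
    def fused_summary(self) -> dict:
        return self._stats(self.fused)

    @property
    def baseline_summary(self) -> dict:
        return self._stats(self.baseline)


def metrics_to_csv(metrics: AgreementMetrics, path) -> None:
    """Write one metrics bundle as a two-column ``metric,value`` CSV."""
    import dataclasses

    import pandas as pd

    rows = [(k, v) for k, v in dataclasses.asdict(metrics).items()]
    pd.DataFrame(rows, columns=["metric", "value"]).to_csv(path, index=False)


def run_reliability(
    records,
    config: FusionConfig | None = None,
    n_repetitions: int = 50,
    base_seed: int = 0,
) -> RepetitionSummary:
    """Repeat split/train/test with reshuffled patient order.

    Repetition ``r`` uses seed ``base_seed + r`` for the shuffle and
    the network initialisation, re-trains the fusion network, and
    scores both the fused predictions and the raw AP CV estimates on
    that repetition's held-out fold.
    """
    if n_repetitions < 1:
        raise ValueError("n_repetitions must be >= 1")
    config = config or FusionConfig()
    records = list(records)
    fused_all, baseline_all = [], []
    for r in range(n_repetitions):
        rep_cfg = replace(config, seed=int(base_seed + r) % (2**31))
        try:
            model, report = train_fusion(records, rep_cfg)
            test = [rec for rec in records if rec.hip_id in set(report.test_ids)]
            truth = [rec.nsa_ap_clinician for rec in test]
            preds = [
                predict_fused(model, rec.nsa_ap_cv, rec.nsa_lateral_cv) for rec in test
            ]
            fused_all.append(agreement(preds, truth))
            baseline_all.append(agreement([rec.nsa_ap_cv for rec in test], truth))
        except Exception as exc:  # noqa: BLE001 - seed context is essential
            raise RuntimeError(
                f"reliability repetition {r} (seed {rep_cfg.seed}) failed: {exc}"
            ) from exc
    return RepetitionSummary(
        n_repetitions=n_repetitions, fused=fused_all, baseline=baseline_all
    )
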
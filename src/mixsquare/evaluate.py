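"""Accuracy and repeatability metrics for quantification experiments.

Covers the L1 abundance distance (bounded by [0, 2] on the simplex), the
abundance-weighted L1 between estimated and true fragment-start
distributions, boxplot-style truncation of log10 expression values, a
fold-change ROC for differential-expression calling, titration design
checks for two-sample mixtures (C = 3:1 and D = 1:3 mixes of A and B with
mRNA-fraction correction z) and a detrended per-bin variability curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MixDesignConstants",
    "l1_abundance",
    "weighted_l1_start_distributions",
    "truncate_log_values",
    "fold_change_roc",
    "expected_cd_ratio",
    "titration_consistent",
    "detrended_variability",
    "log_r_squared",
]


def l1_abundance(a, b) -> float:
    """Sum of absolute differences between two abundance vectors; in [0, 2]
    for simplex vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("abundance vectors have different dimensions")
    return float(np.abs(a - b).sum())


def weighted_l1_start_distributions(estimated, true, alpha_est) -> float:
    """Average L1 distance between estimated and true per-transcript start
    distributions, weighted by the estimated relative abundance."""
    alpha_est = np.asarray(alpha_est, dtype=float)
    if not (len(estimated) == len(true) == len(alpha_est)):
        raise ValueError("mismatched numbers of transcripts")
    total = 0.0
    for w, p_est, p_true in zip(alpha_est, estimated, true):
        p_est = np.asarray(p_est, dtype=float)
        p_true = np.asarray(p_true, dtype=float)
        if p_est.shape != p_true.shape:
            raise ValueError("distribution lengths differ for a transcript")
        total += w * float(np.abs(p_est - p_true).sum())
    return total


@dataclass
class TruncationResult:
    log_values: np.ndarray
    not_detected: np.ndarray  # boolean mask
    threshold: float


def truncate_log_values(values) -> TruncationResult:
    """Truncate log10 values below Q1 - 1.5*IQR of the finite logs.

    Values whose log10 falls below the threshold (including zeros, whose
    log is -inf) are set to the threshold and flagged not-detected.
    Quartiles use linear interpolation (numpy default, type 7).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if np.any(values < 0):
        raise ValueError("values must be non-negative")
    with np.errstate(divide="ignore"):
        logs = np.log10(values)
    finite = logs[np.isfinite(logs)]
    if finite.size == 0:
        raise ValueError("no positive values to set a threshold from")
    q1, q3 = np.percentile(finite, [25, 75])
    threshold = q1 - 1.5 * (q3 - q1)
    nd = ~(logs >= threshold)  # catches -inf and NaN-free below-threshold
    out = logs.copy()
    out[nd] = threshold
    return TruncationResult(log_values=out, not_detected=nd, threshold=float(threshold))


@dataclass
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    tpr_at_fpr: dict[float, float] = field(default_factory=dict)

    @property
    def auc(self) -> float:
        order = np.argsort(self.fpr)
        return float(np.trapezoid(self.tpr[order], self.fpr[order]))


def fold_change_roc(
    reference_fc,
    estimated_fc,
    thresholds=None,
    up_cut: float = 2.0,
    down_cut: float = 0.5,
    fpr_levels=(0.05, 0.10, 0.15),
) -> RocResult:
    """ROC for calling differential expression from estimated fold changes.

    Reference labels: up-regulated if reference fold change > ``up_cut``,
    down-regulated if < ``down_cut``, otherwise null.  For each threshold
    theta a transcript is called up if its estimated fold change exceeds
    theta and down if it is below 1/theta.  True positives are
    correct-direction calls; false positives are calls on null transcripts.
    Estimated fold changes may be infinite (outliers are not truncated).
    """
    ref = np.asarray(reference_fc, dtype=float)
    est = np.asarray(estimated_fc, dtype=float)
    if ref.shape != est.shape:
        raise ValueError("paired vectors required")
    up = ref > up_cut
    down = ref < down_cut
    null = ~(up | down)
    n_pos = int(up.sum() + down.sum())
    n_null = int(null.sum())
    if n_null == 0:
        raise ValueError("no null transcripts: FPR undefined")
    if thresholds is None:
        finite = est[np.isfinite(est) & (est > 0)]
        cand = np.unique(np.concatenate([finite, 1.0 / finite]))
        cand = cand[cand >= 1.1]
        thresholds = np.unique(np.concatenate([[1.1], cand, cand + 1e-9]))
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    fpr_list, tpr_list = [], []
    for theta in thresholds:
        call_up = est > theta
        call_down = est < 1.0 / theta
        tp = int((call_up & up).sum() + (call_down & down).sum())
        fp = int(((call_up | call_down) & null).sum())
        tpr_list.append(tp / n_pos if n_pos else 0.0)
        fpr_list.append(fp / n_null)
    fpr = np.array(fpr_list)
    tpr = np.array(tpr_list)
    order = np.argsort(fpr, kind="stable")
    fpr_s, tpr_s = fpr[order], tpr[order]
    tpr_at = {
        lvl: float(np.interp(lvl, fpr_s, tpr_s)) for lvl in fpr_levels
    }
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, tpr_at_fpr=tpr_at)


@dataclass(frozen=True)
class MixDesignConstants:
    """Two-sample titration constants: C = 3:1 and D = 1:3 volumetric mixes
    of A and B, corrected by the mRNA-fraction ratio z."""

    z: float = 1.43

    @property
    def k1(self) -> float:
        return 3 * self.z / (3 * self.z + 1)

    @property
    def k2(self) -> float:
        return self.z / (self.z + 3)


def expected_cd_ratio(A: float, B: float, constants: MixDesignConstants | None = None) -> float:
    """Predicted C/D concentration ratio from the A and B measurements:
    (k1*A + (1-k1)*B) / (k2*A + (1-k2)*B)."""
    c = constants or MixDesignConstants()
    denom = c.k2 * A + (1 - c.k2) * B
    if denom <= 0:
        raise ValueError("C/D ratio undefined (non-positive denominator)")
    return (c.k1 * A + (1 - c.k1) * B) / denom


def titration_consistent(A: float, B: float, C: float, D: float) -> bool:
    """True when the mixes fall in titration order: A > C > D > B when
    A > B, the reverse when B > A; ties A == B count as consistent."""
    for v in (A, B, C, D):
        if not np.isfinite(v) or v < 0:
            raise ValueError("titration values must be finite and non-negative")
    if A > B:
        return A > C > D > B
    if B > A:
        return B > D > C > A
    return True


def detrended_variability(
    replicate_logs: pd.DataFrame,
    housekeeping: list[str] | None = None,
    n_bins: int = 100,
) -> pd.DataFrame:
    """Median per-bin standard deviation of detrended log10 values.

    ``replicate_logs`` has transcripts as the index and one column per
    replicate.  Each replicate is shifted so its median over the
    housekeeping set matches the common (mean) target; the x-axis is the
    per-transcript mean of the detrended logs, divided into ``n_bins``
    equal-width bins; the y-axis is the median over each bin of the
    per-transcript standard deviation across replicates.  Empty bins are
    omitted.
    """
    if replicate_logs.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    logs = replicate_logs.astype(float)
    if housekeeping is not None:
        hk = logs.loc[logs.index.intersection(housekeeping)]
        if hk.empty:
            raise ValueError("housekeeping set matches no transcripts")
        medians = hk.median(axis=0)
        target = medians.mean()
        logs = logs - (medians - target)
    x = logs.mean(axis=1).to_numpy()
    sd = logs.std(axis=1, ddof=1).to_numpy()
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin": b,
                "x_center": 0.5 * (edges[b] + edges[b + 1]),
                "median_sd": float(np.median(sd[mask])),
                "n": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def log_r_squared(a, b) -> float:
    """Squared Pearson correlation of two (already truncated) log vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
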
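"""Accuracy metrics, rank-sum statistics and report assembly.

Two scalar metrics compare an estimated joint-angle series ``y`` with
the ground-truth series ``x``:

* RMSE — root-mean-square error, sensitive to shape and offset errors;
* ROME — range-of-motion error, ``(max x - min x) - (max y - min y)``,
  offset-invariant and sensitive only to the estimated movement
  amplitude.  ROME is signed per trial; report aggregates use its
  magnitude.

Method comparisons use the two-sided Wilcoxon-Mann-Whitney rank-sum
test, computed exactly by full enumeration of rank assignments for
small samples (n + m <= 16, which covers two groups of seven) and by
the tie-corrected normal approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError, ValidationError
from .trajectories import JointTrajectory, SAGITTAL_CHANNELS

JOINTS = ("hip", "knee", "ankle")
METRICS = ("rmse", "rome")
METHODS = ("rigid", "eikpe")

_EXACT_LIMIT = 16


def _paired(x, y) -> tuple:
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size == 0 or x.size != y.size:
        raise ValidationError(f"series must be non-empty and equal length ({x.size} vs {y.size})")
    return x, y


def rmse(x: Sequence[float], y: Sequence[float]) -> float:
    """Root-mean-square difference between paired angle series (deg)."""
    x, y = _paired(x, y)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def rome(x: Sequence[float], y: Sequence[float]) -> float:
    """Range-of-motion error (deg, signed): range(x) - range(y)."""
    x, y = _paired(x, y)
    return float((x.max() - x.min()) - (y.max() - y.min()))


def improvement_pct(e_rigid: float, e_eikpe: float) -> float:
    """Error reduction (%) of the coupled estimator over the rigid baseline."""
    if not e_rigid > 0:
        raise ValidationError("improvement undefined for a non-positive baseline error")
    if e_eikpe < 0:
        raise ValidationError("estimator error must be >= 0")
    return 100.0 * (e_rigid - e_eikpe) / e_rigid


def ranksum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value.

    Exact by enumeration of all C(n+m, n) rank assignments (mid-ranks
    for ties) when n + m <= 16; tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float).reshape(-1)
    b = np.asarray(b, dtype=float).reshape(-1)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    n, m = a.size, b.size
    if n + m <= _EXACT_LIMIT:
        ranks = stats.rankdata(np.concatenate([a, b]))
        w_obs = float(ranks[:n].sum())
        mu = n * (n + m + 1) / 2.0
        dev = abs(w_obs - mu)
        count = 0
        for idx in combinations(range(n + m), n):
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12:
                count += 1
        return count / comb(n + m, n)
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)


# ----------------------------------------------------------------------
# report assembly
# ----------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-joint, per-method error summary across subjects.

    ``per_subject[metric][joint][method]`` holds one error value per
    subject (|ROME| for the range metric); ``table`` is the aggregated
    mean ± sd layout with improvement percentages (computed from the
    unrounded means, rounded last) and rank-sum p-values.
    """

    per_subject: Dict[str, Dict[str, Dict[str, np.ndarray]]]
    n_subjects: int
    table: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.table is None:
            self.table = self._build_table()

    def _build_table(self) -> pd.DataFrame:
        rows = []
        for joint in JOINTS:
            for metric in METRICS:
                samples = self.per_subject[metric][joint]
                e_rigid = samples["rigid"]
                e_eikpe = samples["eikpe"]
                mean_rigid = float(np.mean(e_rigid))
                mean_eikpe = float(np.mean(e_eikpe))
                if mean_rigid > 0:
                    impr = round(improvement_pct(mean_rigid, mean_eikpe))
                else:
                    impr = 0
                rows.append(
                    {
                        "joint": joint,
                        "metric": metric.upper(),
                        "rigid_mean": mean_rigid,
                        "rigid_sd": float(np.std(e_rigid, ddof=1)) if e_rigid.size > 1 else 0.0,
                        "eikpe_mean": mean_eikpe,
                        "eikpe_sd": float(np.std(e_eikpe, ddof=1)) if e_eikpe.size > 1 else 0.0,
                        "improvement_pct": impr,
                        "p_value": ranksum_test(e_eikpe, e_rigid),
                    }
                )
        return pd.DataFrame(rows)

    def improvement(self, joint: str, metric: str) -> float:
        row = self.table[(self.table.joint == joint) & (self.table.metric == metric.upper())]
        return float(row["improvement_pct"].iloc[0])

    def mean_error(self, joint: str, metric: str, method: str) -> float:
        row = self.table[(self.table.joint == joint) & (self.table.metric == metric.upper())]
        return float(row[f"{method}_mean"].iloc[0])

    def p_value(self, joint: str, metric: str) -> float:
        row = self.table[(self.table.joint == joint) & (self.table.metric == metric.upper())]
        return float(row["p_value"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        payload = self.table.to_json(orient="records", double_precision=10)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def boxplot(self, path) -> None:
        """Box plots of per-subject errors, one panel per metric."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        for ax, metric in zip(axes, METRICS):
            data, labels = [], []
            for joint in JOINTS:
                for method in METHODS:
                    data.append(self.per_subject[metric][joint][method])
                    labels.append(f"{joint}\n{method}")
            ax.boxplot(data, tick_labels=labels)
            ax.set_title(metric.upper())
            ax.set_ylabel("error (deg)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _joint_channel(joint: str) -> str:
    return f"{joint}_flexion"


def build_report(
    gt: Mapping[str, JointTrajectory],
    rigid: Mapping[str, JointTrajectory],
    eikpe: Mapping[str, JointTrajectory],
) -> EvalReport:
    """Assemble the per-joint, per-method error report across subjects.

    ``gt``, ``rigid`` and ``eikpe`` map subject keys to sagittal
    joint-angle trajectories; keys and lengths must align.
    """
    keys = list(gt)
    if set(keys) != set(rigid) or set(keys) != set(eikpe):
        raise SchemaError("subject keys of gt/rigid/eikpe do not match")
    per_subject: Dict[str, Dict[str, Dict[str, np.ndarray]]] = {
        metric: {joint: {m: np.empty(len(keys)) for m in METHODS} for joint in JOINTS}
        for metric in METRICS
    }
    estimates = {"rigid": rigid, "eikpe": eikpe}
    for si, key in enumerate(keys):
        for joint in JOINTS:
            channel = _joint_channel(joint)
            x = gt[key].channel(channel)
            for method, mapping in estimates.items():
                y = mapping[key].channel(channel)
                if y.size != x.size:
                    raise SchemaError(
                        f"subject {key!r}, joint {joint!r}: length mismatch {y.size} vs {x.size}"
                    )
                per_subject["rmse"][joint][method][si] = rmse(x, y)
                per_subject["rome"][joint][method][si] = abs(rome(x, y))
    return EvalReport(per_subject=per_subject, n_subjects=len(keys))
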
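"""ROC analysis of regional measures as diagnostic discriminators.

For each measure (BP_ND, SUVR, sCBF, R1) and region, the empirical ROC
curve of patients versus healthy controls summarises how well the measure
separates the groups. The area under the curve (AUC) equals the
probability that a randomly chosen patient scores on the disease side of a
randomly chosen control (ties counting one half — the Mann-Whitney
convention). The operating cutoff is the ROC point closest to the upper
left corner (perfect sensitivity and specificity).

Binding measures discriminate in the high direction (more amyloid in
disease); flow measures in the low direction (hypoperfusion in disease).
AUC standard errors use the Hanley-McNeil formula; pairwise AUC
comparisons use DeLong's test on the empirical structural components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics

from .errors import WarmPetError

__all__ = [
    "RocResult",
    "DEFAULT_DIRECTIONS",
    "roc_curve",
    "auc_sem_hanley_mcneil",
    "auc_region_panel",
    "compare_auc",
]

#: Which way each measure points in disease.
DEFAULT_DIRECTIONS = {"BP_ND": "higher", "SUVR": "higher",
                      "sCBF": "lower", "R1": "lower"}


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC curve with its AUC and operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    positive_direction: str
    # oriented scores (larger = disease) retained for DeLong comparisons
    patient_scores: np.ndarray = field(repr=False, default=None)
    control_scores: np.ndarray = field(repr=False, default=None)


def roc_curve(patient_scores, control_scores,
              positive_direction: str = "higher") -> RocResult:
    """Empirical ROC of patients versus controls.

    ``positive_direction`` states whether larger (``"higher"``) or smaller
    (``"lower"``) values indicate disease. The cutoff is the ROC point
    closest (Euclidean) to the corner (FPR 0, TPR 1), ties broken toward
    higher specificity, reported on the score scale as the midpoint between
    the two observations straddling the selected threshold.
    """
    pat = np.asarray(patient_scores, dtype=float)
    ctl = np.asarray(control_scores, dtype=float)
    if pat.size == 0 or ctl.size == 0:
        raise WarmPetError("both patient and control groups need >= 1 score")
    if not (np.all(np.isfinite(pat)) and np.all(np.isfinite(ctl))):
        raise WarmPetError("ROC scores must be finite")
    if positive_direction not in ("higher", "lower"):
        raise WarmPetError("positive_direction must be 'higher' or 'lower'")
    sign = 1.0 if positive_direction == "higher" else -1.0
    x = sign * pat  # oriented: larger = disease
    y = sign * ctl

    labels = np.concatenate([np.ones_like(x), np.zeros_like(y)])
    scores = np.concatenate([x, y])
    fpr, tpr, thr = metrics.roc_curve(labels, scores)
    auc = float(metrics.auc(fpr, tpr))

    dist2 = fpr ** 2 + (1.0 - tpr) ** 2
    # lexsort: among distance ties prefer the lower FPR (higher specificity)
    order = np.lexsort((fpr, dist2))
    best = int(order[0])
    cutoff_internal = _midpoint_cutoff(scores, thr[best])
    return RocResult(
        thresholds=sign * thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        cutoff=float(sign * cutoff_internal),
        sens_at_cutoff=float(tpr[best]),
        spec_at_cutoff=float(1.0 - fpr[best]),
        positive_direction=positive_direction,
        patient_scores=x,
        control_scores=y,
    )


def _midpoint_cutoff(scores: np.ndarray, threshold: float) -> float:
    """Midpoint between the lowest observation called positive at the
    threshold and the highest called negative; the threshold itself when
    no observation falls on one side."""
    above = scores[scores >= threshold]
    below = scores[scores < threshold]
    if above.size == 0 or below.size == 0:
        return float(threshold) if np.isfinite(threshold) else float(scores.max())
    return float((above.min() + below.max()) / 2.0)


def auc_sem_hanley_mcneil(auc: float, n_patients: int, n_controls: int) -> float:
    """Hanley-McNeil standard error of an empirical AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc ** 2 / (1.0 + auc)
    var = (auc * (1.0 - auc)
           + (n_patients - 1) * (q1 - auc ** 2)
           + (n_controls - 1) * (q2 - auc ** 2)) / (n_patients * n_controls)
    return float(np.sqrt(max(var, 0.0)))


def auc_region_panel(table: pd.DataFrame, patient_group: str,
                     hc_group: str = "HC",
                     directions: dict | None = None) -> pd.DataFrame:
    """AUC +/- SEM per region x measure for one patient group vs controls.

    Returns a DataFrame with columns (region, measure, direction, auc, sem,
    cutoff, sens, spec, n_patients, n_controls).
    """
    directions = {**DEFAULT_DIRECTIONS, **(directions or {})}
    rows = []
    for region in table["region"].unique():
        for measure in table["measure"].unique():
            sel = (table["region"] == region) & (table["measure"] == measure)
            pat = table.loc[sel & (table["group"] == patient_group), "value"]
            ctl = table.loc[sel & (table["group"] == hc_group), "value"]
            direction = directions.get(measure, "higher")
            res = roc_curve(pat.to_numpy(), ctl.to_numpy(), direction)
            rows.append({
                "region": region, "measure": measure, "direction": direction,
                "auc": res.auc,
                "sem": auc_sem_hanley_mcneil(res.auc, len(pat), len(ctl)),
                "cutoff": res.cutoff, "sens": res.sens_at_cutoff,
                "spec": res.spec_at_cutoff,
                "n_patients": len(pat), "n_controls": len(ctl),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DeLong AUC comparison
# ---------------------------------------------------------------------------

def _structural_components(patients: np.ndarray, controls: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Mann-Whitney kernel means: for each patient the fraction of controls
    it outranks (ties = 1/2), and symmetrically for each control."""
    diff = patients[:, None] - controls[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def compare_auc(result_a: RocResult, result_b: RocResult,
                paired: bool = True) -> tuple[float, float]:
    """DeLong test of the difference between two empirical AUCs.

    ``paired=True`` requires the two results to score the same subjects
    (equal group sizes, matched order) and accounts for the covariance of
    the AUCs; ``paired=False`` treats them as independent samples.
    Returns ``(auc_a - auc_b, two-sided p)``.
    """
    xa, ya = result_a.patient_scores, result_a.control_scores
    xb, yb = result_b.patient_scores, result_b.control_scores
    v10a, v01a, auc_a = _structural_components(xa, ya)
    v10b, v01b, auc_b = _structural_components(xb, yb)
    diff = auc_a - auc_b
    if paired:
        if len(xa) != len(xb) or len(ya) != len(yb):
            raise WarmPetError(
                "paired AUC comparison requires the same subjects under both "
                f"measures: got {len(xa)}/{len(ya)} vs {len(xb)}/{len(yb)}"
            )
        m, n = len(xa), len(ya)
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
               + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    else:
        var = (np.var(v10a, ddof=1) / len(xa) + np.var(v01a, ddof=1) / len(ya)
               + np.var(v10b, ddof=1) / len(xb) + np.var(v01b, ddof=1) / len(yb))
    if var <= 0:
        return float(diff), 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(diff), float(p)
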
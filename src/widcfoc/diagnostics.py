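"""Exact diagnostic statistics and stratified evaluation.

Sensitivity and specificity are exact binomial estimates x/n with
two-sided Clopper-Pearson confidence intervals from beta quantiles:

    lower = BetaInv(alpha/2;     x,     n - x + 1)   (0 when x = 0)
    upper = BetaInv(1 - alpha/2; x + 1, n - x)       (1 when x = n)

ROC curves are empirical with tied scores grouped; AUC is the
normalized Mann-Whitney U statistic (concordant pairs + half ties).
The paired-difference interval is the standard paired-t form
Delta +- t_{alpha/2, N-1} * SD / sqrt(N).  Stratified evaluation joins
subject covariates, score calls and contamination groups, and computes
each marker's sensitivity/specificity per stratum (risk class, gDNA
contamination group, time to diagnosis, stage, BRCA status,
CA125-negative subset).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragment_qc import ContaminationCall
from .scoring import EXCLUDED, NEGATIVE, POSITIVE, ScoreCall
from .simulate.cohort import SubjectRecord

__all__ = [
    "DiagnosticEstimate",
    "PairedDifferenceCI",
    "StratumSpec",
    "clopper_pearson",
    "sens_spec",
    "roc_curve",
    "auc_mann_whitney",
    "paired_difference_ci",
    "paired_concordance",
    "evaluate_strata",
    "stage_detection_table",
    "write_estimates",
]


@dataclasses.dataclass(frozen=True)
class DiagnosticEstimate:
    stratum: str
    metric: str  # sensitivity | specificity
    x: int
    n: int
    ci_lower: float
    ci_upper: float
    level: float = 0.95
    n_excluded: int = 0
    marker: str = ""

    @property
    def point(self) -> float:
        return self.x / self.n

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError("need 0 <= x <= n")
        if not self.ci_lower <= self.x / self.n <= self.ci_upper:
            raise ValueError("point estimate outside its CI")

    def display(self) -> str:
        """'80.0% (56.3%-94.3%)' — percentages to one decimal."""
        return (
            f"{100 * self.point:.1f}% "
            f"({100 * self.ci_lower:.1f}%-{100 * self.ci_upper:.1f}%)"
        )


def clopper_pearson(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence bounds for x successes in n trials."""
    if n < 1 or not 0 <= x <= n:
        raise ValueError("need n >= 1 and 0 <= x <= n")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lower, upper


def _binary(pred: str | bool) -> bool:
    if isinstance(pred, bool):
        return pred
    if pred == POSITIVE:
        return True
    if pred == NEGATIVE:
        return False
    raise ValueError(f"not a binary prediction: {pred!r}")


def sens_spec(
    predictions: Sequence[str | bool],
    truth_labels: Sequence[bool],
    level: float = 0.95,
    stratum: str = "",
    marker: str = "",
) -> dict[str, DiagnosticEstimate | None]:
    """Sensitivity over cases and specificity over controls with exact CIs.

    ``truth_labels`` is True for cancer.  Predictions equal to
    ``"excluded"`` are dropped (count recorded on the estimates).  A
    side with no subjects yields None for that metric.
    """
    if len(predictions) != len(truth_labels):
        raise ValueError("predictions and labels must align")
    kept = [
        (_binary(p), bool(t))
        for p, t in zip(predictions, truth_labels)
        if p != EXCLUDED
    ]
    n_excluded = len(predictions) - len(kept)
    out: dict[str, DiagnosticEstimate | None] = {}
    for metric, label in (("sensitivity", True), ("specificity", False)):
        side = [p for p, t in kept if t is label]
        if not side:
            out[metric] = None
            continue
        x = sum(1 for p in side if p is label)  # TP among cases / TN among controls
        lo, hi = clopper_pearson(x, len(side), level)
        out[metric] = DiagnosticEstimate(
            stratum, metric, x, len(side), lo, hi, level, n_excluded, marker
        )
    return out


def auc_mann_whitney(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC as the normalized count of concordant case-control pairs (+1/2 ties)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    cases, controls = s[y], s[~y]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need both cases and controls")
    greater = (cases[:, None] > controls[None, :]).sum()
    ties = (cases[:, None] == controls[None, :]).sum()
    return float((greater + 0.5 * ties) / (cases.size * controls.size))


def roc_curve(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[pd.DataFrame, float]:
    """Empirical ROC with tied scores grouped, plus the Mann-Whitney AUC.

    Returns a frame of (threshold, fpr, tpr) where a sample is positive
    iff its score is strictly above the threshold, evaluated at every
    unique observed score (plus -inf for the (1, 1) corner).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.all() or (~y).all():
        raise ValueError("ROC needs both classes")
    thresholds = np.concatenate([[-np.inf], np.unique(s)])
    rows = []
    for t in thresholds:
        pos = s > t
        rows.append(
            {
                "threshold": t,
                "fpr": float(np.mean(pos[~y])),
                "tpr": float(np.mean(pos[y])),
            }
        )
    return pd.DataFrame(rows), auc_mann_whitney(s, y)


@dataclasses.dataclass(frozen=True)
class PairedDifferenceCI:
    delta: float  # mean per-subject difference
    sd: float  # sample SD of the differences
    n: int
    t_crit: float
    lower: float
    upper: float
    level: float = 0.95


def paired_difference_ci(
    diff_scores: Sequence[float], level: float = 0.95, sd_is_se: bool = False
) -> PairedDifferenceCI:
    """Paired-t interval Delta +- t_{alpha/2, N-1} * SD / sqrt(N).

    With ``sd_is_se`` the dispersion term is treated as a standard error
    directly (no sqrt(N) division) — an alternative reading of the
    published formula; the default is the standard paired-t interval.
    """
    d = np.asarray(diff_scores, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 difference scores")
    delta = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    t_crit = float(stats.t.ppf(1 - (1 - level) / 2, d.size - 1))
    half = t_crit * (sd if sd_is_se else sd / math.sqrt(d.size))
    return PairedDifferenceCI(
        delta, sd, int(d.size), t_crit, delta - half, delta + half, level
    )


def paired_concordance(
    day_values: Sequence[float],
    night_values: Sequence[float],
    split_at: float = 1.0,
    call_threshold: float | None = None,
) -> dict[str, object]:
    """Day/night agreement, split at a fully-methylated-read percentage.

    Pearson correlation is computed separately for pairs whose mean
    value is above the split and at/below it (undefined with < 3 pairs
    or a constant vector, reported as None).  If ``call_threshold`` is
    given, the number of discordant positive/negative calls across the
    pair is also reported.
    """
    day = np.asarray(day_values, dtype=float)
    night = np.asarray(night_values, dtype=float)
    if day.shape != night.shape:
        raise ValueError("paired vectors must have equal length")
    mean = (day + night) / 2.0

    def _r(mask: np.ndarray) -> float | None:
        if mask.sum() < 3:
            return None
        a, b = day[mask], night[mask]
        if np.std(a) == 0 or np.std(b) == 0:
            return None
        return float(stats.pearsonr(a, b)[0])

    out: dict[str, object] = {
        "r_above": _r(mean > split_at),
        "r_at_or_below": _r(mean <= split_at),
        "n_above": int((mean > split_at).sum()),
        "n_at_or_below": int((mean <= split_at).sum()),
    }
    if call_threshold is not None:
        flips = (day > call_threshold) != (night > call_threshold)
        out["n_discordant_calls"] = int(flips.sum())
    return out


@dataclasses.dataclass(frozen=True)
class StratumSpec:
    """Composable filters over subjects and contamination calls.

    ``None`` disables a filter.  ``high_risk`` selects grade 2/3 cancers
    (controls always pass case-only filters so specificity stays
    estimable within the stratum).
    """

    name: str
    high_risk: bool | None = None
    gdna_group: str | None = None  # lower_contamination | higher_contamination
    max_days_to_diagnosis: int | None = None  # e.g. 365 for '<1 year'
    stage: str | None = None
    brca: str | None = None  # "BRCA1/2" matches either carrier status
    ca125_negative_only: bool = False

    def admits(
        self,
        subject: SubjectRecord,
        score: ScoreCall,
        contamination: ContaminationCall | None,
    ) -> bool:
        if self.gdna_group is not None:
            if contamination is None or contamination.group != self.gdna_group:
                return False
        if self.ca125_negative_only and score.ca125_status != NEGATIVE:
            return False
        if subject.is_case:
            if self.high_risk is not None and subject.high_risk != self.high_risk:
                return False
            if self.max_days_to_diagnosis is not None:
                dtd = subject.days_to_diagnosis
                if dtd is None or dtd >= self.max_days_to_diagnosis:
                    return False
            if self.stage is not None and subject.stage != self.stage:
                return False
            if self.brca is not None:
                if self.brca == "BRCA1/2":
                    if subject.brca_status not in ("BRCA1", "BRCA2"):
                        return False
                elif subject.brca_status != self.brca:
                    return False
        return True


MARKERS = ("wid_cfoc", "ca125", "combined")


def _marker_prediction(score: ScoreCall, marker: str) -> str:
    if marker == "wid_cfoc":
        return POSITIVE if score.wid_cfoc_positive else NEGATIVE
    if marker == "ca125":
        return score.ca125_status
    if marker == "combined":
        return score.combined_status
    raise ValueError(f"unknown marker {marker!r}")


def evaluate_strata(
    subjects: Sequence[SubjectRecord],
    scores: Mapping[str, ScoreCall],
    contamination: Mapping[str, ContaminationCall] | None,
    strata: Sequence[StratumSpec],
    level: float = 0.95,
    markers: Sequence[str] = MARKERS,
) -> list[DiagnosticEstimate]:
    """One estimate per stratum x marker x metric.

    Samples without a score (e.g. failed mapping-rate QC) are skipped;
    CA125-excluded samples drop out of the CA125/combined estimates
    only.  An empty stratum contributes no rows rather than failing.
    """
    estimates: list[DiagnosticEstimate] = []
    for spec in strata:
        members = [
            (s, scores[s.subject_id])
            for s in subjects
            if s.subject_id in scores
            and spec.admits(
                s,
                scores[s.subject_id],
                (contamination or {}).get(s.subject_id),
            )
        ]
        if not members:
            continue
        for marker in markers:
            preds = [_marker_prediction(sc, marker) for _, sc in members]
            labels = [s.is_case for s, _ in members]
            for est in sens_spec(
                preds, labels, level, stratum=spec.name, marker=marker
            ).values():
                if est is not None:
                    estimates.append(est)
    return estimates


def stage_detection_table(
    subjects: Sequence[SubjectRecord],
    scores: Mapping[str, ScoreCall],
    marker: str = "wid_cfoc",
) -> pd.DataFrame:
    """Detected/total cancer counts per FIGO stage (I-IV, unknown)."""
    rows = []
    for stage in ("I", "II", "III", "IV", "unknown"):
        cases = [
            s
            for s in subjects
            if s.is_case and s.stage == stage and s.subject_id in scores
        ]
        detected = sum(
            1
            for s in cases
            if _marker_prediction(scores[s.subject_id], marker) == POSITIVE
        )
        rows.append({"stage": stage, "detected": detected, "total": len(cases)})
    return pd.DataFrame(rows)


def write_estimates(
    estimates: Iterable[DiagnosticEstimate], path: str | Path
) -> None:
    rows = [
        {
            "stratum": e.stratum,
            "marker": e.marker,
            "metric": e.metric,
            "x": e.x,
            "n": e.n,
            "point_pct": round(100 * e.point, 1),
            "ci_lower_pct": round(100 * e.ci_lower, 1),
            "ci_upper_pct": round(100 * e.ci_upper, 1),
            "n_excluded": e.n_excluded,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
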
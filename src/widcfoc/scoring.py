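"""WID-cfOC threshold calibration and sample scoring, with CA125 integration.

The WID-cfOC score is a rule over the three per-region percentages of
fully methylated reads: during calibration, each region receives the
cutoff whose specificity on calibration controls is closest to a target
(default 97%); a sample is score-positive if *any* region's percentage
is strictly above its threshold, and negative only when all regions are
at or below theirs.  Thresholds calibrated on one cohort transfer
unchanged to another (diagnostic -> early-detection).

CA125 is dichotomized at the clinical 35 U/mL cutoff; when no serum
measurement exists at the index date, the temporal imputation rules
apply: an abnormal value *before* the index sample implies positive, a
normal value *after* implies negative, anything else is excluded.  The
combined marker is the OR of the two calls.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionThreshold",
    "ThresholdSet",
    "ScoreCall",
    "CA125Record",
    "calibrate_threshold",
    "calibrate_threshold_set",
    "score_sample",
    "ca125_classify",
    "ca125_impute",
    "combined_score",
    "score_cohort",
    "write_scores",
]

CA125_CUTOFF = 35.0  # U/mL, clinical abnormality threshold
POSITIVE, NEGATIVE, EXCLUDED = "positive", "negative", "excluded"


@dataclasses.dataclass(frozen=True)
class RegionThreshold:
    region_id: str
    threshold_pct: float
    achieved_specificity: float
    achieved_sensitivity: float | None

    def __post_init__(self) -> None:
        if self.threshold_pct < 0:
            raise ValueError("threshold must be >= 0")
        if not 0.0 <= self.achieved_specificity <= 1.0:
            raise ValueError("specificity outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class ThresholdSet:
    thresholds: tuple[RegionThreshold, ...]
    target_specificity: float = 0.97
    calibration_set_id: str = ""

    def __getitem__(self, region_id: str) -> RegionThreshold:
        for t in self.thresholds:
            if t.region_id == region_id:
                return t
        raise KeyError(region_id)

    @property
    def region_ids(self) -> tuple[str, ...]:
        return tuple(t.region_id for t in self.thresholds)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_specificity": self.target_specificity,
            "calibration_set_id": self.calibration_set_id,
            "regions": [dataclasses.asdict(t) for t in self.thresholds],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            thresholds=tuple(RegionThreshold(**r) for r in payload["regions"]),
            target_specificity=payload["target_specificity"],
            calibration_set_id=payload.get("calibration_set_id", ""),
        )


@dataclasses.dataclass
class ScoreCall:
    sample_id: str
    region_pcts: dict[str, float | None]  # None = no amplification
    wid_cfoc_positive: bool
    ca125_status: str = EXCLUDED  # positive | negative | excluded
    all_regions_undefined: bool = False  # negative-by-absence flag

    @property
    def combined_status(self) -> str:
        return combined_score(self.wid_cfoc_positive, self.ca125_status)


@dataclasses.dataclass(frozen=True)
class CA125Record:
    measurements: tuple[tuple[datetime.date, float], ...]
    index_date: datetime.date

    def __post_init__(self) -> None:
        if any(v < 0 for _, v in self.measurements):
            raise ValueError("CA125 values must be >= 0")


def calibrate_threshold(
    control_pcts: Sequence[float],
    case_pcts: Sequence[float] = (),
    target_specificity: float = 0.97,
    region_id: str = "",
) -> RegionThreshold:
    """Pick the per-region cutoff whose control specificity is closest to target.

    Candidate cutoffs are the sorted unique observed values (controls
    and cases pooled); a sample is positive iff its value is *strictly
    above* the cutoff, so specificity at cutoff t is
    ``#{controls <= t} / n_controls`` — achievable specificities come in
    steps of 1/n_controls.  Ties on |specificity - target| break toward
    the higher specificity, remaining ties toward the lower cutoff.
    """
    controls = np.asarray([v for v in control_pcts if v is not None], dtype=float)
    if controls.size == 0:
        raise ValueError("calibration requires at least one control value")
    cases = np.asarray([v for v in case_pcts if v is not None], dtype=float)
    if np.any(controls < 0) or np.any(cases < 0) or not (
        np.all(np.isfinite(controls)) and np.all(np.isfinite(cases))
    ):
        raise ValueError("percentages must be finite and >= 0")
    candidates = np.unique(np.concatenate([controls, cases]))
    best: tuple[float, float, float] | None = None  # (|gap|, -spec, threshold)
    best_spec = 0.0
    for t in candidates:
        spec = float(np.mean(controls <= t))
        key = (abs(spec - target_specificity), -spec, float(t))
        if best is None or key < best:
            best, best_spec = key, spec
    threshold = best[2]
    sens = float(np.mean(cases > threshold)) if cases.size else None
    return RegionThreshold(region_id, threshold, best_spec, sens)


def calibrate_threshold_set(
    control_pcts: Mapping[str, Sequence[float]],
    case_pcts: Mapping[str, Sequence[float]],
    target_specificity: float = 0.97,
    calibration_set_id: str = "",
) -> ThresholdSet:
    """Calibrate every region of a panel; region order follows ``control_pcts``."""
    thresholds = tuple(
        calibrate_threshold(
            control_pcts[rid], case_pcts.get(rid, ()), target_specificity, rid
        )
        for rid in control_pcts
    )
    return ThresholdSet(thresholds, target_specificity, calibration_set_id)


def score_sample(
    region_pcts: Mapping[str, float | None],
    thresholds: ThresholdSet,
    sample_id: str = "",
) -> ScoreCall:
    """WID-cfOC call: positive iff any defined region is above its threshold.

    Equality with the threshold is negative (the rule is strictly
    'above').  Regions with no amplification (None) are skipped; a
    sample undefined in *all* regions is negative-by-absence and flagged
    so downstream analyses can exclude it instead.
    """
    positive = False
    any_defined = False
    for rid, pct in region_pcts.items():
        if pct is None:
            continue
        any_defined = True
        try:
            t = thresholds[rid]
        except KeyError:
            raise ValueError(f"no calibrated threshold for region {rid!r}") from None
        if pct > t.threshold_pct:
            positive = True
    return ScoreCall(
        sample_id=sample_id,
        region_pcts=dict(region_pcts),
        wid_cfoc_positive=positive,
        all_regions_undefined=not any_defined,
    )


def ca125_classify(value: float) -> str:
    """Dichotomize a serum CA125 value at the 35 U/mL abnormality cutoff."""
    if value < 0:
        raise ValueError("CA125 cannot be negative")
    return POSITIVE if value >= CA125_CUTOFF else NEGATIVE


def ca125_impute(record: CA125Record) -> str:
    """CA125 status at the index date, with temporal imputation.

    A measurement on the index date is classified directly.  Otherwise
    the nearest measurement decides: abnormal *before* the index date
    stays abnormal (positive); normal *after* the index date was already
    normal at index (negative).  A normal value only before, an abnormal
    value only after, or no measurement at all leaves the index status
    unknowable -> excluded.
    """
    same_day = [v for d, v in record.measurements if d == record.index_date]
    if same_day:
        return ca125_classify(same_day[0])
    before = [
        (d, v) for d, v in record.measurements if d < record.index_date
    ]
    after = [(d, v) for d, v in record.measurements if d > record.index_date]
    if before:
        nearest_before = max(before, key=lambda dv: dv[0])
        if ca125_classify(nearest_before[1]) == POSITIVE:
            return POSITIVE
    if after:
        nearest_after = min(after, key=lambda dv: dv[0])
        if ca125_classify(nearest_after[1]) == NEGATIVE:
            return NEGATIVE
    return EXCLUDED


def combined_score(wid_positive: bool, ca125_status: str) -> str:
    """OR of the methylation and CA125 calls; CA125-excluded stays excluded."""
    if ca125_status == EXCLUDED:
        return EXCLUDED
    if ca125_status not in (POSITIVE, NEGATIVE):
        raise ValueError(f"bad CA125 status {ca125_status!r}")
    return POSITIVE if (wid_positive or ca125_status == POSITIVE) else NEGATIVE


def score_cohort(
    region_pcts_by_sample: Mapping[str, Mapping[str, float | None]],
    thresholds: ThresholdSet,
    ca125_records: Mapping[str, CA125Record] | None = None,
) -> list[ScoreCall]:
    calls = []
    for sid, pcts in region_pcts_by_sample.items():
        call = score_sample(pcts, thresholds, sample_id=sid)
        if ca125_records and sid in ca125_records:
            call.ca125_status = ca125_impute(ca125_records[sid])
        calls.append(call)
    return calls


def write_scores(calls: Sequence[ScoreCall], path: str | Path) -> None:
    region_ids = sorted({rid for c in calls for rid in c.region_pcts})
    rows = []
    for c in calls:
        row: dict[str, object] = {"sample_id": c.sample_id}
        for rid in region_ids:
            v = c.region_pcts.get(rid)
            row[f"pct_{rid}"] = "" if v is None else v
        row["wid_cfoc"] = POSITIVE if c.wid_cfoc_positive else NEGATIVE
        row["ca125"] = c.ca125_status
        row["combined"] = c.combined_status
        row["all_regions_undefined"] = c.all_regions_undefined
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
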
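"""Synthetic case-control cohorts for the diagnostic and early-detection studies.

Each subject carries the covariates the downstream analyses stratify on
(grade, stage, BRCA status, sampling vs diagnosis dates, CA125 history)
plus two pieces of simulation ground truth invisible to the analysis:
the circulating tumor fraction and the amount of high-molecular-weight
genomic DNA (gDNA) contaminating the plasma.

Default designs mirror the two published cohorts: a diagnostic set of 41
controls (4 healthy volunteers + 37 benign pelvic pathologies) and 27
ovarian cancers of which 20 are high risk (grade 2/3), and an
early-detection set of 29 matched case-control pairs with heavy gDNA
contamination from long-term archival storage.  CA125 is log-normal per
group, calibrated so medians/IQRs land on the published values
(controls 14 [10-22] U/mL, cancers 152 [42-296] U/mL in the diagnostic
set; 12 [9-14] and 34 [12-69] in the early-detection set).
"""

from __future__ import annotations

import dataclasses
import datetime
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SubjectRecord",
    "GroupDesign",
    "CohortDesign",
    "simulate_cohort",
    "diagnostic_design",
    "early_detection_design",
    "precision_design",
    "write_sample_sheet",
    "write_ca125_table",
]

GROUPS = ("control_healthy", "control_benign", "cancer")

# IQR half-width in standard normal units: quartiles sit at +-0.6745 sigma
_Z_IQR = 0.6744897501960817


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and interquartile range."""
    mu = float(np.log(median))
    sigma = float(np.log(q3 / q1) / (2 * _Z_IQR))
    return mu, sigma


@dataclasses.dataclass
class SubjectRecord:
    subject_id: str
    group: str  # control_healthy | control_benign | cancer
    histology: str = ""
    grade: str = "unknown"  # 1 | 2 | 3 | unknown
    stage: str = "unknown"  # I | II | III | IV | unknown
    brca_status: str = "unknown"  # BRCA1 | BRCA2 | wildtype | unknown
    sample_date: datetime.date = datetime.date(2020, 1, 1)
    diagnosis_date: datetime.date | None = None
    ca125_history: list[tuple[datetime.date, float]] = dataclasses.field(
        default_factory=list
    )
    tumor_fraction_truth: float = 0.0
    gdna_contamination_truth: float = 0.0
    #: per-subject rate of coordinately methylated background alleles —
    #: the biological noise floor of the fully-methylated-read readout
    epimutation_rate_truth: float = 0.0
    match_id: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.group != "cancer" and self.tumor_fraction_truth != 0.0:
            raise ValueError("controls must have tumor_fraction_truth == 0")
        if not 0.0 <= self.tumor_fraction_truth <= 1.0:
            raise ValueError("tumor_fraction_truth must lie in [0, 1]")
        if self.gdna_contamination_truth < 0:
            raise ValueError("gdna_contamination_truth must be >= 0")

    @property
    def is_case(self) -> bool:
        return self.group == "cancer"

    @property
    def high_risk(self) -> bool:
        """High-risk disease = grade 2 or 3 (all others low/unknown risk)."""
        return self.grade in ("2", "3")

    @property
    def days_to_diagnosis(self) -> int | None:
        if self.diagnosis_date is None:
            return None
        return (self.diagnosis_date - self.sample_date).days


@dataclasses.dataclass
class GroupDesign:
    """Per-group counts and distributions."""

    n: int
    ca125_median: float
    ca125_q1: float
    ca125_q3: float
    # cases only ------------------------------------------------------
    n_high_risk: int = 0  # grade 2/3 cases
    grade_counts: dict[str, int] | None = None  # overrides n_high_risk split
    stage_counts: dict[str, int] | None = None
    brca_counts: dict[str, int] | None = None
    histologies: tuple[str, ...] = ()
    tumor_fraction_median: float = 0.0
    tumor_fraction_sigma: float = 1.0
    # plasma quality --------------------------------------------------
    gdna_median: float = 0.1
    gdna_sigma: float = 0.5
    # background noise floor ------------------------------------------
    epimutation_median: float = 0.002
    epimutation_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be non-negative")
        if self.n_high_risk > self.n:
            raise ValueError("n_high_risk cannot exceed group size")


@dataclasses.dataclass
class CohortDesign:
    name: str
    groups: dict[str, GroupDesign]
    ca125_available_frac: dict[str, float] = dataclasses.field(default_factory=dict)
    # cases: days from index sample to diagnosis, log-normal
    days_to_diagnosis_median: float = 0.0
    days_to_diagnosis_sigma: float = 1.0
    study_start: datetime.date = datetime.date(2019, 9, 1)
    matched: bool = False


def diagnostic_design() -> CohortDesign:
    """Pelvic-mass diagnostic cohort: 41 controls, 27 cancers, 20 high risk."""
    return CohortDesign(
        name="diagnostic",
        groups={
            "control_healthy": GroupDesign(
                n=4, ca125_median=14, ca125_q1=10, ca125_q3=22
            ),
            "control_benign": GroupDesign(
                n=37, ca125_median=14, ca125_q1=10, ca125_q3=22
            ),
            "cancer": GroupDesign(
                n=27,
                ca125_median=152,
                ca125_q1=42,
                ca125_q3=296,
                n_high_risk=20,
                grade_counts={"1": 5, "2": 1, "3": 19, "unknown": 2},
                stage_counts={"I": 3, "II": 1, "III": 10, "IV": 7, "unknown": 6},
                histologies=("HGSOC",) * 19 + ("LGSOC",) * 3
                + ("endometrioid", "mucinous") + ("other",) * 3,
                tumor_fraction_median=0.02,
                tumor_fraction_sigma=1.0,
            ),
        },
        ca125_available_frac={"control": 39 / 41, "cancer": 24 / 27},
        days_to_diagnosis_median=0.0,  # sampled at clinical diagnosis
    )


def early_detection_design() -> CohortDesign:
    """Pre-diagnosis screening cohort: 29 matched case-control pairs.

    Archival plasma, so gDNA contamination is high and variable; tumor
    fractions are an order of magnitude below the diagnostic setting.
    """
    return CohortDesign(
        name="early_detection",
        groups={
            "control_healthy": GroupDesign(
                n=29,
                ca125_median=12,
                ca125_q1=9,
                ca125_q3=14,
                brca_counts={"BRCA1": 18, "BRCA2": 6, "wildtype": 4, "unknown": 1},
                gdna_median=1.0,
                gdna_sigma=1.0,
            ),
            "control_benign": GroupDesign(n=0, ca125_median=12, ca125_q1=9, ca125_q3=14),
            "cancer": GroupDesign(
                n=29,
                ca125_median=34,
                ca125_q1=12,
                ca125_q3=69,
                n_high_risk=27,
                grade_counts={"1": 1, "3": 27, "unknown": 1},
                stage_counts={"I": 7, "II": 2, "III": 15, "IV": 2, "unknown": 3},
                brca_counts={"BRCA1": 17, "BRCA2": 5, "wildtype": 6, "unknown": 1},
                histologies=("HGSOC",) * 22 + ("endometrioid",) * 4 + ("other",) * 3,
                tumor_fraction_median=0.002,
                tumor_fraction_sigma=1.0,
                gdna_median=1.0,
                gdna_sigma=1.0,
            ),
        },
        ca125_available_frac={"control": 22 / 29, "cancer": 24 / 29},
        days_to_diagnosis_median=600.0,
        days_to_diagnosis_sigma=1.0,
        matched=True,
    )


def precision_design(n_pairs: int = 15) -> CohortDesign:
    """Day/night analytical-precision cohort: cancer cases sampled twice."""
    return CohortDesign(
        name="precision",
        groups={
            "control_healthy": GroupDesign(n=0, ca125_median=14, ca125_q1=10, ca125_q3=22),
            "control_benign": GroupDesign(n=0, ca125_median=14, ca125_q1=10, ca125_q3=22),
            "cancer": GroupDesign(
                n=n_pairs,
                ca125_median=152,
                ca125_q1=42,
                ca125_q3=296,
                n_high_risk=n_pairs,
                tumor_fraction_median=0.02,
                tumor_fraction_sigma=1.0,
            ),
        },
    )


def _allocate(counts: dict[str, int] | None, n: int, default: str) -> list[str]:
    if not counts:
        return [default] * n
    out: list[str] = []
    for key, k in counts.items():
        out.extend([key] * k)
    if len(out) > n:
        raise ValueError("category counts exceed group size")
    out.extend([default] * (n - len(out)))
    return out


def simulate_cohort(design: CohortDesign, seed: int = 0) -> list[SubjectRecord]:
    """Draw a cohort matching ``design`` exactly in all category counts.

    Group sizes, grade/stage/BRCA counts and the number of high-risk
    cases are deterministic; CA125 values, tumor fractions, gDNA
    contamination and days-to-diagnosis are random but seeded.
    """
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    idx = 0
    for group in GROUPS:
        g = design.groups.get(group)
        if g is None or g.n == 0:
            continue
        mu, sigma = lognormal_from_median_iqr(g.ca125_median, g.ca125_q1, g.ca125_q3)
        ca125 = np.exp(rng.normal(mu, sigma, size=g.n))
        if group == "cancer":
            grades = _allocate(
                g.grade_counts
                or {"3": g.n_high_risk, "1": g.n - g.n_high_risk},
                g.n,
                "unknown",
            )
            n_hr = sum(1 for gr in grades if gr in ("2", "3"))
            if g.grade_counts is None and n_hr != g.n_high_risk:  # pragma: no cover
                raise AssertionError("high-risk allocation mismatch")
            stages = _allocate(g.stage_counts, g.n, "unknown")
            brcas = _allocate(g.brca_counts, g.n, "unknown")
            hists = list(g.histologies) + ["unknown"] * (g.n - len(g.histologies))
            rng.shuffle(stages)
            rng.shuffle(brcas)
            tf = np.exp(
                rng.normal(np.log(max(g.tumor_fraction_median, 1e-12)),
                           g.tumor_fraction_sigma, size=g.n)
            )
            tf = np.clip(tf, 0.0, 1.0)
        else:
            grades = ["unknown"] * g.n
            stages = ["unknown"] * g.n
            hists = ["healthy" if group == "control_healthy" else "benign"] * g.n
            if g.brca_counts:
                brcas = _allocate(g.brca_counts, g.n, "unknown")
                rng.shuffle(brcas)
            else:
                brcas = ["unknown"] * g.n
            tf = np.zeros(g.n)
        gdna = np.exp(rng.normal(np.log(max(g.gdna_median, 1e-12)), g.gdna_sigma, g.n))
        epimut = np.clip(
            np.exp(
                rng.normal(
                    np.log(max(g.epimutation_median, 1e-12)), g.epimutation_sigma, g.n
                )
            ),
            0.0,
            1.0,
        )
        avail_key = "cancer" if group == "cancer" else "control"
        p_avail = design.ca125_available_frac.get(avail_key, 1.0)
        n_avail = int(round(p_avail * g.n))
        avail = np.zeros(g.n, dtype=bool)
        avail[rng.choice(g.n, size=n_avail, replace=False)] = True
        for j in range(g.n):
            sample_date = design.study_start + datetime.timedelta(
                days=int(rng.integers(0, 365))
            )
            diagnosis_date = None
            if group == "cancer":
                if design.days_to_diagnosis_median > 0:
                    dtd = int(
                        np.exp(
                            rng.normal(
                                np.log(design.days_to_diagnosis_median),
                                design.days_to_diagnosis_sigma,
                            )
                        )
                    )
                else:
                    dtd = 0
                diagnosis_date = sample_date + datetime.timedelta(days=max(dtd, 0))
            history: list[tuple[datetime.date, float]] = []
            if avail[j]:
                history.append((sample_date, float(ca125[j])))
            else:
                # health-record measurement displaced from the index sample
                offset = int(rng.integers(30, 300)) * (1 if rng.random() < 0.5 else -1)
                history.append(
                    (sample_date + datetime.timedelta(days=offset), float(ca125[j]))
                )
            subjects.append(
                SubjectRecord(
                    subject_id=f"{design.name[:4].upper()}{idx:04d}",
                    group=group,
                    histology=hists[j],
                    grade=grades[j],
                    stage=stages[j],
                    brca_status=brcas[j],
                    sample_date=sample_date,
                    diagnosis_date=diagnosis_date,
                    ca125_history=history,
                    tumor_fraction_truth=float(tf[j]),
                    gdna_contamination_truth=float(gdna[j]),
                    epimutation_rate_truth=float(epimut[j]),
                )
            )
            idx += 1
    if design.matched:
        cases = [s for s in subjects if s.is_case]
        controls = [s for s in subjects if not s.is_case]
        for c, k in zip(cases, controls):
            c.match_id, k.match_id = k.subject_id, c.subject_id
    return subjects


def write_sample_sheet(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "histology": s.histology,
            "grade": s.grade,
            "stage": s.stage,
            "brca_status": s.brca_status,
            "sample_date": s.sample_date.isoformat(),
            "diagnosis_date": s.diagnosis_date.isoformat() if s.diagnosis_date else "",
            "match_id": s.match_id or "",
            "tumor_fraction_truth": s.tumor_fraction_truth,
            "gdna_contamination_truth": s.gdna_contamination_truth,
            "epimutation_rate_truth": s.epimutation_rate_truth,
        }
        for s in subjects
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_ca125_table(subjects: Sequence[SubjectRecord], path: str | Path) -> None:
    rows = [
        {"subject_id": s.subject_id, "date": d.isoformat(), "value": v}
        for s in subjects
        for d, v in s.ca125_history
    ]
    pd.DataFrame(rows, columns=["subject_id", "date", "value"]).to_csv(
        path, sep="\t", index=False
    )
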
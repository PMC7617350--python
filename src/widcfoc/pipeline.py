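"""End-to-end workflows: simulate -> align/call -> calibrate -> score -> evaluate.

Two named study scenarios are provided:

* **diagnostic**: calibrate per-region thresholds on the diagnostic
  cohort at the target specificity, then evaluate the methylation
  score, CA125 and their combination on the same cohort;
* **early-detection transfer**: apply the diagnostic thresholds
  *unchanged* to a pre-diagnosis cohort, stratified by gDNA
  contamination (cohort-median split computed within the new cohort)
  and by time to diagnosis.

The coupling between plasma quality and signal lives here: a subject
with gDNA contamination g sees its effective tumor fraction diluted to
theta/(1+g) (leukocyte gDNA is on-target but unmethylated) and emits
off-target high-molecular-weight reads at fraction g/(1+g) of output,
which drives the mapping-rate QC.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from . import align_call, diagnostics, fragment_qc, scoring
from .simulate import (
    AmpliconRegion,
    CohortDesign,
    FragmentSizeProfile,
    ReadSimParams,
    SubjectRecord,
    simulate_cohort,
    simulate_fragment_profile,
    simulate_reads,
)

__all__ = [
    "SampleResult",
    "subject_read_params",
    "run_sample",
    "run_cohort",
    "apply_qc_exclusions",
    "default_strata",
    "early_detection_strata",
    "run_diagnostic_workflow",
    "run_early_detection_workflow",
    "DiagnosticRun",
    "EarlyDetectionRun",
]

MAX_OFFTARGET_FRACTION = 0.95


@dataclasses.dataclass
class SampleResult:
    subject: SubjectRecord
    summaries: dict[str, align_call.RegionMethylationSummary]
    qc: align_call.SampleQC
    profile: FragmentSizeProfile

    @property
    def region_pcts(self) -> dict[str, float | None]:
        return {rid: s.pct_fully_methylated for rid, s in self.summaries.items()}


def _child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible 31-bit child seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def subject_read_params(
    subject: SubjectRecord, base: ReadSimParams, seed: int
) -> ReadSimParams:
    """Specialize read-simulation parameters to one subject's ground truth."""
    g = subject.gdna_contamination_truth
    # gDNA is unmethylated at the marker loci, so on-target templates from
    # lysed leukocytes dilute tumor *and* epimutant cfDNA alleles alike
    theta = subject.tumor_fraction_truth / (1.0 + g)
    epsilon = subject.epimutation_rate_truth / (1.0 + g)
    offtarget = min(g / (1.0 + g), MAX_OFFTARGET_FRACTION)
    return dataclasses.replace(
        base,
        tumor_fraction=theta,
        background_epimutation_rate=epsilon,
        offtarget_gdna_read_fraction=offtarget,
        seed=seed,
    )


def run_sample(
    subject: SubjectRecord,
    panel: Sequence[AmpliconRegion],
    base_params: ReadSimParams,
    seed: int,
    max_mismatch_rate: float = align_call.DEFAULT_MAX_MISMATCH_RATE,
) -> SampleResult:
    """Simulate one sample's reads and run them through alignment + calling."""
    params = subject_read_params(subject, base_params, seed)
    pairs, _ = simulate_reads(subject.subject_id, panel, params)
    summaries, qc, _ = align_call.process_sample(
        subject.subject_id, pairs, panel, max_mismatch_rate
    )
    profile = simulate_fragment_profile(subject.gdna_contamination_truth, seed=seed)
    return SampleResult(subject, summaries, qc, profile)


def run_cohort(
    subjects: Sequence[SubjectRecord],
    panel: Sequence[AmpliconRegion],
    base_params: ReadSimParams,
    seed: int,
) -> tuple[list[SampleResult], list[str]]:
    """Process a cohort; returns results of QC-passing samples and a log.

    A sample failing the 2% mapping-rate QC is excluded; in a matched
    design its partner is excluded with it.
    """
    seeds = _child_seeds(seed, len(subjects))
    results = [
        run_sample(s, panel, base_params, sd) for s, sd in zip(subjects, seeds)
    ]
    return apply_qc_exclusions(results)


def apply_qc_exclusions(
    results: Sequence[SampleResult],
) -> tuple[list[SampleResult], list[str]]:
    """Drop QC-failing samples and, in matched designs, their partners."""
    failed = {r.subject.subject_id for r in results if not r.qc.passed}
    log = [f"excluded {sid}: qc_maprate" for sid in sorted(failed)]
    matched_out = {
        r.subject.subject_id
        for r in results
        if r.subject.match_id in failed and r.subject.subject_id not in failed
    }
    log += [f"excluded {sid}: matched_pair" for sid in sorted(matched_out)]
    kept = [
        r
        for r in results
        if r.subject.subject_id not in failed
        and r.subject.subject_id not in matched_out
    ]
    return kept, log


def _ca125_records(
    results: Sequence[SampleResult],
) -> dict[str, scoring.CA125Record]:
    return {
        r.subject.subject_id: scoring.CA125Record(
            tuple(r.subject.ca125_history), r.subject.sample_date
        )
        for r in results
    }


def _score(
    results: Sequence[SampleResult], thresholds: scoring.ThresholdSet
) -> dict[str, scoring.ScoreCall]:
    calls = scoring.score_cohort(
        {r.subject.subject_id: r.region_pcts for r in results},
        thresholds,
        _ca125_records(results),
    )
    return {c.sample_id: c for c in calls}


def _contamination(
    results: Sequence[SampleResult],
) -> tuple[dict[str, fragment_qc.ContaminationCall], float]:
    calls = [
        fragment_qc.cfdna_gdna_ratio(r.profile, r.subject.subject_id)
        for r in results
    ]
    grouped, median = fragment_qc.stratify_by_median(calls)
    return {c.sample_id: c for c in grouped}, median


def default_strata() -> list[diagnostics.StratumSpec]:
    """Diagnostic-set strata: all cancers, high-risk, CA125-negative subset."""
    return [
        diagnostics.StratumSpec("all"),
        diagnostics.StratumSpec("high_risk", high_risk=True),
        diagnostics.StratumSpec(
            "high_risk_ca125_negative", high_risk=True, ca125_negative_only=True
        ),
    ]


def early_detection_strata() -> list[diagnostics.StratumSpec]:
    """Early-detection strata: contamination split x risk class x <1 year."""
    lower, higher = fragment_qc.LOWER, fragment_qc.HIGHER
    return [
        diagnostics.StratumSpec("all"),
        diagnostics.StratumSpec("lower_contamination", gdna_group=lower),
        diagnostics.StratumSpec("higher_contamination", gdna_group=higher),
        diagnostics.StratumSpec("high_risk", high_risk=True),
        diagnostics.StratumSpec(
            "high_risk_lower_contamination", high_risk=True, gdna_group=lower
        ),
        diagnostics.StratumSpec(
            "high_risk_lower_contamination_lt1yr",
            high_risk=True,
            gdna_group=lower,
            max_days_to_diagnosis=365,
        ),
    ]


@dataclasses.dataclass
class DiagnosticRun:
    subjects: list[SubjectRecord]
    results: list[SampleResult]
    thresholds: scoring.ThresholdSet
    scores: dict[str, scoring.ScoreCall]
    estimates: list[diagnostics.DiagnosticEstimate]
    exclusion_log: list[str]


@dataclasses.dataclass
class EarlyDetectionRun:
    subjects: list[SubjectRecord]
    results: list[SampleResult]
    scores: dict[str, scoring.ScoreCall]
    contamination: dict[str, fragment_qc.ContaminationCall]
    contamination_median: float
    estimates: list[diagnostics.DiagnosticEstimate]
    exclusion_log: list[str]


def run_diagnostic_workflow(
    design: CohortDesign,
    panel: Sequence[AmpliconRegion],
    base_params: ReadSimParams,
    seed: int,
    target_specificity: float = 0.97,
    level: float = 0.95,
) -> DiagnosticRun:
    """Simulate the diagnostic cohort, calibrate thresholds, evaluate markers."""
    subjects = simulate_cohort(design, seed)
    results, log = run_cohort(subjects, panel, base_params, seed + 1)
    control_pcts: dict[str, list[float]] = {r.region_id: [] for r in panel}
    case_pcts: dict[str, list[float]] = {r.region_id: [] for r in panel}
    for res in results:
        bucket = case_pcts if res.subject.is_case else control_pcts
        for rid, pct in res.region_pcts.items():
            if pct is not None:
                bucket[rid].append(pct)
    thresholds = scoring.calibrate_threshold_set(
        control_pcts, case_pcts, target_specificity, calibration_set_id=design.name
    )
    scores = _score(results, thresholds)
    estimates = diagnostics.evaluate_strata(
        [r.subject for r in results], scores, None, default_strata(), level
    )
    return DiagnosticRun(subjects, results, thresholds, scores, estimates, log)


def run_early_detection_workflow(
    design: CohortDesign,
    panel: Sequence[AmpliconRegion],
    base_params: ReadSimParams,
    thresholds: scoring.ThresholdSet,
    seed: int,
    level: float = 0.95,
) -> EarlyDetectionRun:
    """Apply previously calibrated thresholds to a pre-diagnosis cohort.

    No recalibration happens here; the contamination median is computed
    within this cohort, as in the published analysis.
    """
    subjects = simulate_cohort(design, seed)
    results, log = run_cohort(subjects, panel, base_params, seed + 1)
    scores = _score(results, thresholds)
    contamination, median = _contamination(results)
    estimates = diagnostics.evaluate_strata(
        [r.subject for r in results],
        scores,
        contamination,
        early_detection_strata(),
        level,
    )
    return EarlyDetectionRun(
        subjects, results, scores, contamination, median, estimates, log
    )
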
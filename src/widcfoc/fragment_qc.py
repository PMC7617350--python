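"""Genomic-DNA contamination quantification and cohort-median stratification.

Archival plasma samples accumulate high-molecular-weight genomic DNA
(gDNA) from leukocyte lysis, which dilutes the cell-free DNA signal.
Contamination is quantified per sample as the mass ratio
cfDNA / gDNA integrated from the fragment-size profile (cfDNA window
50-700 bp around the mononucleosome peak; gDNA window > 700 bp), and
samples are split at the cohort median: ratio <= median is the *higher*
contamination group, ratio > median the *lower* one.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate.profiles import FragmentSizeProfile

__all__ = [
    "ContaminationCall",
    "cfdna_gdna_ratio",
    "stratify_by_median",
    "write_contamination_table",
    "DEFAULT_CF_WINDOW",
    "DEFAULT_GDNA_WINDOW",
]

DEFAULT_CF_WINDOW = (50.0, 700.0)
DEFAULT_GDNA_WINDOW = (700.0, math.inf)

HIGHER, LOWER = "higher_contamination", "lower_contamination"


@dataclasses.dataclass
class ContaminationCall:
    sample_id: str
    cfdna_mass: float
    gdna_mass: float
    group: str | None = None  # assigned by stratify_by_median

    @property
    def ratio(self) -> float:
        """cfDNA/gDNA mass ratio; +inf when no gDNA mass was detected."""
        if self.gdna_mass == 0:
            return math.inf
        return self.cfdna_mass / self.gdna_mass

    @property
    def ratio_is_infinite(self) -> bool:
        return self.gdna_mass == 0


def cfdna_gdna_ratio(
    profile: FragmentSizeProfile,
    sample_id: str = "",
    cf_window_bp: tuple[float, float] = DEFAULT_CF_WINDOW,
    gdna_window_bp: tuple[float, float] = DEFAULT_GDNA_WINDOW,
) -> ContaminationCall:
    """Integrate profile mass over the two size windows and form the ratio.

    Windows must not overlap.  A profile with zero total mass is invalid
    (failed quantification), whereas zero gDNA mass is a perfectly clean
    sample: the ratio is flagged infinite and sorts above all finite ones.
    """
    if cf_window_bp[0] >= cf_window_bp[1] or gdna_window_bp[0] >= gdna_window_bp[1]:
        raise ValueError("windows must be (low, high) with low < high")
    if max(cf_window_bp[0], gdna_window_bp[0]) < min(cf_window_bp[1], gdna_window_bp[1]):
        raise ValueError("cfDNA and gDNA windows must be disjoint")
    if profile.total_mass <= 0:
        raise ValueError(f"{sample_id or 'profile'}: zero total mass")
    hi = gdna_window_bp[1]
    if math.isinf(hi):
        hi = float(profile.bin_edges[-1])
    cf = profile.mass_in_window(*cf_window_bp)
    gd = profile.mass_in_window(gdna_window_bp[0], hi)
    return ContaminationCall(sample_id, cfdna_mass=cf, gdna_mass=gd)


def stratify_by_median(
    calls: Sequence[ContaminationCall],
) -> tuple[list[ContaminationCall], float]:
    """Split samples at the cohort-median cfDNA/gDNA ratio.

    Infinite ratios (no detectable gDNA) sort above every finite value.
    Samples with ratio <= median carry relatively more gDNA and form the
    higher-contamination group; ratio > median forms the lower one.
    Median is the midpoint of central order statistics for even n.
    Returns new grouped calls plus the median; input order is preserved
    and never affects grouping.
    """
    if len(calls) < 2:
        raise ValueError("need at least 2 samples to stratify")
    ratios = np.array([c.ratio for c in calls], dtype=float)
    median = float(np.median(ratios))
    grouped = [
        dataclasses.replace(
            c, group=HIGHER if c.ratio <= median else LOWER
        )
        for c in calls
    ]
    return grouped, median


def write_contamination_table(
    calls: Sequence[ContaminationCall], median: float, path: str | Path
) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "cfdna_mass": c.cfdna_mass,
            "gdna_mass": c.gdna_mass,
            "ratio": "inf" if c.ratio_is_infinite else c.ratio,
            "group": c.group or "",
            "cohort_median": median,
        }
        for c in calls
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
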
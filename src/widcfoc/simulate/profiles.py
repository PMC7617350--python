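"""Fragment-size profiles: cfDNA mononucleosome peak vs high-MW gDNA.

Plasma cell-free DNA has a characteristic mononucleosomal fragment
length (~167 bp).  Lysis of white blood cells during collection or
storage releases high-molecular-weight genomic DNA (>700 bp), which
shows up as a second component on a capillary electropherogram.  The
profile here is a binned mass density of that mixture: the cfDNA
component carries unit mass and the gDNA component carries
``contamination`` units, so the downstream cfDNA/gDNA mass ratio is
1/contamination by construction.

Profiles are built from truncated-Gaussian CDF integration, so they are
exactly reproducible; ``seed`` only drives optional multiplicative
jitter emulating fluorescence noise (off by default).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "FragmentSizeProfile",
    "simulate_fragment_profile",
    "write_profiles",
    "read_profiles",
]

CFDNA_MODE_BP = 167.0
CFDNA_SD_BP = 20.0
GDNA_MODE_BP = 850.0
GDNA_SD_BP = 60.0
GDNA_MIN_BP = 700.0  # standard high-MW window boundary


@dataclasses.dataclass(frozen=True)
class FragmentSizeProfile:
    """Binned fragment-size mass (arbitrary fluorescence-like units)."""

    bin_edges: tuple[float, ...]  # strictly increasing, length nbins+1
    mass: tuple[float, ...]  # nonnegative, length nbins

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if edges.ndim != 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if mass.size != edges.size - 1:
            raise ValueError("mass must have len(bin_edges) - 1 entries")
        if np.any(mass < 0):
            raise ValueError("mass must be nonnegative")

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.mass))

    def mass_in_window(self, lo: float, hi: float) -> float:
        """Integrate mass over [lo, hi); partial bins contribute pro rata."""
        edges = np.asarray(self.bin_edges)
        mass = np.asarray(self.mass)
        left = edges[:-1]
        right = edges[1:]
        overlap = np.clip(np.minimum(right, hi) - np.maximum(left, lo), 0, None)
        width = right - left
        return float(np.sum(mass * overlap / width))


def _component_mass(
    edges: np.ndarray, mode: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Per-bin mass of a Gaussian truncated to [lo, hi], normalized to 1."""
    cdf = norm.cdf(np.clip(edges, lo, hi), loc=mode, scale=sd)
    mass = np.diff(cdf)
    total = norm.cdf(hi, mode, sd) - norm.cdf(lo, mode, sd)
    return mass / total


def simulate_fragment_profile(
    gdna_contamination_truth: float,
    seed: int = 0,
    bin_width_bp: float = 10.0,
    max_bp: float = 1100.0,
    scale: float = 100.0,
    jitter: float = 0.0,
) -> FragmentSizeProfile:
    """Electropherogram stand-in for one plasma sample.

    ``gdna_contamination_truth`` is the gDNA:cfDNA mass ratio (0 = clean
    plasma).  ``jitter`` adds seeded multiplicative noise per bin.
    """
    if gdna_contamination_truth < 0:
        raise ValueError("contamination must be >= 0")
    edges = np.arange(50.0, max_bp + bin_width_bp, bin_width_bp)
    cf = _component_mass(edges, CFDNA_MODE_BP, CFDNA_SD_BP, 50.0, GDNA_MIN_BP)
    gd = _component_mass(edges, GDNA_MODE_BP, GDNA_SD_BP, GDNA_MIN_BP, max_bp)
    mass = scale * (cf + gdna_contamination_truth * gd)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        mass = mass * np.exp(rng.normal(0.0, jitter, size=mass.size))
    return FragmentSizeProfile(tuple(edges), tuple(mass))


def write_profiles(
    profiles: dict[str, FragmentSizeProfile], path: str | Path
) -> None:
    rows = []
    for sample_id, prof in profiles.items():
        for lo, hi, m in zip(prof.bin_edges[:-1], prof.bin_edges[1:], prof.mass):
            rows.append(
                {"sample_id": sample_id, "bin_start": lo, "bin_end": hi, "mass": m}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> dict[str, FragmentSizeProfile]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, FragmentSizeProfile] = {}
    for sample_id, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("bin_start")
        edges = tuple(grp["bin_start"].tolist() + [float(grp["bin_end"].iloc[-1])])
        out[str(sample_id)] = FragmentSizeProfile(edges, tuple(grp["mass"]))
    return out
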
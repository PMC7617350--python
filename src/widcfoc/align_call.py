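"""Bisulfite-aware alignment and read-level methylation calling.

The assay measures, per target region, the percentage of *fully
methylated reads*: reads in which every CpG of the region is read as C
(i.e. was protected from bisulfite conversion).  Because the panel is a
handful of short amplicons, alignment is an exhaustive ungapped scan in
the reduced bisulfite alphabet (C2T: every C folded to T, or G2A
symmetrically), which removes the methylation signal from the matching
problem.  Methylation is then called from the *unreduced* fragment at
the region's CpG cytosines.

Per-sample QC follows the assay's single filtering rule: samples whose
read-pair mapping rate is below 2% are excluded; no other read
filtering is applied.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate.panel import AmpliconRegion
from .simulate.reads import ReadPair, revcomp

__all__ = [
    "AlignmentResult",
    "ReadMethylationCall",
    "RegionMethylationSummary",
    "SampleQC",
    "reduce_alphabet",
    "merge_pair",
    "align_fragment",
    "align_fragment_bruteforce",
    "compute_mapping_rate",
    "call_read_methylation",
    "summarize_region",
    "process_sample",
    "write_region_summaries",
    "write_sam",
]

MIN_MAPPING_RATE = 0.02  # samples below this pair-mapping rate are excluded
DEFAULT_MAX_MISMATCH_RATE = 0.1
METH, UNMETH, AMBIG, UNCOV = "methylated", "unmethylated", "ambiguous", "uncovered"


def reduce_alphabet(seq: str, mode: str) -> str:
    """Collapse the bisulfite-ambiguous base: C2T folds C->T, G2A folds G->A."""
    if mode == "C2T":
        return seq.replace("C", "T")
    if mode == "G2A":
        return seq.replace("G", "A")
    raise ValueError(f"unknown reduction mode {mode!r}")


@dataclasses.dataclass(frozen=True)
class AlignmentResult:
    read_id: str
    region_id: str | None
    offset: int  # 0-based start on the reference
    mismatches: int  # in the reduced alphabet, N positions excluded
    mapped: bool


@dataclasses.dataclass(frozen=True)
class ReadMethylationCall:
    read_id: str
    region_id: str
    cpg_states: tuple[str, ...]  # one of METH/UNMETH/AMBIG/UNCOV per region CpG

    @property
    def fully_methylated(self) -> bool:
        """All region CpGs covered and every one read as methylated."""
        return all(s == METH for s in self.cpg_states)

    @property
    def partial(self) -> bool:
        return any(s == UNCOV for s in self.cpg_states)


@dataclasses.dataclass
class RegionMethylationSummary:
    sample_id: str
    region_id: str
    n_reads_mapped: int
    n_fully_methylated: int
    n_partial: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_fully_methylated <= self.n_reads_mapped:
            raise ValueError("fully methylated count exceeds mapped count")

    @property
    def no_amplification(self) -> bool:
        return self.n_reads_mapped == 0

    @property
    def pct_fully_methylated(self) -> float | None:
        """Percent fully methylated, or None when no reads mapped."""
        if self.n_reads_mapped == 0:
            return None
        return 100.0 * self.n_fully_methylated / self.n_reads_mapped


@dataclasses.dataclass(frozen=True)
class SampleQC:
    sample_id: str
    n_pairs_total: int
    n_pairs_mapped: int

    @property
    def mapping_rate(self) -> float:
        return self.n_pairs_mapped / self.n_pairs_total

    @property
    def passed(self) -> bool:
        return self.mapping_rate >= MIN_MAPPING_RATE


def merge_pair(
    r1_seq: str,
    r2_seq: str,
    r1_qual: str | None = None,
    r2_qual: str | None = None,
    min_overlap: int = 10,
    min_overlap_identity: float = 0.75,
) -> tuple[str, bool]:
    """Merge a read pair into one fragment sequence.

    ``r2_seq`` is given in sequencing orientation and reverse-
    complemented internally.  The overlap is the shift of the reverse
    mate against the forward mate with the highest base identity; at
    disagreeing overlap positions the higher-quality base wins, quality
    ties become N.  Returns ``(fragment, overlapped)``; pairs without an
    acceptable overlap are concatenated (two independent sub-reads of
    one fragment) with ``overlapped=False``.
    """
    if not r1_seq or not r2_seq:
        raise ValueError("both mates must be non-empty")
    r1q = r1_qual if r1_qual is not None else "I" * len(r1_seq)
    r2q = (r2_qual if r2_qual is not None else "I" * len(r2_seq))[::-1]
    r2 = revcomp(r2_seq)
    a1 = np.frombuffer(r1_seq.encode(), dtype=np.uint8)
    a2 = np.frombuffer(r2.encode(), dtype=np.uint8)
    best_shift, best_score, best_len = None, -1.0, 0
    max_shift = len(a1) - min_overlap
    for shift in range(0, max_shift + 1):
        ov = min(len(a1) - shift, len(a2))
        if ov < min_overlap:
            break
        matches = int(np.sum(a1[shift : shift + ov] == a2[:ov]))
        score = matches / ov
        # prefer longer overlaps on equal identity (shift scanned ascending,
        # so strict > keeps the longest-overlap candidate)
        if score > best_score:
            best_shift, best_score, best_len = shift, score, ov
    if best_shift is None or best_score < min_overlap_identity:
        return r1_seq + r2, False
    shift, ov = best_shift, best_len
    merged = list(r1_seq[:shift])
    for i in range(ov):
        b1, b2 = r1_seq[shift + i], r2[i]
        if b1 == b2:
            merged.append(b1)
        else:
            q1, q2 = ord(r1q[shift + i]), ord(r2q[i])
            merged.append(b1 if q1 > q2 else b2 if q2 > q1 else "N")
    merged.append(r2[ov:])
    if len(a1) - shift > ov:  # forward mate extends past the reverse mate
        merged.append(r1_seq[shift + ov :])
    return "".join(merged), True


class PanelIndex:
    """Pre-reduced references for fast repeated alignment."""

    def __init__(self, panel: Sequence[AmpliconRegion]):
        if not panel:
            raise ValueError("panel must be non-empty")
        self.panel = list(panel)
        self._reduced = [
            np.frombuffer(
                reduce_alphabet(r.ref_seq, r.conversion_mode).encode(), dtype=np.uint8
            )
            for r in self.panel
        ]


def align_fragment(
    fragment: str,
    panel: Sequence[AmpliconRegion] | PanelIndex,
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    read_id: str = "",
) -> AlignmentResult:
    """Best ungapped placement of a fragment on the panel.

    Fragment and references are reduced per each region's conversion
    mode; the best (region, offset) minimizes reduced-alphabet
    mismatches, with N positions excluded from both mismatch count and
    rate denominator.  Ties break to the lower region index, then lower
    offset.  ``mapped`` iff the best mismatch rate <= ``max_mismatch_rate``.
    """
    index = panel if isinstance(panel, PanelIndex) else PanelIndex(panel)
    best: tuple[int, int, int] | None = None  # (mismatches, region_idx, offset)
    frag_arrays: dict[str, np.ndarray] = {}
    for ri, (region, ref) in enumerate(zip(index.panel, index._reduced)):
        mode = region.conversion_mode
        if mode not in frag_arrays:
            frag_arrays[mode] = np.frombuffer(
                reduce_alphabet(fragment, mode).encode(), dtype=np.uint8
            )
        frag = frag_arrays[mode]
        L = frag.size
        if L == 0 or L > ref.size:
            continue
        informative = frag != ord("N")
        windows = np.lib.stride_tricks.sliding_window_view(ref, L)
        mism = np.sum((windows != frag) & informative, axis=1)
        o = int(np.argmin(mism))  # first minimum -> lowest offset
        if best is None or int(mism[o]) < best[0]:
            best = (int(mism[o]), ri, o)
    if best is None:
        return AlignmentResult(read_id, None, 0, 0, False)
    mm, ri, offset = best
    # rate over informative (non-N) positions of this fragment
    frag = frag_arrays[index.panel[ri].conversion_mode]
    denom = int(np.sum(frag != ord("N")))
    mapped = denom > 0 and mm / denom <= max_mismatch_rate
    return AlignmentResult(
        read_id, index.panel[ri].region_id if mapped else None, offset if mapped else 0,
        mm, mapped
    )


def align_fragment_bruteforce(
    fragment: str,
    panel: Sequence[AmpliconRegion],
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
    read_id: str = "",
) -> AlignmentResult:
    """Pure-Python exhaustive scorer over every region x offset.

    Independent reference implementation used to validate
    :func:`align_fragment`; O(regions x offsets x length) scalar loops.
    """
    best = None
    for ri, region in enumerate(panel):
        ref = reduce_alphabet(region.ref_seq, region.conversion_mode)
        frag = reduce_alphabet(fragment, region.conversion_mode)
        if not frag or len(frag) > len(ref):
            continue
        for offset in range(len(ref) - len(frag) + 1):
            mm = sum(
                1
                for i, b in enumerate(frag)
                if b != "N" and b != ref[offset + i]
            )
            key = (mm, ri, offset)
            if best is None or key < best:
                best = key
    if best is None:
        return AlignmentResult(read_id, None, 0, 0, False)
    mm, ri, offset = best
    frag = reduce_alphabet(fragment, panel[ri].conversion_mode)
    denom = sum(1 for b in frag if b != "N")
    mapped = denom > 0 and mm / denom <= max_mismatch_rate
    return AlignmentResult(
        read_id, panel[ri].region_id if mapped else None, offset if mapped else 0,
        mm, mapped
    )


def compute_mapping_rate(
    alignments: Iterable[AlignmentResult], n_pairs_total: int, sample_id: str = ""
) -> SampleQC:
    """Pair-level mapping rate; a sample passes at >= 2% (strictly-below excluded)."""
    if n_pairs_total <= 0:
        raise ValueError("n_pairs_total must be positive")
    n_mapped = sum(1 for a in alignments if a.mapped)
    if n_mapped > n_pairs_total:
        raise ValueError("more mapped alignments than read pairs")
    return SampleQC(sample_id, n_pairs_total, n_mapped)


def call_read_methylation(
    alignment: AlignmentResult, fragment: str, region: AmpliconRegion
) -> ReadMethylationCall:
    """Call per-CpG methylation from the unreduced fragment.

    At each region CpG covered by the aligned span: C means the cytosine
    was protected (methylated), T means converted (unmethylated),
    anything else (sequencing N, disagreeing mates) is ambiguous.
    A read is fully methylated only if it covers *all* region CpGs and
    every one reads methylated; ambiguous never counts as methylated.
    """
    if not alignment.mapped:
        raise ValueError("cannot call methylation on an unmapped fragment")
    if alignment.region_id != region.region_id:
        raise ValueError("alignment/region mismatch")
    lo, hi = alignment.offset, alignment.offset + len(fragment)
    if region.conversion_mode == "C2T":
        meth_base, unmeth_base, site_shift = "C", "T", 0
    else:  # bottom strand reads the G of the CpG; A indicates conversion
        meth_base, unmeth_base, site_shift = "G", "A", 1
    states = []
    for p in region.cpg_positions:
        q = p + site_shift
        if not (lo <= q < hi):
            states.append(UNCOV)
            continue
        base = fragment[q - lo]
        if base == meth_base:
            states.append(METH)
        elif base == unmeth_base:
            states.append(UNMETH)
        else:
            states.append(AMBIG)
    return ReadMethylationCall(alignment.read_id, region.region_id, tuple(states))


def summarize_region(
    calls: Sequence[ReadMethylationCall], sample_id: str, region_id: str
) -> RegionMethylationSummary:
    """Fully-methylated-read percentage for one sample x region.

    Zero mapped reads is a valid outcome ('no amplification'): the
    percentage is undefined and flagged, never silently 0.
    """
    for c in calls:
        if c.region_id != region_id:
            raise ValueError("mixed regions passed to summarize_region")
    return RegionMethylationSummary(
        sample_id=sample_id,
        region_id=region_id,
        n_reads_mapped=len(calls),
        n_fully_methylated=sum(1 for c in calls if c.fully_methylated),
        n_partial=sum(1 for c in calls if c.partial),
    )


def process_sample(
    sample_id: str,
    pairs: Sequence[ReadPair],
    panel: Sequence[AmpliconRegion],
    max_mismatch_rate: float = DEFAULT_MAX_MISMATCH_RATE,
) -> tuple[dict[str, RegionMethylationSummary], SampleQC, list[AlignmentResult]]:
    """Merge, align and call every pair of a sample; summarize per region.

    Beyond the 2% mapping-rate QC there is no read filtering: every
    mapped pair contributes to exactly one region's denominator.
    """
    if not pairs:
        raise ValueError(f"{sample_id}: no read pairs")
    index = PanelIndex(panel)
    regions = {r.region_id: r for r in panel}
    calls: dict[str, list[ReadMethylationCall]] = {r.region_id: [] for r in panel}
    alignments: list[AlignmentResult] = []
    for p in pairs:
        fragment, _ = merge_pair(p.r1_seq, p.r2_seq, p.r1_qual, p.r2_qual)
        aln = align_fragment(fragment, index, max_mismatch_rate, read_id=p.read_id)
        alignments.append(aln)
        if aln.mapped:
            region = regions[aln.region_id]
            calls[region.region_id].append(
                call_read_methylation(aln, fragment, region)
            )
    qc = compute_mapping_rate(alignments, len(pairs), sample_id)
    summaries = {
        rid: summarize_region(cs, sample_id, rid) for rid, cs in calls.items()
    }
    return summaries, qc, alignments


def write_region_summaries(
    summaries: Iterable[RegionMethylationSummary], path: str | Path
) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "region_id": s.region_id,
            "n_reads_mapped": s.n_reads_mapped,
            "n_fully_methylated": s.n_fully_methylated,
            "n_partial": s.n_partial,
            "pct_fully_methylated": (
                "" if s.pct_fully_methylated is None else s.pct_fully_methylated
            ),
            "no_amplification": s.no_amplification,
        }
        for s in summaries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_sam(
    alignments: Sequence[AlignmentResult],
    fragments: dict[str, str],
    panel: Sequence[AmpliconRegion],
    path: str | Path,
) -> None:
    """Plain-text SAM of accepted (mapped) fragment alignments."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for r in panel:
            fh.write(f"@SQ\tSN:{r.region_id}\tLN:{len(r)}\n")
        for a in alignments:
            if not a.mapped:
                continue
            seq = fragments.get(a.read_id, "*")
            cigar = f"{len(seq)}M" if seq != "*" else "*"
            fh.write(
                f"{a.read_id}\t0\t{a.region_id}\t{a.offset + 1}\t255\t{cigar}"
                f"\t*\t0\t0\t{seq}\t*\tNM:i:{a.mismatches}\n"
            )
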
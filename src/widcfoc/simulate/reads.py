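"""Bisulfite amplicon read simulation.

Models the measurement chain of a targeted bisulfite sequencing assay on
plasma DNA:

1. each on-target fragment is tumor-derived with probability equal to
   the circulating tumor fraction θ;
2. per-fragment CpG methylation states are Bernoulli draws — probability
   ``m_t`` (default 1.0, tumor DNA is fully methylated at these regions)
   or ``m_b`` (default 0.01, low somatic background);
3. bisulfite chemistry converts unmethylated C→T with probability ``c``
   (conversion rate, default 0.995) and erroneously converts methylated
   C→T with probability ``o`` (over-conversion, default 0.005);
   non-CpG cytosines are always unmethylated and convert at rate ``c``;
4. uniform substitution sequencing error;
5. off-target high-molecular-weight gDNA reads (uniform random
   sequence) at a configurable fraction of total output.

Reads are emitted as a Phred+33 FASTQ pair (R1 = fragment 5' end,
R2 = reverse complement of the 3' end) together with a per-fragment
truth table recording origin and methylation states, which downstream
round-trip tests compare against pipeline output.
"""

from __future__ import annotations

import dataclasses
import gzip
import io
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np

from .panel import AmpliconRegion

__all__ = [
    "ReadSimParams",
    "SimulatedFragment",
    "ReadPair",
    "bisulfite_convert",
    "simulate_reads",
    "write_fastq_pair",
    "write_truth_table",
]

_COMP = str.maketrans("ACGTN", "TGCAN")
_PROBS = (
    "tumor_fraction", "tumor_cpg_meth_prob", "background_cpg_meth_prob",
    "background_epimutation_rate", "conversion_rate", "overconversion_rate",
    "seq_error_rate", "offtarget_gdna_read_fraction",
)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclasses.dataclass(frozen=True)
class ReadSimParams:
    """Knobs of the read simulator; all probabilities in [0, 1]."""

    depth_per_region: int = 200
    read_length: int = 150
    tumor_fraction: float = 0.0
    tumor_cpg_meth_prob: float = 1.0
    background_cpg_meth_prob: float = 0.01
    #: probability a background fragment carries a coordinately fully
    #: methylated allele (rare somatic epimutations in normal tissue);
    #: 0 keeps CpG states independent Bernoulli draws
    background_epimutation_rate: float = 0.0
    conversion_rate: float = 0.995
    overconversion_rate: float = 0.005
    seq_error_rate: float = 0.001
    offtarget_gdna_read_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth_per_region < 0:
            raise ValueError("depth_per_region must be >= 0")
        for name in _PROBS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclasses.dataclass
class SimulatedFragment:
    """Ground truth for one sequenced fragment."""

    fragment_id: str
    region_id: str | None  # None for off-target gDNA
    origin: str  # tumor | background | offtarget
    cpg_states: tuple[bool, ...]  # True = methylated; () for off-target

    @property
    def fully_methylated(self) -> bool:
        return bool(self.cpg_states) and all(self.cpg_states)


@dataclasses.dataclass
class ReadPair:
    read_id: str
    r1_seq: str
    r1_qual: str
    r2_seq: str
    r2_qual: str


def bisulfite_convert(
    fragment_seq: str,
    cpg_states: Sequence[bool],
    cpg_offsets: Sequence[int],
    c: float,
    o: float,
    rng: np.random.Generator,
) -> str:
    """Apply the bisulfite chemistry model to a top-strand fragment.

    A cytosine at a CpG offset survives as C with probability ``1-o``
    if methylated and ``1-c`` if unmethylated; every other cytosine is
    treated as unmethylated and converts with probability ``c``.
    """
    if len(cpg_states) != len(cpg_offsets):
        raise ValueError("cpg_states and cpg_offsets must align")
    n = len(fragment_seq)
    offsets = list(cpg_offsets)
    if any(p < 0 or p >= n for p in offsets):
        raise ValueError("cpg offset outside fragment")
    protected = {p for p, m in zip(offsets, cpg_states) if m}
    out = list(fragment_seq)
    for i, base in enumerate(out):
        if base != "C":
            continue
        if i in protected:
            if rng.random() < o:  # over-conversion of methylated C
                out[i] = "T"
        else:
            # unmethylated CpG C and every non-CpG C convert at rate c
            if rng.random() < c:
                out[i] = "T"
    return "".join(out)


def _apply_seq_error(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def simulate_reads(
    subject_id: str,
    panel: Sequence[AmpliconRegion],
    params: ReadSimParams,
) -> tuple[list[ReadPair], list[SimulatedFragment]]:
    """Simulate a paired-end read set for one sample over the panel.

    Returns the read pairs and the per-fragment truth table.  The number
    of pairs equals on-target fragments (``depth_per_region`` per
    region) plus the off-target reads implied by
    ``offtarget_gdna_read_fraction`` (as a fraction of total output).
    Deterministic for fixed ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    pairs: list[ReadPair] = []
    truth: list[SimulatedFragment] = []
    L = params.read_length
    qual = "I" * L  # constant Q40; per-base quality modelling is out of scope
    if params.depth_per_region == 0:
        warnings.warn(f"{subject_id}: zero depth requested, empty read set")
    n_on = params.depth_per_region * len(panel)
    f = params.offtarget_gdna_read_fraction
    n_off = int(round(n_on * f / (1.0 - f))) if f < 1.0 else 0
    if f >= 1.0 and n_on > 0:
        raise ValueError("offtarget fraction must be < 1 when on-target depth > 0")
    k = 0
    for region in panel:
        for _ in range(params.depth_per_region):
            is_tumor = rng.random() < params.tumor_fraction
            if is_tumor:
                p_meth = params.tumor_cpg_meth_prob
            elif rng.random() < params.background_epimutation_rate:
                p_meth = 1.0  # coordinately methylated normal-tissue allele
            else:
                p_meth = params.background_cpg_meth_prob
            states = tuple(bool(s) for s in rng.random(region.n_cpgs) < p_meth)
            frag = bisulfite_convert(
                region.ref_seq,
                states,
                region.cpg_positions,
                params.conversion_rate,
                params.overconversion_rate,
                rng,
            )
            rid = f"{subject_id}:frag{k:06d}"
            r1 = _apply_seq_error(frag[:L], params.seq_error_rate, rng)
            r2 = _apply_seq_error(revcomp(frag[-L:]), params.seq_error_rate, rng)
            pairs.append(ReadPair(rid, r1, qual[: len(r1)], r2, qual[: len(r2)]))
            truth.append(
                SimulatedFragment(rid, region.region_id,
                                  "tumor" if is_tumor else "background", states)
            )
            k += 1
    for _ in range(n_off):
        # long gDNA fragment: mates sample opposite ends, no overlap
        gfrag = _random_seq(4 * L, rng)
        rid = f"{subject_id}:frag{k:06d}"
        pairs.append(
            ReadPair(rid, gfrag[:L], qual, revcomp(gfrag[-L:]), qual)
        )
        truth.append(SimulatedFragment(rid, None, "offtarget", ()))
        k += 1
    return pairs, truth


def _open_write(path: Path):
    if path.suffix == ".gz":
        # fixed mtime/filename so identical seeds give byte-identical files
        raw = open(path, "wb")
        return gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0)
    return open(path, "wb")


def write_fastq_pair(
    pairs: Sequence[ReadPair], r1_path: str | Path, r2_path: str | Path
) -> None:
    """Write Phred+33 FASTQ mates; ``.gz`` suffix triggers gzip output."""
    for path, which in ((Path(r1_path), 1), (Path(r2_path), 2)):
        buf = io.StringIO()
        for p in pairs:
            seq = p.r1_seq if which == 1 else p.r2_seq
            q = p.r1_qual if which == 1 else p.r2_qual
            buf.write(f"@{p.read_id}/{which}\n{seq}\n+\n{q}\n")
        with _open_write(path) as fh:
            fh.write(buf.getvalue().encode())


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """(read_id, seq, qual) triples from a plain or gzipped FASTQ."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    out = []
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            q = fh.readline().strip()
            out.append((header[1:], seq, q))
    return out


def write_truth_table(
    truth: Sequence[SimulatedFragment], path: str | Path
) -> None:
    payload = [
        {
            "fragment_id": t.fragment_id,
            "region_id": t.region_id,
            "origin": t.origin,
            "cpg_states": list(t.cpg_states),
            "fully_methylated": t.fully_methylated,
        }
        for t in truth
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
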
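"""Synthetic amplicon reference panels for targeted bisulfite sequencing.

The assay interrogates a small number of PCR amplicons (three by default,
mirroring the EFC 144 / EFC 204 / EFC 228 regions in ZNF154, C2CD4D and
WNT6).  Real region sequences are not public, so the panel here is
synthetic by construction: random sequence in which CpG dinucleotides
occur *only* at the positions we place them.  That property makes every
read-level methylation call auditable — any CG in a reference is a
designed CpG site.

Panels round-trip through FASTA (sequences) + BED (spans, 0-based
half-open), so a real panel can be dropped in unchanged.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AmpliconRegion",
    "make_reference_panel",
    "write_panel_fasta",
    "write_panel_bed",
    "read_panel",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: genomic gene tags used for the default three-region panel
DEFAULT_GENE_TAGS = ("ZNF154", "C2CD4D", "WNT6")


@dataclasses.dataclass(frozen=True)
class AmpliconRegion:
    """One target region of the multiplex panel.

    Parameters
    ----------
    region_id:
        Label, e.g. ``"EFC144"``.
    ref_seq:
        Uppercase DNA reference of the amplicon.
    cpg_positions:
        0-based offsets of the C of each CpG, strictly increasing.
    conversion_mode:
        ``"C2T"`` (original-top strand) or ``"G2A"`` (original-bottom).
    genomic_label:
        Free-text gene tag (e.g. ``"ZNF154"``).
    """

    region_id: str
    ref_seq: str
    cpg_positions: tuple[int, ...]
    conversion_mode: str = "C2T"
    genomic_label: str = ""

    def __post_init__(self) -> None:
        if self.conversion_mode not in ("C2T", "G2A"):
            raise ValueError(f"unknown conversion mode {self.conversion_mode!r}")
        pos = tuple(self.cpg_positions)
        if len(pos) < 1:
            raise ValueError("a region needs at least one CpG")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("cpg_positions must be strictly increasing")
        for p in pos:
            if self.ref_seq[p : p + 2] != "CG":
                raise ValueError(
                    f"{self.region_id}: position {p} is not a CG dinucleotide"
                )
        object.__setattr__(self, "cpg_positions", pos)

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)

    def __len__(self) -> int:
        return len(self.ref_seq)


def _random_sequence_without_cpg(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random DNA of length ``n`` containing no CG dinucleotide.

    Sampled left to right; after a C, the G is re-drawn from {A,C,T}.
    """
    seq = _BASES[rng.integers(0, 4, size=n)]
    # kill CG pairs created by the draw; replacing G keeps no new CG possible
    not_g = np.frombuffer(b"ACT", dtype=np.uint8)
    while True:
        cg = np.flatnonzero((seq[:-1] == ord("C")) & (seq[1:] == ord("G")))
        if cg.size == 0:
            return seq
        seq[cg + 1] = not_g[rng.integers(0, 3, size=cg.size)]


def make_reference_panel(
    n_regions: int = 3,
    region_length_bp: int = 220,
    n_cpgs_per_region: int = 6,
    seed: int = 0,
    conversion_mode: str = "C2T",
) -> list[AmpliconRegion]:
    """Generate a synthetic amplicon panel.

    CpGs are placed non-overlapping with at least one spacer base between
    consecutive sites, and the remaining sequence is guaranteed CG-free,
    so ``cpg_positions`` enumerates *all* CpGs of each reference.
    Deterministic for a fixed ``seed``.

    Raises
    ------
    ValueError
        If the requested CpG count cannot be placed in the region
        (requires ``region_length_bp >= 2 * n_cpgs_per_region + 10``).
    """
    if n_cpgs_per_region < 1:
        raise ValueError("n_cpgs_per_region must be >= 1")
    if region_length_bp < 2 * n_cpgs_per_region + 10:
        raise ValueError(
            f"region_length_bp={region_length_bp} too short for "
            f"{n_cpgs_per_region} CpGs (need >= {2 * n_cpgs_per_region + 10})"
        )
    rng = np.random.default_rng(seed)
    regions: list[AmpliconRegion] = []
    for i in range(n_regions):
        seq = _random_sequence_without_cpg(region_length_bp, rng)
        # slot model: choose CpG start positions on a grid of 2-bp slots,
        # then keep them >= 3 apart so sites never overlap or abut
        candidates = np.arange(1, region_length_bp - 2)
        positions: list[int] = []
        order = rng.permutation(candidates)
        for p in order:
            if all(abs(int(p) - q) >= 3 for q in positions):
                positions.append(int(p))
                if len(positions) == n_cpgs_per_region:
                    break
        if len(positions) < n_cpgs_per_region:  # pragma: no cover - guarded by pre
            raise ValueError("could not place requested CpGs")
        positions.sort()
        for p in positions:
            # writing "CG" at p cannot create a stray CG at p-1 (xC) or
            # p+1 (Gx), so placements never interact
            seq[p] = ord("C")
            seq[p + 1] = ord("G")
        # re-validate: the only CGs are the placed ones
        s = seq.tobytes().decode()
        tag = DEFAULT_GENE_TAGS[i] if i < len(DEFAULT_GENE_TAGS) else f"GENE{i + 1}"
        regions.append(
            AmpliconRegion(
                region_id=("EFC144", "EFC204", "EFC228")[i] if i < 3 else f"EFC{900 + i}",
                ref_seq=s,
                cpg_positions=tuple(positions),
                conversion_mode=conversion_mode,
                genomic_label=tag,
            )
        )
        all_cg = {m for m in range(len(s) - 1) if s[m : m + 2] == "CG"}
        if all_cg != set(positions):  # pragma: no cover - construction guarantee
            raise AssertionError("stray CG dinucleotide in synthetic reference")
    return regions


def write_panel_fasta(panel: Sequence[AmpliconRegion], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.ref_seq), id=r.region_id, description=r.genomic_label)
        for r in panel
    ]
    SeqIO.write(records, str(path), "fasta")


def write_panel_bed(panel: Sequence[AmpliconRegion], path: str | Path) -> None:
    """BED of region spans plus one line per CpG site (0-based half-open)."""
    with open(path, "w") as fh:
        for r in panel:
            fh.write(f"{r.region_id}\t0\t{len(r)}\tregion\t0\t+\n")
            for p in r.cpg_positions:
                fh.write(f"{r.region_id}\t{p}\t{p + 2}\tCpG\t0\t+\n")


def read_panel(
    fasta_path: str | Path,
    bed_path: str | Path | None = None,
    conversion_mode: str = "C2T",
) -> list[AmpliconRegion]:
    """Load a panel from FASTA (+ optional BED of CpG sites).

    Without a BED, CpG positions are taken as every CG dinucleotide in
    each reference — correct for panels written by this package.
    """
    cpgs_by_region: dict[str, list[int]] = {}
    if bed_path is not None:
        with open(bed_path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = line.split("\t")
                if len(fields) >= 4 and fields[3] == "CpG":
                    cpgs_by_region.setdefault(fields[0], []).append(int(fields[1]))
    panel = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in cpgs_by_region:
            pos = sorted(cpgs_by_region[rec.id])
        else:
            pos = [m for m in range(len(seq) - 1) if seq[m : m + 2] == "CG"]
        panel.append(
            AmpliconRegion(
                region_id=rec.id,
                ref_seq=seq,
                cpg_positions=tuple(pos),
                conversion_mode=conversion_mode,
                genomic_label=rec.description.split(maxsplit=1)[-1]
                if rec.description != rec.id
                else "",
            )
        )
    return panel
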
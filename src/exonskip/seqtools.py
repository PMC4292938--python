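"""Deterministic sequence arithmetic: cDNA intervals, frameshift codons, and
junction-targeting siRNA duplex design.

Coordinate convention: cDNA (c.) coordinates are 1-based and inclusive with
c.1 at the A of the start codon, so codon ``k`` spans ``c.(3k-2)..c.(3k)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "CdnaInterval",
    "interval_length",
    "frameshift_codon",
    "deletion_product_length",
    "DuplexDesign",
    "design_sirna",
    "junction_target_window",
]

_DNA_ALPHABET = set("ACGT")


@dataclass(frozen=True, order=True)
class CdnaInterval:
    """A 1-based inclusive interval on a cDNA (c.-notation)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"cDNA coordinates are 1-based; got start={self.start}")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, other: "CdnaInterval") -> bool:
        return self.start <= other.start and other.end <= self.end


def interval_length(interval: CdnaInterval) -> int:
    """Number of bases in a 1-based inclusive interval: end - start + 1."""
    return len(interval)


def frameshift_codon(deletion_start: int) -> int:
    """1-based index of the codon containing the first deleted base.

    A deletion whose length is not a multiple of three shifts the reading
    frame from this codon onward; e.g. removing exon 12 (starting at c.2208)
    truncates the protein from residue ceil(2208 / 3) = 736.
    """
    if deletion_start < 1:
        raise ValueError("deletion_start must be >= 1")
    return math.ceil(deletion_start / 3)


def deletion_product_length(amplicon: CdnaInterval, deletion: CdnaInterval) -> int:
    """Size of the PCR product after an internal deletion.

    The deletion must lie entirely inside the amplicon; the result is
    ``len(amplicon) - len(deletion)``.
    """
    if not amplicon.contains(deletion):
        raise ValueError(
            f"deletion c.{deletion.start}-c.{deletion.end} is not contained in "
            f"amplicon c.{amplicon.start}-c.{amplicon.end}"
        )
    return interval_length(amplicon) - interval_length(deletion)


@dataclass(frozen=True)
class DuplexDesign:
    """An siRNA duplex against a 19-base DNA target.

    ``sense_strand`` / ``antisense_strand`` are the synthesized strands:
    RNA transliteration of the target (resp. its reverse complement), ``*``
    marking the phosphorothioate linkages between the first three and last
    three bases of the 19-nt core, and a DNA ``TT`` dinucleotide appended at
    each 3' end.
    """

    target_dna: str
    sense_strand: str
    antisense_strand: str
    overhang: str = "TT"

    @property
    def sense_core(self) -> str:
        return self.sense_strand.replace("*", "")[:-2]

    @property
    def antisense_core(self) -> str:
        return self.antisense_strand.replace("*", "")[:-2]


def _thioate_annotate(core: str, overhang: str = "TT") -> str:
    """Insert '*' at the three terminal linkages of each end of the core."""
    n = len(core)
    starred_links = {0, 1, 2, n - 4, n - 3, n - 2}  # link i joins base i and i+1
    parts = []
    for i, base in enumerate(core):
        parts.append(base)
        if i in starred_links:
            parts.append("*")
    return "".join(parts) + overhang


def design_sirna(target_dna: str) -> DuplexDesign:
    """Design the phosphorothioate-protected duplex for a 19-mer DNA target.

    The sense strand is the RNA transliteration of the target; the antisense
    strand is the RNA transliteration of its reverse complement.  Both carry
    phosphorothioate marks on the first and last three linkages of the 19-nt
    core and a 3' DNA TT overhang, and the cores are perfectly complementary.
    """
    target = str(target_dna).upper()
    if len(target) != 19:
        raise ValueError(f"target must be a 19-base DNA sequence, got length {len(target)}")
    if not set(target) <= _DNA_ALPHABET:
        bad = "".join(sorted(set(target) - _DNA_ALPHABET))
        raise ValueError(f"target must be over A/C/G/T; found {bad!r}")
    sense_core = str(Seq(target).transcribe())
    antisense_core = str(Seq(target).reverse_complement().transcribe())
    return DuplexDesign(
        target_dna=target,
        sense_strand=_thioate_annotate(sense_core),
        antisense_strand=_thioate_annotate(antisense_core),
    )


def junction_target_window(
    exon_end_coord: int, flank: int = 20
) -> tuple[CdnaInterval, CdnaInterval]:
    """The +/- ``flank``-base window around a splice junction.

    ``exon_end_coord`` is the coordinate (on the spliced mutant transcript)
    of the last base before the junction.  Returns the upstream interval of
    ``flank`` bases ending there and the downstream interval of ``flank``
    bases starting just after it.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if exon_end_coord <= flank:
        raise ValueError("exon_end_coord must exceed flank")
    upstream = CdnaInterval(exon_end_coord - flank + 1, exon_end_coord)
    downstream = CdnaInterval(exon_end_coord + 1, exon_end_coord + flank)
    return upstream, downstream
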
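"""Bundled reference constants for the CD22 exon-12 skipping analysis.

These are the published constants the analysis consumes as data: the genomic
alignments of the ten probes in probeset 217422_s_at (CD22 exons 10-14), the
cDNA coordinates of the RT-PCR amplicons and of the skipped exon, and the
junction-targeting siRNA sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from .exon_index import ProbeAlignmentRecord, parse_probe_alignments
from .seqtools import CdnaInterval

__all__ = [
    "Fixtures",
    "load_fixtures",
    "SIRNA_TARGET_SENSE_SEQUENCES",
    "SIRNA_SENSE_STRAND",
    "SIRNA_ANTISENSE_STRAND",
    "SCRAMBLED_SENSE_STRAND",
    "SCRAMBLED_ANTISENSE_STRAND",
    "PRIMER_AMPLICONS",
    "EXON12_DELETION",
    "PRINTED_MUTANT_P7_PRODUCT_BP",
]

#: The three AA-motif 19-mer target (sense) DNA sequences covering the
#: exon 11 - exon 13 junction of the mis-spliced transcript.
SIRNA_TARGET_SENSE_SEQUENCES = (
    "AAAGAGATGCAGAGTCCTC",
    "GAGATGCAGAGTCCTCAGA",
    "AAGAGATGCAGAGTCCTCA",
)

#: The synthesized duplex: phosphorothioate linkages marked "*", DNA "TT"
#: 3' overhangs.
SIRNA_SENSE_STRAND = "A*A*A*GAGAUGCAGAGUC*C*U*CTT"
SIRNA_ANTISENSE_STRAND = "G*A*G*GACUCUGCAUCUC*U*U*UTT"
SCRAMBLED_SENSE_STRAND = "U*U*C*UCCGAACGUGUCA*C*G*UTT"
SCRAMBLED_ANTISENSE_STRAND = "A*C*G*UGACACGUUCGGA*G*A*ATT"

#: RT-PCR amplicons on the CD22 cDNA (c.-coordinates, 1-based inclusive).
PRIMER_AMPLICONS = {
    "P7": CdnaInterval(2180, 2361),  # exon 11 -> exon 13, spans exon 12; 182 bp
    "P9": CdnaInterval(2304, 2463),  # exon 12 -> exon 14, spans exon 13; 160 bp
    "P10": CdnaInterval(433, 645),  # exon 4 control; 213 bp
}

#: The skipped exon on the cDNA.
EXON12_DELETION = CdnaInterval(2208, 2327)

#: Published size of the mutant P7 product.  Arithmetically the deletion
#: leaves 182 - 120 = 62 bases; the published figure is 63 bp.  The package
#: reports the arithmetic value and keeps the published one here so the
#: one-base discrepancy stays visible.
PRINTED_MUTANT_P7_PRODUCT_BP = 63


@dataclass(frozen=True)
class Fixtures:
    probe_alignments: tuple[ProbeAlignmentRecord, ...]
    sirna_targets: tuple[str, ...] = SIRNA_TARGET_SENSE_SEQUENCES
    primer_amplicons: dict = field(default_factory=lambda: dict(PRIMER_AMPLICONS))
    exon12_deletion: CdnaInterval = EXON12_DELETION


def load_probe_alignments() -> list[ProbeAlignmentRecord]:
    """Parse the bundled 217422_s_at probe alignment records."""
    text = (
        resources.files("exonskip")
        .joinpath("data/probe_alignments_217422_s_at.txt")
        .read_text(encoding="utf-8")
    )
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return parse_probe_alignments(lines)


def load_fixtures() -> Fixtures:
    """Return all bundled constants as structured data."""
    return Fixtures(probe_alignments=tuple(load_probe_alignments()))
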
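#!/usr/bin/env python
"""Junction siRNA designs and RT-PCR coordinate arithmetic.

Designs the phosphorothioate-protected duplexes for the three bundled
19-mer targets covering the exon 11 - exon 13 junction of the mis-spliced
transcript, and tabulates the amplicon sizes, the skipped-exon product and
the frameshift codon from the bundled cDNA coordinates.
"""

from pathlib import Path

import pandas as pd

from exonskip.fixtures import load_fixtures, PRINTED_MUTANT_P7_PRODUCT_BP
from exonskip.io import write_table
from exonskip.seqtools import (
    deletion_product_length,
    design_sirna,
    frameshift_codon,
    interval_length,
)

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    fx = load_fixtures()

    rows = []
    for target in fx.sirna_targets:
        duplex = design_sirna(target)
        rows.append(
            {"target_dna": target, "sense": duplex.sense_strand,
             "antisense": duplex.antisense_strand}
        )
        print(f"target 5'-{target}-3'")
        print(f"  sense     5'-{duplex.sense_strand}-3'")
        print(f"  antisense 5'-{duplex.antisense_strand}-3'")
    write_table(pd.DataFrame(rows), ROOT / "results" / "sirna_designs.tsv", index=False)

    print()
    for name, iv in fx.primer_amplicons.items():
        print(f"{name}: c.{iv.start}-c.{iv.end} -> {interval_length(iv)} bp")
    deletion = fx.exon12_deletion
    mutant = deletion_product_length(fx.primer_amplicons["P7"], deletion)
    print(f"exon-12 deletion c.{deletion.start}-c.{deletion.end} "
          f"({interval_length(deletion)} bases) -> mutant P7 product {mutant} bp "
          f"(reported as {PRINTED_MUTANT_P7_PRODUCT_BP} bp; 1-base discrepancy)")
    print(f"frameshift starts at residue {frameshift_codon(deletion.start)}")


if __name__ == "__main__":
    main()
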
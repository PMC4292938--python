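# Genomic alignments of the HG-U133 Plus 2.0 probes in probeset 217422_s_at
# (CD22, exons 10-14), one probe per line, coordinates 1-based inclusive.
HG-U133_PLUS_2:217422_S_AT_11 aligned to chr19: 35837525–35837549 (Exon 14)
HG-U133_PLUS_2:217422_S_AT_10 aligned to chr19: 35837478–35837502 (Exon 14)
HG-U133_PLUS_2:217422_S_AT_8 aligned to chr19: 35837100–35837124 (Exon 13)
HG-U133_PLUS_2:217422_S_AT_9 aligned to chr19: 35837117–35837139 (Exon 13)
HG-U133_PLUS_2:217422_S_AT_7 aligned to chr19:35836590–35836614 (Exon 12)
HG-U133_PLUS_2:217422_S_AT_6 aligned to chr19:35836566–35836590 (Exon 12)
HG-U133_PLUS_2:217422_S_AT_5 aligned to chr19:35836535–35836559 (Exon 12)
HG-U133_PLUS_2:217422_S_AT_4 aligned to chr19:35835979–35836003 (Exon 11)
HG-U133_PLUS_2:217422_S_AT_3 aligned to chr19:35835811–35835960 (Exon 11)
HG-U133_PLUS_2:217422_S_AT_2 aligned to chr19:35835741–35835765 (Exon 10)
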
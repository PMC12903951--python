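# SQK-PCS109 cDNA-PCR sequencing kit primers (strand-switching primer at the
# 5' end, VN primer on the polyA side). Configuration data — verify against
# the vendor's current kit documentation before production use.
kit_name: PCS109
front_ap: TTTCTGTTGGTGCTGATATTGCTGGG
rear_ap: ACTTGCCTGTCGCTCTATCTTC
polya_side: rear
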
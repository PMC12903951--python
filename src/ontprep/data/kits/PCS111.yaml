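# SQK-PCS111 cDNA-PCR sequencing kit primers (same SSP/VNP pair as PCS109 for
# alignment purposes; UMI bases are not part of the matched pattern).
# Configuration data — verify against the vendor's current kit documentation.
kit_name: PCS111
front_ap: TTTCTGTTGGTGCTGATATTGCTGGG
rear_ap: ACTTGCCTGTCGCTCTATCTTC
polya_side: rear
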
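# miRNA families established as phasiRNA triggers.
# One family per line; '#' starts a comment. Edit freely.
miR173
miR390
miR393
miR426
miR482
miR828
miR1507
miR1509
miR1514
miR2109
miR2118
miR2275
miR3623
miR4392
miR6445
miR7122
miR9863
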
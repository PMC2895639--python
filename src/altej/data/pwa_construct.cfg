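# P-element excision gap construct: each arm carries the 8-bp target-site
# duplication (lowercase) and the 17-nt 3' single-stranded tail (uppercase).
name = P_wa
left_arm = acccagacCATGATGAAATAACATA
right_arm = TATGTTATTTCATCATGacccagac
left_overhang_len = 17
right_overhang_len = 17
tsd_len = 8
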
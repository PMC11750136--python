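region,Brain #1,Brain #2,Brain #3,Brain #4,Brain #5
EN,288,201,310,210,250
BLA,85,107,175,208,118
SP (lateral),27,36,69,69,17
SP (medial),69,111,130,127,121
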
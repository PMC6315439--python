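symbol	direction	studies
CST3	down	B35;B37;B38;B39
CHI3L1	up	B32;B34;B41
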
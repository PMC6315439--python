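symbol	direction	studies
ALDOA	up	B47;B48;B49;B53;B57
SOD1	up	B53;B54;B56
SOD2	up	B44;B48;B52;B58
YWHAG	up	B44;B52;B54
CALR	up	B44;B48;B50
GAPDH	up	B49;B53;B54
HSPB1	up	B44;B54;B56
HSPA8	up	B44;B48;B54
PRDX2	up	B44;B48;B51
PRDX6	up	B48;B49;B56
GFAP	up	B47;B54;B62
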
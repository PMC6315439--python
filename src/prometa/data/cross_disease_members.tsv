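symbol	als_studies	sma_studies
CALR	B44;B48;B50	B21;B64
SOD1	B53;B54;B56	B65;B66;B67
ALDOA	B47;B48;B49;B53;B57	B22;B65;B66
HSPD1	B44;B58	B22;B65;B66
PRDX2	B44;B48;B51	B66;B67
VDAC1	B47;B52;B57	B64;B66
VIM	B44;B47;B54	B21;B64
PGK1	B48;B49;B60	B22;B66
ANXA5	B52;B54	B66;B68
HSP90B1	B47;B54	B64;B66
GAPDH	B49;B53;B54	B65;B66;B67
HSP90AA1	B44;B54	B22;B64;B65
ATP5A1	B47;B54;B57;B60	B22;B66
YWHAG	B44;B52;B54	B22;B66;B68
CNP	B44;B52	B64
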
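1OB4
1OB7
2OXL
3MD5
1AGN
1NKO
2OCT
3FVA
3DWV
3MGN
4DPZ
2J32
3MEA
3A0M
3IVV
3W4Q
3P6J
2DKO
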
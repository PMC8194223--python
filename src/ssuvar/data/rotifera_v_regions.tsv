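name	start	length
V1	64	39
V2	187	125
V3	524	83
V4	700	286
V5	1174	50
V6	1374	42
V7	1491	79
V8	1660	73
V9	1880	54
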
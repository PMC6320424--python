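sex,prefix
M,63
M,64
M,65
M,66
M,67
M,628
F,185
F,600
F,601
F,602
F,603
F,604
F,605
F,606
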
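# genes: A B C D
A D
B D
Root A
Root B
Root C
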
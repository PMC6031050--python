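# genes: A B F G H
A B
F G
G H
Root A
Root F
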
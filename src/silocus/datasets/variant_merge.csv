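variant,canonical
A01a,A01
A01b,A01
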
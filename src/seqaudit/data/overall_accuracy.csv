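transformation,printed_accuracy
aac,0.91
sez,0.90
dav,0.88
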
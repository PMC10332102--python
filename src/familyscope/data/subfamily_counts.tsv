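subfamily	count
ERF	63
DREB	31
AP2	37
RAV	4
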
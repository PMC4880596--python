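# Calcium setpoints of the two-population model, for `neuroplast analyze calcium`.
ex: 0.05
in: 0.2
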
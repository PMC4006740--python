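16	1649999	7250000	F1-IV.3,F2-IV.3	8
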
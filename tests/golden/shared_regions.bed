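16	195027	7043990	F1-IV.3,F2-IV.3	29
16	9189859	9711842	F1-IV.3,F2-IV.3	25
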
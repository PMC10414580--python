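codes: [NSR, CRBBB, AF, QAb, LAD, STach]
normal_code: NSR
significance: 1
similarity: 0.5
contradiction: [[STach, NSR]]
prevalence_floor: 1
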
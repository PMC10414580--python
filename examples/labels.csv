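instance_id,truth,prediction
p01,CRBBB|AF|QAb,CRBBB|AF
p02,NSR,NSR
p03,AF,AF|LAD
p04,CRBBB,STach
p05,AF|QAb,AF|QAb
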
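study_id,d1_sequence,d2_allocation,d3_blinding,d4_attrition,d5_reporting,d6_other
REFLEX,unclear,unclear,low,unclear,low,low
WA16291,unclear,unclear,low,low,low,low
DANCER,unclear,unclear,unclear,low,low,low
SERENE,unclear,unclear,unclear,low,low,low
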
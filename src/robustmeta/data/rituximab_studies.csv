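study_id,r_control,n_control,r_treatment,n_treatment
REFLEX,10,201,80,298
WA16291,5,40,17,40
DANCER,16,122,41,122
SERENE,16,172,44,170
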
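patient_id,death_date
P002,2011-04-15
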
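patient_id,procedure_date,procedure
P003,2014-10-01,ASCT
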
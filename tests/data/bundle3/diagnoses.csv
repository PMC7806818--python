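patient_id,claim_date,icd9,position,setting
P001,2013-02-01,203.00,primary,outpatient
P001,2013-03-01,203.01,primary,outpatient
P001,2012-06-01,285.9,secondary,outpatient
P002,2010-05-20,203.0,primary,outpatient
P002,2010-06-01,203,secondary,inpatient
P003,2014-01-10,203.00,primary,outpatient
P003,2014-02-10,203.00,primary,outpatient
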
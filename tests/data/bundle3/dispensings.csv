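patient_id,dispense_date,drug,days_supply,setting
P001,2013-02-05,bortezomib,28,outpatient
P001,2013-02-05,thalidomide,28,outpatient
P001,2013-03-05,bortezomib,28,outpatient
P001,2013-03-05,thalidomide,28,outpatient
P001,2013-04-02,bortezomib,28,outpatient
P001,2013-04-02,thalidomide,28,outpatient
P002,2010-06-01,melphalan,30,outpatient
P002,2010-06-01,prednisolone,30,outpatient
P002,2010-07-01,melphalan,30,outpatient
P002,2010-07-01,prednisolone,30,outpatient
P003,2014-01-15,thalidomide,28,outpatient
P003,2014-02-12,thalidomide,28,outpatient
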
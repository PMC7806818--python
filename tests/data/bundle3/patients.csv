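patient_id,birth_date,sex,enroll_start,enroll_end
P001,1950-03-10,female,2005-01-01,
P002,1940-07-22,male,2006-05-01,2016-06-30
P003,1975-11-02,male,2012-01-01,
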
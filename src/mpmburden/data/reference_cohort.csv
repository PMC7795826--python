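patient_id,n_biopsies_taken,n_positive
P01,13,0
P02,13,0
P03,13,0
P04,13,0
P05,13,0
P06,13,0
P07,13,0
P08,13,0
P09,13,0
P10,13,0
P11,13,0
P12,13,0
P13,13,0
P14,13,0
P15,13,0
P16,13,0
P17,13,0
P18,13,0
P19,13,0
P20,13,1
P21,13,1
P22,13,1
P23,13,1
P24,13,2
P25,13,2
P26,13,7
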
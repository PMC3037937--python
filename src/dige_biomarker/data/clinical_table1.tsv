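patient_id	tumor_stage	gleason	hormone_therapy	psa
T 4850	pT2c	3+4	NA	NA
T 4484	pT2c	3+4	No	8.6
T 2443	pT2c	3+3	No	7.9
T 2258	pT2a	3+3	No	3.9
T 3969	pT3b	4+3	No	30.4
T 3972	pT2c	3+4	No	13.77
T 2621	pT2c	3+4	No	7.53
T 2266	pT2a	3+4	No	5.53
T 3455	pT2c	3+3	No	5.5
T 2620	pT2c	4+3	No	9.51
T 4486	pT2c	3+4	No	29.41
T 2267	pT3a	3+4	No	NA
T 3974	pT3a	4+5	No	6.3
T 2437	pT2c	4+3	No	11.2
T 4167	pT3a	3+4	No	5.33
T 3132	pT2c	3+4	No	13.56
T 2442	pT2c	3+4	No	18.8
T 2933	pT2c	4+3	No	7.09
T 2259	pT2c	3+4	No	8.9
T 2936	pT2c	3+4	No	4.19
T 2434	pT2c	3+4	No	10.3
T 4766	NA	NA	NA	NA
T 3982	NA	NA	NA	NA
T 36126	NA	NA	NA	NA
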
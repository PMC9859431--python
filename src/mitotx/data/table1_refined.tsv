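#gene	strand	start	end	start_codon	stop_codon
trnI	J	1	71
trnQ	N	142	73
trnM	J	155	224
ND2	J	229	1204	AUA	U
trnW	J	1205	1268
trnC	N	1329	1261
trnY	N	1402	1337
COX1	J	1407	2942	UUG	UAA
trnL2	J	2949	3019
COX2	J	3020	3698	AUA	U
trnK	J	3699	3770
trnD	J	3775	3842
ATP8	J	3844	4002	UUG	UAA
ATP6	J	3996	4665	AUG	U
COX3	J	4666	5453	AUG	UA
trnG	J	5454	5518
ND3	J	5519	5872	AUA	UAA
trnA	J	5881	5949
trnR	J	5950	6017
trnN	J	6019	6084
trnS1	J	6085	6153
trnE	J	6154	6218
trnF	N	6282	6217
ND5	N	7990	6290	AUU	UAA
trnH	N	8057	7992
ND4	N	9384	8059	AUG	UAG
ND4L	N	9665	9378	UUG	UAA
trnT	J	9668	9732
trnP	N	9797	9734
ND6	J	9801	10280	AUG	UAA
CYTB	J	10282	11418	AUG	UAA
trnS2	J	11421	11489
ND1	N	12433	11510	AUG	UAA
trnL1	N	12500	12434
lrRNA	N	13774	12501
trnV	N	13841	13775
srRNA	N	14661	13842
CR	J	14662	16214
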
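target_class	total_predicted	predicted_unconfirmed	confirmed	percent_confirmed_reported
GPCR	10650	5708	4942	46
Enzymes	4081	1374	2707	66
Kinase	3768	688	3080	81
NuclearReceptor	1293	684	609	47
OtherFamilies	605	197	408	67
Transporter	1788	651	1137	63
Unclassified	1057	429	628	59
Cytochrome	2827	36	2791	98
IonChannel	1303	322	981	75
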
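drug	intended_targets	cmax_um	pcmax_reported	n_offtargets_pic50_gt6
Afatinib	EGFR;HER2;HER4	0.0520	7.2800	11
Bosutinib	BCR-Abl;Src	0.3770	6.4200	>50
Celecoxib	COX-2	4.6000	5.3400	19
Ceritinib	ALK	1.2100	5.9200	17
Erlotinib	EGFR	3.1500	5.5000	25
Finasteride	5-Alpha Reductase	0.1240	6.9100	4
Gefitinib	EGFR	0.3560	6.4500	21
Hydroxychloroquine	Cathepsin L	0.3500	6.4600	8
Imiquimod	TLR7R	0.0056	8.2500	5
Lapatinib	ERBB2;EGFR	4.1800	5.3800	11
Olaparib	PARP	13.1000	4.8800	9
Sirolimus	mTOR	0.0160	7.7800	12
Tamoxifen Citrate	Estrogen Receptor	0.1080	6.9700	21
Teniposide	Topoisomerase II	23.1000	4.6400	9
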
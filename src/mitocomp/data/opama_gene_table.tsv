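#species	Otolithoides_pama_OQ784575.1
#genome_length	16513
name	start	end	strand	class
trnF	1	69	H	tRNA
rrnS	70	1019	H	rRNA
trnV	1020	1091	H	tRNA
rrnL	1093	2795	H	rRNA
trnL2	2796	2869	H	tRNA
nad1	2870	3844	H	PCG
trnI	3849	3918	H	tRNA
trnQ	3918	3988	L	tRNA
trnM	3988	4056	H	tRNA
nad2	4057	5103	H	PCG
trnW	5103	5174	H	tRNA
trnA	5175	5243	L	tRNA
trnN	5246	5318	L	tRNA
OL	5319	5353	L	NC
trnC	5354	5419	L	tRNA
trnY	5420	5489	L	tRNA
cox1	5491	7047	H	PCG
trnS2	7043	7113	L	tRNA
trnD	7117	7185	H	tRNA
cox2	7193	7883	H	PCG
trnK	7884	7957	H	tRNA
atp8	7959	8126	H	PCG
atp6	8117	8800	H	PCG
cox3	8800	9585	H	PCG
trnG	9585	9655	H	tRNA
nad3	9656	10004	H	PCG
trnR	10005	10073	H	tRNA
nad4l	10074	10370	H	PCG
nad4	10364	11744	H	PCG
trnH	11745	11813	H	tRNA
trnS1	11814	11881	H	tRNA
trnL1	11889	11961	H	tRNA
nad5	11962	13800	H	PCG
nad6	13797	14318	L	PCG
trnE	14319	14387	L	tRNA
cytb	14392	15532	H	PCG
trnT	15533	15604	H	tRNA
trnP	15609	15678	L	tRNA
CR	15679	16513	H	NC
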
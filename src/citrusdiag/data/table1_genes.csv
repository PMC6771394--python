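pathway,code,gene_id,chromosome,begin,end,size_bp,n_introns,n_exons,total_snps,interspecific,interspecific_pct,intraspecific,intraspecific_pct,intraspecific_type
carotenoid,CCS_8,Ciclev10028245m,8,19259623,19261508,1886,0,1,48,14,29.1,6,12.5,MM
sugar,GT_9,Ciclev10004221m,9,15981287,15989471,8185,6,6,105,48,45.7,33,31.4,MM
chlorophyll,PAO_8,Ciclev10028147m,8,21112804,21117215,4412,6,7,159,19,11.9,13,8.1,RR (6) MM (7)
carotenoid,CRTISO_6,Ciclev10011230m,6,19578179,19583475,3018,5,6,104,23,22.1,0,0,-
carotenoid,DXS_1,Ciclev10007595m,1,2200405,2205620,2580,9,10,89,46,51.7,18,20.2,MM
carotenoid,DXS_7,Ciclev10024949m,7,5042508,5046278,2676,9,10,72,23,31.9,15,20.8,RR
carotenoid,DXS_9,Ciclev10004432m,9,2353442,2357780,2786,9,10,71,29,40.8,8,11.26,RR
carotenoid,HYB_9,Ciclev10005481m,9,29488658,29491181,2524,6,7,55,17,30.9,4,7.27,RR
carotenoid,LCYb_9,Ciclev10004730m,9,22728310,22730086,1777,1,2,27,16,38.5,8,15.7,MM
carotenoid,LCYe_1,Ciclev10008410m,1,10946316,10949617,3302,6,7,39,21,53.8,0,,-
carotenoid,NCED_2,Ciclev10014639m,2,35235517,35237892,2376,0,1,44,11,25.0,4,9.1,RR
carotenoid,NCED_3,Ciclev10019364m,3,29351854,29354190,2337,0,1,32,15,46.8,1,3.1,RR
carotenoid,NCED_9,Ciclev10006710m,9,10202439,10204217,1779,0,1,50,8,16.0,21,42.0,RR (11) MM (10)
carotenoid,PDS_9a,Ciclev10005632m,9,17789634,17793258,3625,6,7,54,24,44.4,9,16.6,MM
carotenoid,PDS_9b,Ciclev10007114m,9,17778571,17785482,6912,5,6,143,81,56.6,16,11.1,MM
carotenoid,PSY_6,Ciclev10011841m,6,21390477,21396087,5611,5,6,172,45,26.1,36,20.9,RR (17) MM (19)
carotenoid,ZEP_7,Ciclev10025089m,7,3222483,3228894,6412,13,14,98,40,40.8,16,16.3,MM
carotenoid,Z-ISO_3,Ciclev10020648m,3,39692471,39696185,1644,3,4,87,22,25.2,20,22.9,MM
sugar,INV_6,Ciclev10013701m,6,20333619,20338112,4494,5,6,141,36,25.5,42,29.7,RR
sugar,INV_7a,Ciclev10025243m,7,6557251,6560551,3301,3,4,80,14,17.5,14,17.5,RR
sugar,INV_7b,Ciclev10025259m,7,6561319,6564055,2737,3,4,39,24,61.5,3,7.7,RR
sugar,INV_9,Ciclev10004465m,9,27282487,27287560,5074,5,6,158,24,15.2,42,26.5,MM
sugar,SPP_2,Ciclev10015425m,2,645817,651088,5272,6,7,69,41,59.4,6,8.7,MM
sugar,SPP_6,Ciclev10011822m,6,19586148,19590349,4202,3,4,111,33,29.7,19,17.1,MM
sugar,SPS_1,Ciclev10007311m,1,25880824,25887976,7153,6,7,149,68,45.6,19,12.75,MM
sugar,SPS_1a,Ciclev10007312m,1,1634245,1639542,5298,6,7,130,1,0.76,77,59.2,MM
sugar,SPS_3,Ciclev10018655m,3,23001026,23009675,8650,9,10,243,31,12.7,31,12.7,RR (7) MM (24)
sugar,SUSY_1a,Ciclev10010343m,1,24769195,24772566,3372,10,11,67,21,31.3,18,26.8,RR
sugar,SUSY_1b,Ciclev10007483m,1,24814539,24820057,4649,6,7,60,20,33.3,11,18.3,RR
sugar,SUSY_3,Ciclev10018889m,3,46011238,46017249,6012,10,11,83,23,27.7,17,20.5,RR
sugar,SUSY_6,Ciclev10011062m,6,21404402,21408079,3678,6,7,43,24,55.8,9,20.9,MM
sugar,SUSY_9,Ciclev10004341m,9,1499634,1505333,5700,12,13,69,32,46.3,6,8.7,RR
sugar,SUT1_5,Ciclev10000828m,5,39525923,39529412,3490,2,3,97,10,10.3,0,0,-
sugar,SUT2_4,Ciclev10030996m,4,23705523,23711365,5843,9,10,105,38,36.1,16,15.2,RR
sugar,SUT4_5,Ciclev10000941m,5,35065343,35070910,5568,4,4,75,27,36,16,21.3,RR
sugar,FEH_1,Ciclev10007827m,1,4119709,4122521,2813,3,4,76,44,57.8,0,0,-
chlorophyll,GDR_2,Ciclev10015206m,2,10231921,10233354,1432,0,1,48,4,8.3,7,14.6,MM
chlorophyll,GDR_3,Ciclev10020061m,3,7268419,7270557,2139,1,2,55,7,12.7,4,7.2,MM
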
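pair_id,taxon,iso,gain,loss,total,population,branch_length
1,Agta,agt,50,32,82,780,138.91
1,Gaddang,gad,54,34,88,30000,138.91
2,AmbaiYapen,amk,112,36,148,10100,777.07
2,WindesiWandamen,wad,117,12,129,5000,777.07
3,AmbrymSouthEast,tvk,74,45,119,3700,0.07
3,PaameseSouth,pma,51,31,82,6000,0.07
4,Anakalang,akg,12,23,35,16000,828.02
4,Wanukaka,wnk,23,36,59,10000,828.02
5,Aputai,apx,14,16,30,150,111.68
5,Perai,wet,12,14,26,280,111.68
6,As,asz,86,26,112,230,1905.88
6,BigaMisool,xmt,85,25,110,1250,1905.88
7,Atoni,aoz,124,46,170,700000,1224.4
7,RotiTermanu_D,twu,97,18,115,30000,1224.4
8,AttaPamplona,att,26,18,44,1000,0.0
8,Ibanag,ibg,34,28,62,500000,0.0
9,Avava,tmb,57,67,124,700,552.95
9,Neveei,vnm,44,42,86,500,552.95
10,Bali,ban,106,58,164,3330000,1897.9
10,Sasak,sas,73,59,132,2100000,1897.9
11,Baree,pmf,80,36,116,137000,9.22
11,Mori,xmz,104,48,152,14000,9.22
12,Belait,beg,72,34,106,1000,1107.19
12,BerawanLongTerawan,zbw,85,43,128,1000,1107.19
13,Bintulu,bny,70,38,108,4200,2335.48
13,MelanauMukah,mel,68,40,108,113000,2335.48
14,Bobot,bty,47,21,68,4500,971.12
14,Bonfia,bnf,50,17,67,1000,971.12
15,Bonerate,bna,27,13,40,9500,0.0
15,Popalia,bhq,27,12,39,130000,0.0
16,BontokGuinaang,bnc,56,34,90,40700,0.0
16,KankanayNorthern,xnn,37,33,70,70000,0.0
17,BugineseSoppeng_D,bug,80,50,130,5000000,2102.0
17,TaeSToraja,rob,58,41,99,340000,2102.0
18,Bugotu,bgt,107,51,158,4050,0.2
18,Nggela,nlg,72,30,102,11900,0.2
19,Bukat,bvk,100,47,147,400,1102.31
19,Lahanan,lhn,71,25,96,350,1102.31
20,Buli,bzq,114,19,133,2520,1578.2
20,Giman,gzn,152,41,193,2900,1578.2
21,BuruNamroleBay,mhs,110,38,148,33000,2158.07
21,Soboyo,tlv,121,53,174,4520,2158.07
22,Bwaidoga,bwd,52,14,66,6500,4.1
22,Diodio,ddi,57,29,86,2180,4.1
23,Cebuano,ceb,31,44,75,15800000,553.03
23,Surigaonon,sgd,70,42,112,400000,553.03
24,ChekeHolo,mrn,94,61,155,10800,313.81
24,KilokakaYsabel,jaj,34,23,57,10,313.81
25,Dai,dij,52,18,70,820,0.01
25,NorthBabar,bcd,50,17,67,1000,0.01
26,Dehu,dhv,190,22,212,13000,1722.11
26,Nengone,nen,185,30,215,8720,1722.11
27,Dobuan,dob,73,38,111,10000,667.39
27,Molima,mox,81,35,116,4010,667.39
28,Emae,mmw,4,23,27,400,0.0
28,UveaWest,uve,2,24,26,2200,0.0
29,Gapapaiwa,pwg,76,18,94,3000,756.15
29,Ubir,ubr,101,44,145,2560,756.15
30,Geser,ges,63,23,86,36500,476.2
30,Watubela,wah,71,36,107,4000,476.2
31,GhariGuadalcanal,gri,39,31,70,12100,0.01
31,Tolo,tlr,33,33,66,12500,0.01
32,GorontaloHulondalo,gor,96,50,146,1000000,0.12
32,Kaidipang,kzp,71,22,93,26600,0.12
33,HituAmbon,htu,64,27,91,16000,531.14
33,Paulohi,plh,73,33,106,50,531.14
34,HoavaNewGeorgia,hoa,61,41,102,460,400.12
34,MarovoNewGeorgia,mvo,67,54,121,8090,400.12
35,Imroing,imr,31,24,55,560,327.51
35,TelaMasbuar,tvm,25,16,41,1050,327.51
36,Inibaloi,ibl,35,33,68,111000,117.06
36,KallahanKayapaProper,kak,22,20,42,15000,117.06
37,ItnegBinongan,itb,34,40,74,7500,0.01
37,KalingaGuinaangLubuagan_D,knb,29,36,65,30000,0.01
38,Jawe,jaz,109,24,133,990,0.0
38,Nelemwa,nee,118,26,144,1090,0.0
39,Kalagan,kqe,33,38,71,70000,0.0
39,Mansaka,msk,25,31,56,57800,0.0
40,Kapampangan,pam,74,41,115,1900000,1165.44
40,SambalBotolan,sbl,108,56,164,32900,1165.44
41,Kapingamarangi,kpg,4,18,22,3000,226.89
41,Nukuoro,nkr,3,16,19,860,226.89
42,Kedang,ksx,106,37,143,30000,1219.42
42,Lamaholot,slp,93,33,126,180000,1219.42
43,Kemak,kem,65,16,81,72000,866.01
43,Mambai,mgm,80,27,107,131000,866.01
44,Kerinci,kvr,56,33,89,260000,188.09
44,Minangkabau,min,29,37,66,5530000,188.09
45,Komering,kge,74,37,111,470000,1899.99
45,Lampung,ljp,45,29,74,827000,1899.99
46,KoronadalBlaan,bpr,10,11,21,150000,415.53
46,SaranganiBlaan,bps,4,5,9,90800,415.53
47,Kuanua,ksd,111,31,142,61000,652.24
47,LungaLungaMinigir,vmg,83,21,104,600,652.24
48,KwaraaeSolomonIslands,kwf,43,33,76,32400,197.9
48,Toambaita,mlu,47,49,96,12600,197.9
49,Leipon,lek,42,22,64,650,840.7
49,Loniu,los,43,20,63,460,840.7
50,Lenakel,tnl,34,25,59,11500,0.0
50,TannaSouthwest,nwi,26,13,39,4500,0.0
51,Levei,tlx,62,16,78,1600,1480.51
51,Likum,lib,56,13,69,80,1480.51
52,Lou,loj,74,36,110,1000,2.12
52,Nauna,ncn,64,25,89,100,2.12
53,Luangiua,ojv,6,14,20,2370,189.54
53,Sikaiana,sky,3,17,20,730,189.54
54,Maanyan,mhy,74,22,96,150000,1100.0
54,MerinaMalagasy,plt,119,54,173,7520000,1100.0
55,Manam,mva,94,36,130,7950,171.1
55,Wogeo,woc,87,34,121,1620,171.1
56,Mangareva,mrv,1,28,29,600,670.85
56,Marquesan,mrq,23,33,56,5400,670.85
57,ManoboIlianenKibudtungan_D,mbi,22,34,56,14600,125.89
57,WBukidnonManobo,mbb,23,31,54,15000,125.89
58,ManoboKalamansigCotabatoParil_D,mta,47,48,95,30000,306.23
58,ManoboSaranganiKayaponga_D,mbs,33,34,67,58000,306.23
59,Masiwang,bnf,17,4,21,1000,0.0
59,Werinama,bty,19,7,26,4500,0.0
60,Matukar,mjk,51,16,67,430,556.52
60,Megiar,tbc,49,18,67,40000,556.52
61,Modang,mxd,90,24,114,15300,339.52
61,PunanKelai,sge,83,21,104,2000,339.52
62,Mokilese,mkj,15,9,24,1500,1232.98
62,Ponapean,pon,34,29,63,31350,1232.98
63,Mortlockese,mrl,2,6,8,5900,156.44
63,Satawalese,stw,1,7,8,460,156.44
64,Mota,mtt,87,33,120,900,933.62
64,Mwotlap,mlv,68,42,110,1800,933.62
65,Naman,lzl,52,42,94,15,415.28
65,Tape,mrs,70,74,144,15,415.28
66,Ngadha,nxg,77,26,103,60000,162.76
66,Soa,ssq,73,36,109,10000,162.76
67,NgaiborSAru,txn,100,19,119,7910,1319.07
67,UjirNAru,udj,89,8,97,1030,1319.07
68,Nguna,llp,57,24,81,9500,2179.01
68,SouthEfate,erk,62,39,101,6000,2179.01
69,Niue,niu,12,52,64,2030,0.0
69,UveaEast,wls,7,25,32,9620,0.0
70,PeteraraMaewo,mwo,45,44,89,1400,1667.29
70,Raga,lml,47,38,85,6500,1667.29
71,Rurutuan,aut,38,19,57,3000,31.67
71,TahitianModern,tah,27,33,60,68260,31.67
72,Saliba,sbe,82,29,111,2500,0.0
72,Suau,swp,48,24,72,6800,0.0
73,SangilSaraganiIslands,snl,42,41,83,15000,497.32
73,SangirTabukang_D,sxn,20,19,39,255000,497.32
74,Seimat,ssg,98,39,137,1000,2128.97
74,Wuvulu,wuv,100,35,135,1000,2128.97
75,Serili,sve,27,14,41,330,480.25
75,SouthEastBabar,vbb,21,10,31,4460,480.25
76,SubanonSiocon,suc,47,17,64,125000,415.21
76,SubanunSindangan,syb,50,23,73,140000,415.21
77,SyeErromangan,erg,53,15,68,1900,1828.8
77,Ura,uur,61,28,89,6,1828.8
78,Taiof,sps,88,39,127,1400,26.49
78,Teop,tio,129,40,169,5000,26.49
79,Tigak,tgc,63,39,102,6000,558.85
79,TungagTungakLavongai,lcm,123,22,145,12000,558.85
80,Tokelau,tkl,12,45,57,1410,1428.51
80,Tuvalu,tvl,4,21,25,10700,1428.51
81,VaghuaChoiseul,tva,63,35,98,1960,0.01
81,Varisi,vrs,40,20,60,5160,0.01
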
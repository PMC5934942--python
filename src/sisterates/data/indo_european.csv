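pair_id,taxon,iso,gain,loss,total,population,branch_length
1,Persian_List,pes,16,36,52,45000000,788.52
1,Tadzik,tgk,39,26,65,6380000,788.52
2,Romanian_List,ron,41,19,60,19900000,727.95
2,Vlach,rup,31,44,75,50000,727.95
3,Sardinian_C,sro,12,22,34,500000,615.19
3,Sardinian_N,src,20,29,49,500000,615.19
4,Ladin,lld,13,18,31,31000,649.3
4,Romansh,roh,20,33,53,40000,649.3
5,French,fra,2,11,13,60000000,522.68
5,Walloon,wln,20,26,46,600000,522.68
6,Portuguese_ST,por,36,24,60,10000000,337.65
6,Spanish,spa,19,36,55,38400000,337.65
7,Irish_A,gle,40,25,65,138000,563.1
7,Scots_Gaelic,gla,47,25,72,58700,563.1
8,Dutch_List,nld,7,17,24,15700000,208.55
8,Flemish,vls,5,22,27,1070000,208.55
9,German_ST,deu,7,14,21,69800000,641.05
9,Luxembourgish,ltz,17,30,47,266000,641.05
10,Faroese,fao,9,14,23,66000,777.56
10,Icelandic_ST,isl,7,27,34,230000,777.56
11,Bulgarian,bul,19,44,63,7020000,712.58
11,Macedonian,mkd,32,14,46,1340000,712.58
12,Lusatian_L,dsb,4,8,12,6670,54.8
12,Lusatian_U,hsb,1,5,6,13300,54.8
13,Byelorussian,bel,15,45,60,2220000,535.34
13,Ukrainian,ukr,42,26,68,32000000,535.34
14,Latvian,lav,68,46,114,1470000,1359.36
14,Lithuanian_ST,lit,61,40,101,2800000,1359.36
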
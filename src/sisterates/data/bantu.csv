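pair_id,taxon,iso,gain,loss,total,population,branch_length
1,A15C_Akossi,bss,1,7,8,100000,479.35
1,A15C_Mkaa,bqz,3,9,12,30000,479.35
2,A24_Duala,dua,0,11,11,87700,684.16
2,A27_Malimba,mzd,5,16,21,2230,684.16
3,A32C_Batanga,bnm,0,9,9,9000,572.43
3,A34_Benga,bng,2,11,13,3900,572.43
4,A41_Barombi-Kang,bbi,3,11,14,3000,526.0
4,A42_Abo,abb,0,8,8,12000,526.0
5,A44_Tunen,tvu,8,23,31,35300,1226.99
5,A46_Nomaande,lem,12,27,39,6000,1226.99
6,A62B_Mmala,mmu,0,1,1,8000,317.48
6,A62C_Libie,ekm,4,5,9,6400,317.48
7,A841_Badwe,ozm,1,3,4,40000,149.27
7,A84_Njem,njy,0,2,2,4400,149.27
8,A91_Kwakum,kwu,12,25,37,10000,1193.38
8,A93_Kako,kkj,8,21,29,100000,1193.38
9,B201_Ndasa,nda,0,2,2,4530,182.77
9,B24_Wumbvu,wum,2,4,6,18300,182.77
10,B252_Mahongwe,mhb,1,10,11,8000,433.1
10,B25_Kota,koq,2,11,13,25000,433.1
11,B301_Viya,gev,4,23,27,50,1263.89
11,B305_Vove,buw,1,20,21,4000,1263.89
12,B304_Pinzi,pic,1,7,8,1000,251.89
12,B32_Kande,kbs,2,8,10,500,251.89
13,B52_Nzebi,nzb,1,7,8,120000,350.62
13,B53_Tsaangi_Poungi,tsa,2,8,10,13600,350.62
14,Bamun_Grassfields,bax,7,7,14,420000,536.22
14,Mungaka_Grassfields,mhk,6,6,12,50100,536.22
15,C142_Mondongo,bui,1,8,9,4000,313.36
15,C412_Libobi,bmg,2,9,11,20000,313.36
16,C37_Ebudza,bja,8,16,24,226000,1116.06
16,C42_Ebwela,bwl,12,20,32,8400,1116.06
17,C71_Tetela,tll,6,19,25,750000,930.34
17,C76_Ombo,oml,4,17,21,8400,930.34
18,C83_Bushong,buf,0,10,10,155000,751.44
18,C85_Wongo,won,2,12,14,12700,751.44
19,D201_Liko,lik,10,31,41,60000,1176.87
19,D21_Baali,bcp,11,32,43,42000,1176.87
20,D305_Nyanga-li,nyc,4,4,8,48000,583.87
20,D43_Nyanga,nyj,4,4,8,150000,583.87
21,D333_Ndaaka,ndk,3,8,11,25000,467.68
21,D334_Mbo,zmw,5,10,15,11000,467.68
22,E72a_Giryama,nyf,2,14,16,944000,600.19
22,E73_Digo,dig,5,17,22,313000,600.19
23,E74a_Dawida,dav,8,23,31,274000,1081.89
23,G39_Saghala,tga,10,25,35,79000,1081.89
24,F12_Bende,bdp,10,29,39,27000,1126.01
24,F23_Sumbwa,suw,1,20,21,191000,1126.01
25,F24_Kimbu,kiv,4,18,22,78000,762.1
25,F31_Nyiramba,nim,7,21,28,455000,762.1
26,G11_Gogo,gog,2,26,28,1440000,813.11
26,G12_Kagulu,kki,1,25,26,241000,813.11
27,G23_Sambaa,ksb,3,14,17,664000,363.63
27,G24_Bondei,bou,2,13,15,50000,363.63
28,G35_Luguru,ruf,6,21,27,692000,469.0
28,G36_Kami,kcu,1,16,17,16400,469.0
29,G44D_Maore,swb,4,6,10,92800,262.27
29,G44b_Ndzwani,wni,1,3,4,264000,262.27
30,G61_Sangu,sbp,1,20,21,75000,611.71
30,G66_Wanji,wbi,6,25,31,28000,611.71
31,G62_Hehe,heh,3,13,16,805000,491.97
31,G63_Bena,bez,6,16,22,670000,491.97
32,H16a_Kisikongo_2013,kwy,1,12,13,537000,695.08
32,H16a_Kisolongo_DRC_2012,kng,2,13,15,3000000,695.08
33,JD64_Shubi,suj,0,5,5,153000,288.52
33,JD65_Hangaza,han,2,7,9,150000,288.52
34,JD66_Kiha,haq,3,11,14,990000,483.82
34,JD67_Kivinza,vin,2,10,12,10000,483.82
35,JE11_Runyoro,nyo,3,10,13,667000,358.91
35,JE12_Rutooro,ttj,5,12,17,488000,358.91
36,JE13_Runyankore,nyn,0,6,6,2330000,342.41
36,JE14_Rukiga,cgg,3,9,12,1580000,342.41
37,JE21_Runyambo,now,1,9,10,400000,404.52
37,JE22_Haya,hay,1,9,10,1300000,404.52
38,JE25_Jita,jit,5,10,15,205000,494.21
38,JE25_Kilegi,reg,3,8,11,86000,494.21
39,JE31_Lumasaaba,myx,6,9,15,1120000,544.3
39,JE31c_Bukusu,bxk,9,12,21,1433000,544.3
40,K332_Rumanyo,diu,2,11,13,10200,783.09
40,K33_Kwangali,kwn,3,12,15,73100,783.09
41,Kom_Grassfields,bkm,1,2,3,233000,407.67
41,Oku_Grassfields,oku,5,6,11,87000,407.67
42,L31a_Luba-Kasai,lua,2,12,14,6300000,1144.85
42,L32_Kanyok,kny,6,16,22,200000,1144.85
43,L35_Sanga,sng,1,8,9,431000,570.02
43,L41_Kaonde,kqn,0,7,7,206000,570.02
44,M11_Pimbwe,piw,1,7,8,29000,429.35
44,M12_Lungwa,rnw,1,7,8,18000,429.35
45,M21_Ndali,ndh,7,23,30,150000,734.25
45,M31_Nyakyusa,nyy,7,23,30,805000,734.25
46,M21_Wanda,wbh,1,4,5,24000,203.84
46,M22_Namwanga,mwn,0,3,3,140000,203.84
47,M24_Malila,mgq,2,19,21,65000,414.18
47,M25_Safwa,sbk,4,21,25,158000,414.18
48,M52_Lala,leb,1,4,5,353000,293.42
48,M54_Lamba,lam,1,4,5,201000,293.42
49,M61_Lenje,leh,2,7,9,128000,643.12
49,M62_Soli,sby,9,14,23,34100,643.12
50,Moghamo_Grassfields,mgo,9,9,18,183000,715.68
50,Njen_Grassfields,njj,6,6,12,1800,715.68
51,N11_Manda,mgs,1,18,19,22000,671.25
51,N12_Ngoni,ngo,3,20,23,170000,671.25
52,N13_Matengo,mgv,5,16,21,150000,545.66
52,N14_Mpoto,mpa,0,11,11,80000,545.66
53,N31_Chewa,nya,6,18,24,7000000,755.02
53,N42_Kunda,kdn,1,13,14,145000,755.02
54,P21_Yao,yao,10,16,26,2200000,598.01
54,P22_Mwera,mwe,5,11,16,469000,598.01
55,P31G_Ikorovere,mgh,6,6,12,963000,390.78
55,P31_Emakhua,vmw,2,2,4,3090000,390.78
56,S11_Shona,sna,4,13,17,10700000,858.44
56,S16_Kalanga,kck,6,15,21,700000,858.44
57,S311_Shekgalagari,xkv,8,14,22,40000,557.18
57,S31_Tswana,tsn,5,11,16,1070000,557.18
58,S51_Tshwa,tsc,2,6,8,1160000,276.76
58,S53_Tsonga,tso,1,5,6,2280000,276.76
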
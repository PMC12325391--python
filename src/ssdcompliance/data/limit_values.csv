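set_id,strategy,jurisdiction,selector_kind,ph_low,ph_low_closed,ph_high,ph_high_closed,texture_scheme,texture_category,As,Cd,Cr,Cu,Hg,Ni,Pb,Zn,substituted_flags
EU_LL,EU_LL,EU,none,,,,,,,25.5,1.0,100,50,1.0,30,50,150,As;Cr
EU_UL,EU_UL,EU,none,,,,,,,25.5,3.0,100,140,1.5,75,300,300,As;Cr
EU_PH_acid,EU_PH,EU,ph_band,0,0,6,1,,,,1.0,,50,1.0,30,50,150,
EU_PH_neutral,EU_PH,EU,ph_band,6,0,7,1,,,,3.0,,140,1.5,75,300,300,
EU_PH_alkaline,EU_PH,EU,ph_band,7,0,14,1,,,,4.5,,210,2.25,112,450,450,
AT,NATIONAL,AT,none,,,,,,,25.5,1.4,91,81,0.9,55,90,231,As;Cd;Cr;Cu;Hg;Ni;Pb;Zn
AT-lower_austria,NATIONAL,AT-lower_austria,none,,,,,,,25.5,1.5,100,60,1.0,50,100,200,As
AT-upper_austria,NATIONAL,AT-upper_austria,none,,,,,,,25.5,1.0,100,100,1.0,60,100,300,As
AT-burgenland,NATIONAL,AT-burgenland,none,,,,,,,25.5,2.0,100,100,1.5,60,100,300,As
AT-vorarlberg,NATIONAL,AT-vorarlberg,none,,,,,,,25.5,2.0,100,100,1.0,60,100,300,As
AT-steiermark,NATIONAL,AT-steiermark,none,,,,,,,20.0,2.0,100,100,1.0,60,100,300,
AT-carinthia_acid,NATIONAL,AT-carinthia,ph_band,0,0,5.5,1,,,25.5,0.5,50,40,0.2,30,50,100,As
AT-carinthia_mid,NATIONAL,AT-carinthia,ph_band,5.5,0,6.5,1,,,25.5,1.0,75,50,0.5,50,70,150,As
AT-carinthia_alk,NATIONAL,AT-carinthia,ph_band,6.5,0,14,1,,,25.5,1.5,100,100,1.0,70,100,200,As
BE-flanders,NATIONAL,BE-flanders,none,,,,,,,22.0,0.9,46,49,1.3,18,56,162,
BE-walloon,NATIONAL,BE-walloon,none,,,,,,,22.0,2.0,100,50,1.0,50,100,200,
BG_acid,NATIONAL,BG,ph_band,0,0,7.4,1,,,25.0,2.0,200,100,1.0,60,80,250,
BG_alk,NATIONAL,BG,ph_band,7.4,0,14,1,,,25.0,3.0,200,140,1.0,75,100,300,
CY,NATIONAL,CY,none,,,,,,,25.5,3.0,100,140,1.5,75,300,300,As;Cr
CZ_common,NATIONAL,CZ,texture_category,,,,,czech,common_soils,20.0,5.0,90,60,0.3,50,60,120,
CZ_sands,NATIONAL,CZ,texture_category,,,,,czech,sands_claysands_gravelsands,15.0,4.0,55,45,0.3,45,55,105,
DK,NATIONAL,DK,none,,,,,,,25.5,0.5,30,40,0.5,15,40,100,As
FI,NATIONAL,FI,none,,,,,,,25.5,0.5,200,100,0.2,60,60,150,As
FR,NATIONAL,FR,none,,,,,,,25.5,2.0,150,100,1.0,50,100,300,As
DE_clay,NATIONAL,DE,texture_category,,,,,germany,clay,25.5,1.5,100,60,1.0,70,100,200,As
DE_loam_silt,NATIONAL,DE,texture_category,,,,,germany,loam_silt,25.5,1.0,60,40,0.5,50,70,130,As;Zn
DE_sand,NATIONAL,DE,texture_category,,,,,germany,sand,25.5,0.4,30,20,0.1,15,40,60,As
EL,NATIONAL,EL,none,,,,,,,25.5,3.0,100,140,1.5,75,300,300,As;Cr
IE,NATIONAL,IE,none,,,,,,,25.5,1.0,100,50,1.0,30,50,150,As;Cr
IT,NATIONAL,IT,none,,,,,,,25.5,1.5,100,100,1.0,75,100,300,As;Cr
LU,NATIONAL,LU,none,,,,,,,25.5,3.0,200,140,1.5,75,300,300,As
EE,NATIONAL,EE,none,,,,,,,25.5,3.0,100,50,1.5,50,100,300,As
HU,NATIONAL,HU,none,,,,,,,25.5,1.0,75,75,0.5,40,100,200,As
LV,NATIONAL,LV,none,,,,,,,25.5,0.9,90,70,0.5,70,40,100,As
LT,NATIONAL,LT,none,,,,,,,25.5,1.5,80,80,1.0,60,80,260,As
MT_acid,NATIONAL,MT,ph_band,0,0,6,1,,,25.5,0.5,30,20,0.1,15,70,60,As
MT_neutral,NATIONAL,MT,ph_band,6,0,7,1,,,25.5,1.0,60,50,0.5,50,70,150,As
MT_alk,NATIONAL,MT,ph_band,7,0,14,1,,,25.5,1.5,100,100,1.0,70,100,200,As
NL,NATIONAL,NL,none,,,,,,,20.0,0.6,55,40,0.3,35,50,140,
PT_acid,NATIONAL,PT,ph_band,0,0,5.5,1,,,25.5,1.0,50,50,1.0,30,50,150,As
PT_neutral,NATIONAL,PT,ph_band,5.5,0,7,1,,,25.5,3.0,200,100,1.5,75,300,300,As
PT_alk,NATIONAL,PT,ph_band,7,0,14,1,,,25.5,4.0,300,200,2.0,110,450,450,As
PL_light,NATIONAL,PL,texture_category,,,,,poland,light,25.5,1.0,50,25,0.8,20,40,80,As
PL_medium,NATIONAL,PL,texture_category,,,,,poland,medium,25.5,2.0,75,50,1.2,35,60,120,As
PL_heavy,NATIONAL,PL,texture_category,,,,,poland,heavy,25.5,3.0,100,75,1.5,50,80,180,As
RO,NATIONAL,RO,none,,,,,,,25.5,3.0,100,100,1.0,50,50,300,As
SK,NATIONAL,SK,none,,,,,,,25.0,1.0,60,50,0.5,50,70,150,
SI_acid,NATIONAL,SI,ph_band,0,0,6,1,,,25.5,1.0,100,60,0.8,50,85,200,As
SI_alk,NATIONAL,SI,ph_band,6,0,14,1,,,25.5,1.0,30,20,0.8,15,70,60,As
ES_acid,NATIONAL,ES,ph_band,0,0,7,1,,,25.5,1.0,100,50,1.0,30,50,150,As
ES_alk,NATIONAL,ES,ph_band,7,0,14,1,,,25.5,3.0,150,210,1.5,112,300,450,As
SE,NATIONAL,SE,none,,,,,,,25.5,0.4,60,40,0.3,30,40,100,As
UK,NATIONAL,UK,none,,,,,,,50.0,3.0,400,200,1.0,110,300,450,
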
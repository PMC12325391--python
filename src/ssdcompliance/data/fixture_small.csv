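sample_id,country,nuts2,region_code,land_cover,ph_h2o,clay_pct,silt_pct,sand_pct,As,Cd,Cr,Cu,Hg,Ni,Pb,Zn
F01,IE,IE01,,cropland,5.5,20,40,40,5,0.5,40,10,0.1,10,10,50
F02,IE,IE02,,grassland,6.5,25,35,40,5,0.2,40,10,0.1,45,10,50
F03,CY,CY00,,cropland,7.5,30,30,40,5,0.3,40,20,,20,15,80
F04,DE,DE11,,cropland,6.0,5,5,90,5,0.2,20,10,0.05,8,20,40
F05,DE,DE21,,cropland,6.8,60,20,20,5,0.3,40,20,0.2,25,30,80
F06,DE,DE13,,grassland,6.2,20,40,40,5,0.2,30,15,0.1,20,25,60
F07,PL,PL11,,cropland,5.2,8,12,80,4,0.3,20,10,0.1,8,15,40
F08,PL,PL21,,cropland,6.1,20,40,40,5,0.5,30,20,0.2,15,25,60
F09,PL,PL32,,grassland,7.1,45,35,20,6,0.8,40,30,0.3,25,35,90
F10,CZ,CZ01,,cropland,6.4,8,12,80,4,0.9,20,10,0.05,10,15,40
F11,CZ,CZ02,,cropland,5.0,20,40,40,3,0.9,10,5,0.05,5,5,20
F12,AT,AT22,AT-steiermark,cropland,6.5,25,30,45,10,0.5,30,20,0.1,15,20,60
F13,AT,AT34,,grassland,6.0,20,40,40,5,0.4,30,20,0.1,15,20,60
F14,FR,FR10,,cropland,6.5,25,35,40,5,2.0,30,20,0.1,10,20,60
F15,DK,DK01,,cropland,6.5,20,40,40,4,0.1,10,10,0.05,12,10,30
F16,ES,ES30,,cropland,7.5,20,40,40,5,<0.07,30,20,0.1,20,15,70
F17,UK,UKC1,,grassland,6.0,20,40,40,25,0.5,40,20,0.1,20,30,80
F18,SE,SE11,,other,6.0,20,40,40,4,0.2,20,10,0.05,10,10,40
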
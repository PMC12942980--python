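id,name,belt,bt_low,bt_high,p_low,p_high
1,polar desert,polar,0,1.5,0,inf
2,subpolar dry tundra,subpolar,1.5,3,0,125
3,subpolar moist tundra,subpolar,1.5,3,125,250
4,subpolar wet tundra,subpolar,1.5,3,250,500
5,subpolar rain tundra,subpolar,1.5,3,500,inf
6,boreal desert,boreal,3,6,0,125
7,boreal dry scrub,boreal,3,6,125,250
8,boreal moist forest,boreal,3,6,250,500
9,boreal wet forest,boreal,3,6,500,1000
10,boreal rain forest,boreal,3,6,1000,inf
11,cool temperate desert,cool temperate,6,12,0,125
12,cool temperate desert scrub,cool temperate,6,12,125,250
13,cool temperate steppe,cool temperate,6,12,250,500
14,cool temperate moist forest,cool temperate,6,12,500,1000
15,cool temperate wet forest,cool temperate,6,12,1000,2000
16,cool temperate rain forest,cool temperate,6,12,2000,inf
17,warm temperate desert,warm temperate,12,16.970562748477143,0,125
18,warm temperate desert scrub,warm temperate,12,16.970562748477143,125,250
19,warm temperate thorn steppe,warm temperate,12,16.970562748477143,250,500
20,warm temperate dry forest,warm temperate,12,16.970562748477143,500,1000
21,warm temperate moist forest,warm temperate,12,16.970562748477143,1000,2000
22,warm temperate wet forest,warm temperate,12,16.970562748477143,2000,4000
23,warm temperate rain forest,warm temperate,12,16.970562748477143,4000,inf
24,subtropical desert,subtropical,16.970562748477143,24,0,125
25,subtropical desert scrub,subtropical,16.970562748477143,24,125,250
26,subtropical thorn woodland,subtropical,16.970562748477143,24,250,500
27,subtropical dry forest,subtropical,16.970562748477143,24,500,1000
28,subtropical moist forest,subtropical,16.970562748477143,24,1000,2000
29,subtropical wet forest,subtropical,16.970562748477143,24,2000,4000
30,subtropical rain forest,subtropical,16.970562748477143,24,4000,inf
31,tropical desert,tropical,24,inf,0,125
32,tropical desert scrub,tropical,24,inf,125,250
33,tropical thorn woodland,tropical,24,inf,250,500
34,tropical very dry forest,tropical,24,inf,500,1000
35,tropical dry forest,tropical,24,inf,1000,2000
36,tropical moist forest,tropical,24,inf,2000,4000
37,tropical wet forest,tropical,24,inf,4000,8000
38,tropical rain forest,tropical,24,inf,8000,inf
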
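id,seismic_intensity,max_inundation_m,d_station_m,d_shelter_m,arrival_min
3,6+,0.0-0.3,599,"1,892",n/a
8,6+,0.3-1.0,811,"2,125",n/a
14,7,0.3-1.0,951,"2,096",n/a
22,6+,0.3-1.0,"2,694","4,543",60
27,7,0.3-1.0,"1,324","1,418",60
48,6+,0.3-1.0,"1,748","1,336",60
11,7,1.0-2.0,"1,821","2,110",60
18,6+,1.0-2.0,795,265,50
19,7,2.0-3.0,"2,034","2,035",50
21,7,1.0-2.0,"1,844","3,324",35
29,6+,2.0-3.0,840,"1,682",n/a
30,7,1.0-2.0,"1,245","2,724",35
32,7,2.0-3.0,637,655,50
39,6+,1.0-2.0,975,866,60
46,6+,2.0-3.0,781,"1,830",60
47,6-,2.0-3.0,"1,118",483,60
51,6+,1.0-2.0,"1,146","3,909",35
5,6+,3.0-5.0,745,912,50
34,6-,3.0-5.0,56,522,50
49,6+,3.0-5.0,584,"1,074",50
50,6+,3.0-5.0,"2,081",332,35
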
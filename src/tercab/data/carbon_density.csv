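class,name,Ca,Cb,Cs,Cd
1,cropland,5.72,1.18,96.61,2.10
2,forest,19.76,5.31,25.43,2.80
3,shrubland,4.39,3.67,101.33,0.70
4,grassland,4.20,5.84,87.76,1.30
5,water,0,0,0,0
6,barren,0,0,0.86,0
7,impervious,2.60,0.75,34.40,0
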
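class,cropland,forest,shrubland,grassland,water,barren,impervious
cropland,7075.54,2434.87,0.08,4.03,56.04,0.43,260.43
forest,3312.95,19636.95,0.44,0.80,10.70,0.05,67.22
shrubland,0.15,8.01,1.15,0.00,0.00,0.00,0.00
grassland,55.44,4.58,0.02,3.82,8.35,0.42,15.43
water,93.25,26.13,0.02,0.46,393.73,0.11,17.06
barren,21.86,1.69,0.00,1.18,1.10,1.77,2.98
impervious,6.31,0.25,0.00,0.06,11.89,0.02,343.51
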
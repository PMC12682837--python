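parameter,organ,P0_mean,P0_sd,P1_mean,P1_sd,P2_mean,P2_sd,P3_mean,P3_sd
a,stem,0.187,0.01,0.16,0.02,0.166,0.014,0.13,0
l_n,stem,1.487,0.313,0.153,0.175,1.676,0.214,1.636,0.126
r,stem,0.759,0.876,0.915,1.034,1,0.772,1.129,0.66
r,leaf,7.921,2.338,7.914,2.041,8.8,2.976,10.907,3.005
l_max,leaf,38.411,7.88,42.606,14.001,52.237,17.901,49.124,15.521
theta,leaf,0.705,0.306,0.773,0.055,0.794,0.403,0.739,0.262
delay_lat,leaf,3,,3,,3,,3,
RotBeta,leaf,1,,1,,1,,1,
Width_Blade,leaf,1.638,,1.681,,1.561,,1.563,
Area_max,leaf,54.454,,66.695,,80.683,,71.956,
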
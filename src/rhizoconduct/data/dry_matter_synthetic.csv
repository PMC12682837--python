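# Synthetic stand-in whole-plant dry matter at 28 DAS per treatment (g).
# Used only to form the soil-P-to-biomass ratio PB = P / DM_plant for the
# crown-root elongation response when the user supplies no measured values.
treatment,P_mg_per_hg,dm_plant_g
P0,1.8,0.8
P1,3.3,1.5
P2,4.6,2.0
P3,7.7,2.6
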
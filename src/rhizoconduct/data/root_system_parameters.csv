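parameter,P0,P1,P2,P3
first_B,3.6,3.6,3.0,4.0
delay_B,1.0,1.0,1.0,1.0
max_B,3.5,3.5,3.5,3.5
first_SB,8.6,9.4,9.2,8.2
delay_SB,1.0,1.0,1.0,1.0
delay_RC,7.4,6.6,6.3,6.2
n_C,3.0,3.6,3.4,3.0
seedPos_x,0.0,0.0,0.0,0.0
seedPos_y,0.0,0.0,0.0,0.0
seedPos_z,-3.0,-3.0,-3.0,-3.0
simulationTime,28,28,28,28
p_l_lateral,0.04,0.05,0.05,0.05
p_s_lateral,0.96,0.95,0.95,0.95
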
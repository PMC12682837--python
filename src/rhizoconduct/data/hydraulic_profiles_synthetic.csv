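# Synthetic stand-in hydraulic conductivity profiles (NOT measured data).
# Age-dependent radial conductivity k_r (d^-1, head units) and axial
# conductance K_x (cm^3 d^-1) per root type, piecewise linear between knots,
# constant beyond the last knot.  Shapes follow the classic maize
# hydraulics literature: k_r decreases with segment age (suberization),
# K_x increases (xylem maturation); crown roots carry higher proximal
# axial conductance than the other axial types.  Magnitudes are jointly
# scaled once so that a simulated 28-d high-P plant's whole-system
# conductance K_rs falls within the published young-maize range
# [7.00e-5, 2.37e-2] cm^2 d^-1.
type,age_d,kr_per_d,kx_cm3_per_d
primary,0.0,6.0e-5,0.009
primary,8.0,6.0e-5,0.020
primary,14.0,2.2e-5,0.040
primary,28.0,5.7e-6,0.117
seminal,0.0,6.0e-5,0.009
seminal,8.0,6.0e-5,0.020
seminal,14.0,2.2e-5,0.040
seminal,28.0,5.7e-6,0.117
crown,0.0,6.0e-5,0.017
crown,8.0,6.0e-5,0.040
crown,14.0,2.2e-5,0.117
crown,28.0,5.7e-6,0.233
l-lateral,0.0,6.0e-4,3.3e-5
l-lateral,7.0,2.3e-4,2.0e-4
l-lateral,14.0,5.7e-5,4.0e-4
l-lateral,28.0,5.7e-5,5.7e-4
s-lateral,0.0,6.0e-4,3.3e-5
s-lateral,7.0,2.3e-4,2.0e-4
s-lateral,14.0,5.7e-5,4.0e-4
s-lateral,28.0,5.7e-5,5.7e-4
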
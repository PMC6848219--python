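# Mucus viscosity across mucin concentrations, in mPa s, extracted from the
# T4 dhoc diffusion constants by Stokes-Einstein inversion (R_P = 90 nm,
# kT = 4.28 pN nm at 37 C). Upper/lower bounds follow from the diffusion
# coefficient standard deviations.
mucin_pct,eta_mean,eta_upper,eta_lower
0,0.69,0.77,0.62
0.2,0.80,0.90,0.70
0.6,0.96,1.04,0.87
1,0.99,1.09,0.89
2,1.83,2.01,1.66
4,3.39,3.73,3.06
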
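# Anomalous diffusion parameters of phage T4 in mucin solutions, from
# high-speed multiple-particle tracking (Barr et al. 2015, PNAS 112:13675).
# T4 wild type adheres to mucin (subdiffusive): diff_coeff is the generalized
# diffusion constant D_alpha in um^2/s^alpha. T4 dhoc lacks the Hoc Ig-like
# domain (regular diffusion): diff_coeff is the standard diffusion constant D
# in um^2/s. mucin_pct is percent weight/volume. *_sd are standard deviations.
mucin_pct,phage_type,alpha,alpha_sd,diff_coeff,diff_coeff_sd
0,wt,1.02,0.02,3.84,0.17
0,dhoc,0.99,0.03,3.64,0.24
0.2,wt,0.93,0.02,2.38,0.17
0.2,dhoc,0.99,0.04,3.14,0.27
0.6,wt,0.82,0.02,1.18,0.12
0.6,dhoc,1.01,0.02,2.63,0.11
1,wt,0.82,0.01,1.03,0.07
1,dhoc,1.02,0.02,2.54,0.14
2,wt,0.91,0.02,0.90,0.07
2,dhoc,0.99,0.02,1.37,0.07
4,wt,0.86,0.02,0.42,0.04
4,dhoc,0.89,0.02,0.74,0.04
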
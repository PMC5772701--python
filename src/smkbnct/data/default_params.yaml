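# Reference SMK parameters (SCC VII murine squamous-cell carcinoma) and
# KUR-like irradiation defaults.
schema_version: 1
smk_params:
  alpha0_per_Gy: 0.0422
  alpha0_err: 0.0234
  beta0_per_Gy2: 0.00822
  beta0_err: 0.00312
  gamma0_per_h: 4.33
  gamma0_err: 3.74
  r_d_um: 0.24
photon_reference:
  alpha_gamma_per_Gy: 0.0634
  dose_rate_Gy_min: 2.0
irradiation:
  neutron_dose_rate_Gy_h: 0.90
  photon_dose_rate_Gy_h: 0.66
  boron_concentration_ug_g: [17, 23, 26]
compounds:
  BPA:
    intra_extra_ratio: 3.2
  BSH:
    intra_extra_ratio: 0.86
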
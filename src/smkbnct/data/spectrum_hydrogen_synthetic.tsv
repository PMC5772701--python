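# note=synthetic recoil-proton spectrum (epithermal-beam-like stand-in)
species	energy_MeV	weight
proton	1.000000e-02	1.074105e-01
proton	1.157486e-02	9.676773e-02
proton	1.339775e-02	8.715250e-02
proton	1.550771e-02	7.846451e-02
proton	1.794997e-02	7.061326e-02
proton	2.077685e-02	6.351708e-02
proton	2.404892e-02	5.710223e-02
proton	2.783630e-02	5.130218e-02
proton	3.222014e-02	4.605692e-02
proton	3.729438e-02	4.131227e-02
proton	4.316774e-02	3.701941e-02
proton	4.996607e-02	3.313429e-02
proton	5.783506e-02	2.961725e-02
proton	6.694330e-02	2.643255e-02
proton	7.748596e-02	2.354803e-02
proton	8.968895e-02	2.093480e-02
proton	1.038137e-01	1.856692e-02
proton	1.201630e-01	1.642113e-02
proton	1.390871e-01	1.447667e-02
proton	1.609914e-01	1.271500e-02
proton	1.863454e-01	1.111966e-02
proton	2.156922e-01	9.676064e-03
proton	2.496609e-01	8.371381e-03
proton	2.889791e-01	7.194347e-03
proton	3.344894e-01	6.135135e-03
proton	3.871669e-01	5.185206e-03
proton	4.481405e-01	4.337148e-03
proton	5.187165e-01	3.584508e-03
proton	6.004074e-01	2.921602e-03
proton	6.949634e-01	2.343303e-03
proton	8.044108e-01	1.844811e-03
proton	9.310946e-01	1.421406e-03
proton	1.077729e+00	1.068202e-03
proton	1.247457e+00	7.799246e-04
proton	1.443915e+00	5.507327e-04
proton	1.671312e+00	3.741391e-04
proton	1.934521e+00	2.430436e-04
proton	2.239182e+00	1.499106e-04
proton	2.591823e+00	8.708305e-05
proton	3.000000e+00	4.719393e-05
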
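# note=synthetic secondary-electron spectrum (Compton-like stand-in)
species	energy_MeV	weight
electron	3.000000e-03	6.618128e-02
electron	3.518241e-03	6.299859e-02
electron	4.126007e-03	5.995362e-02
electron	4.838763e-03	5.703870e-02
electron	5.674645e-03	5.424643e-02
electron	6.654923e-03	5.156957e-02
electron	7.804542e-03	4.900108e-02
electron	9.152754e-03	4.653411e-02
electron	1.073386e-02	4.416195e-02
electron	1.258811e-02	4.187802e-02
electron	1.476267e-02	3.967587e-02
electron	1.731288e-02	3.754921e-02
electron	2.030362e-02	3.549183e-02
electron	2.381102e-02	3.349770e-02
electron	2.792430e-02	3.156093e-02
electron	3.274814e-02	2.967583e-02
electron	3.840529e-02	2.783697e-02
electron	4.503969e-02	2.603924e-02
electron	5.282016e-02	2.427799e-02
electron	6.194469e-02	2.254911e-02
electron	7.264545e-02	2.084923e-02
electron	8.519474e-02	1.917596e-02
electron	9.991189e-02	1.752807e-02
electron	1.171714e-01	1.590584e-02
electron	1.374124e-01	1.431131e-02
electron	1.611500e-01	1.274863e-02
electron	1.889882e-01	1.122430e-02
electron	2.216353e-01	9.747386e-03
electron	2.599222e-01	8.329500e-03
electron	3.048230e-01	6.984621e-03
electron	3.574802e-01	5.728517e-03
electron	4.192339e-01	4.577775e-03
electron	4.916553e-01	3.548376e-03
electron	5.765873e-01	2.653879e-03
electron	6.761911e-01	1.903388e-03
electron	7.930012e-01	1.299641e-03
electron	9.299898e-01	8.376852e-04
electron	1.090643e+00	5.046318e-04
electron	1.279048e+00	2.808226e-04
electron	1.500000e+00	1.423982e-04
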
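gene	x	y
TG01	0.586770	0.000000
TG02	1.000000	0.401368
TG03	0.240528	0.000000
TG04	0.998325	0.480856
TG05	0.398367	1.000000
TG06	0.503454	0.327418
TG07	0.884446	1.000000
TG08	0.490057	0.117099
TG09	0.622357	0.731271
TG10	0.130626	0.648584
TG11	0.814528	1.000000
TG12	0.611681	0.567736
TG13	0.415323	0.696752
TG14	0.847394	1.000000
TG15	0.390203	0.306285
TG16	0.531924	0.578828
TG17	0.230898	0.417419
TG18	0.484404	1.000000
TG19	0.296420	0.465664
TG20	0.351685	0.789534
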
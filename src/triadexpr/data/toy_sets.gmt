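TOY_SET_A	synthetic toy gene set for examples and tests	g0001	g0002	g0003	g0004	g0005	g0006	g0007	g0008	g0009	g0010	g0011	g0012	g0013	g0014	g0015	g0016	g0017	g0018	g0019	g0020
TOY_SET_B	synthetic toy gene set for examples and tests	g0050	g0051	g0052	g0053	g0054	g0055	g0056	g0057	g0058	g0059
TOY_SET_C	synthetic toy gene set for examples and tests	g0100	g0102	g0104	g0106	g0108	g0110	g0112	g0114	g0116	g0118	g0120	g0122	g0124	g0126	g0128	g0130	g0132	g0134	g0136	g0138
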
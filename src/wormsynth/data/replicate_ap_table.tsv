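method	val	test_1	test_2	test_3
Base dataset	0.938	0.493	0.579	0.508
BD with data augmentation	0.954	0.693	0.725	0.701
BD + ST	0.951	0.735	0.742	0.731
BD + P2P	0.956	0.816	0.810	0.827
BD + ST + P2P	0.935	0.790	0.795	0.770
BD + ST + P2P + SSL	0.951	0.864	0.857	0.854
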
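ethanol	CCO
acetic_acid	CC(=O)O
benzene	c1ccccc1
aspirin	CC(=O)Oc1ccccc1C(=O)O
caffeine	CN1C=NC2=C1C(=O)N(C)C(=O)N2C
glucose	OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O
ibuprofen	CC(C)Cc1ccc(cc1)C(C)C(=O)O
paracetamol	CC(=O)Nc1ccc(O)cc1
nicotine	CN1CCC[C@H]1c1cccnc1
urea	NC(=O)N
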
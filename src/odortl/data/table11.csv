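name,smiles,odt_ppm,benchmark_pred_ppm,transfer_pred_ppm,smiles_corrected
Mesityl Oxide,O=C(C)CC(C)C,0.017,0.00756,0.0804,
Butyraldehyde,CCCCO,0.0003,0.00392,0.0171,
Isobutyl Acetate,C(C)(=O)OCC(C)C,0.008,0.00109,0.157,
alpha-Pinene,CC1CCC2CC1C2(C)C,0.00006,0.00194,0.0238,
2-Methyl Butyl Acetate,CCC(C)COC(=O)C,0.026,0.000511,0.0192,
Vanillin,COC1C(CCC(=C1)CO)O,1.6e-7,0.00102,0.00651,
Camphor,CC1(C2CCC1(C(=O)C2)C)C,0.0026,0.00338,0.0513,
sec-Butyl Acetate,CCC(C)OC(=O)C,0.0025,0.000704,0.187,
n-Amyl Acetate,CCCCCOC(C)O,0.007,9.48e-5,7.31e-5,
Methyl Isobutyl Ketone,C(C(C)C)C(=O)C,0.03,0.00321,0.137,
n-Valeraldehyde,CCCCCO,0.0004,0.00130,0.00645,
1-Hexanol,CCCCCCO,0.0024,0.000369,0.00357,
Naphthalene,C1CCCC2CCCCC12,0.0019,0.00979,0.00292,
Diisobutyl Ketone,C(C(C)C)C(=O)CC(C)C,0.103,0.00491,0.0998,
o-Cresol,CC1CCCCC1O,5e-5,0.00212,0.00228,
2-Methylnaphthalene,CC1CC2CCCCC2CC1,0.00069,0.000806,0.00274,
n-Butyl Alcohol,CCCCO,0.0033,0.00279,0.00352,
1-Pentanol,CCCCCO,0.0055,0.00145,0.00251,
Acetophenone,CC(=O)C1CCCCC1,0.00024,0.000770,0.00197,
tert-Butyl Acetate,CC(=O)OC(C)(C)C,0.008,0.00346,0.0361,
Diethyl Ketone,C(C)C(=O)CC,0.85,0.00850,0.222,
Furfural,C(C1CCCO1)O,0.002,0.00202,0.0258,
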
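# Virtual reaction scheme registry (tab-separated).
# Columns: id	name	mapped-transform (reaction SMARTS)	example-reactants (';'-separated SMILES, slot order)	example-product	literature tag	implicit atoms from fixed reagents (El:count,...)
# Every scheme must reproduce its example at load time; extend the registry by appending records in the same format.
debus_radziszewski	Debus-Radziszewski imidazole synthesis	[#6:1][C:2](=O)[C:3](=O)[#6:4].[#6:5][CH1:6]=[OX1]>>[#6:1]-[c:2]1[nH][c:6](-[#6:5])n[c:3]1-[#6:4]	O=C(c1ccccc1)C(=O)c1ccccc1;O=Cc1ccccc1	c1ccc(-c2nc(-c3ccccc3)c(-c3ccccc3)[nH]2)cc1	benzil + benzaldehyde + NH4OAc -> lophine; ammonia source implicit	N:2
o_acylation	Phenol O-acylation (esterification)	[C:1](=[O:2])[OX2H1].[OX2H1:3][c:4]>>[C:1](=[O:2])[O:3][c:4]	CC(=O)O;Oc1ccccc1	CC(=O)Oc1ccccc1	Steglich esterification of a phenol; acyl-halide route maps to the same bond
amide_coupling	Amide coupling (acid + amine)	[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(NC=O);!$(N[a]):3]>>[C:1](=[O:2])[N:3]	CC(=O)O;NCc1ccccc1	CC(=O)NCc1ccccc1	carbodiimide-mediated amidation
williamson_ether	Williamson ether synthesis (phenol + alkyl halide)	[OX2H1:1][c:2].[CX4;!$(C=[O,S,N]):3][Cl,Br,I]>>[c:2][O:1][C:3]	Oc1ccccc1;CCBr	CCOc1ccccc1	phenol O-alkylation
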
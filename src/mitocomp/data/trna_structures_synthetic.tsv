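gene	planted_class	sequence	structure
trnA	d_armless	GAACGAUACAGGCUGGCUCGCUCUAAGCCAAAGCAGCAAGGAUGGUGCUUCGUUCG	((((((.......(((((.......)))))....((((.......)))))))))).
trnC	t_armless	UGAGUUGCCAGCAAAGCUGGGUGUCAACAGCACACUGCUCUAUGCUAAUUCGG	((((((..(((.....))).((((.......))))...........)))))).
trnD	cloverleaf	AGGAGGUCUGGAUCCCCAAUCCGACAAAAACCAUUUUUGUUGAUGGCUAUCCGAGCCACUUUCUC	(((((((..((((.....)))).(((((.......)))))....(((.......)))))))))).
trnE	t_armless	GUUGUGCUCUCAGCUAGACUGAGGUCCAGUAUAGGGACGAAGGACCAGCGCACAACC	(((((((..((((.....)))).((((.......))))...........))))))).
trnF	cloverleaf	CGAGCUGCAGCGGACCACGCAUGGUACUCCCCACCAUCUGACGUUUACUGAAAACGUCAGUUUGG	(((((((..(((.....))).((((.......))))....(((((.......)))))))))))).
trnG	t_armless	CCCGGAAAUGCGGCUCACGCGAAUGUAUACAGCAUUCCUAACGGUCAUUUCGGGA	(((((((..(((.....))).((((.......))))...........))))))).
trnH	t_armless	GUGGAGACUACACCUUAUGUAAUGUUCGCUCUCAACAAAUUGGCUACACUUCAUG	((((((..((((.....)))).((((.......))))...........)))))).
trnI	t_armless	UAAGGCGCACUCUUGCAGAGUAGCACUGCCUCCGAGUGCUGUAUGCCCAGGCCUUAC	((((((..((((.....)))).(((((.......)))))...........)))))).
trnK	cloverleaf	GGCUUGGCAGCCUAAUAGGCCAUCCGACUUAGGCGGAUCACCAGUACGACACACUCCAAGCCA	(((((((..(((.....))).(((((.......)))))....(((.......)))))))))).
trnL1	cloverleaf	AAGGGUAGCAGUCCAUCUGACGGGUCGUAAUCCCGCAGCUGCUGGGUACAAUUCUUU	((((((..(((.....))).((((.......))))....((.......)))))))).
trnL2	cloverleaf	AACCGCGCUAGGAGAACCUCCUCCCCCUAAUCAGGGGGCGGAGUAUUGCCACUACCGUGGUUC	(((((((..((((.....)))).((((.......))))....(((.......)))))))))).
trnM	cloverleaf	CCCUAAGGAAUCACGGCGAUUUGUGAACGGCGAAUUCACCGAGAAUCCAAUAUAUGGAUUUUGGGGA	((((((..((((.....)))).(((((.......)))))....(((((.......))))))))))).
trnN	d_armless	ACACCCACUAUGAUGACAAGAGUCGUGUCAACCGCUGUCCAGUCUCGACAGGGGUGUG	((((((.......(((((.......)))))....(((((.......))))))))))).
trnP	t_armless	ACGGGUGGUGGUCGCGUACCAAUCUUGAAGUCUAAGAAUAGGUGAAAGGCUCGUA	((((((..((((.....)))).((((.......))))...........)))))).
trnQ	d_armless	UAUGUAUGUCAGAGGUCCUAUUAACGGACUCACGCAUUAGCUGAUAAUGCAUAUAUAC	(((((((.......((((.......))))....(((((.......)))))))))))).
trnR	d_armless	CCUGAAUGGCUAUACUGGAUAGAGCAGUAGAGACUUCGAAAGUUUCGGGA	((((((.......((((.......))))....((.......)))))))).
trnS1	minimal	GAAGGUCGAUCUCGGACUCGAGGAGUCCCUUCUCUGGCAGCUUUCC	((((((.......((((.......))))...........)))))).
trnS2	d_armless	GCUUUUACACUUGGUGCGUCUCAUGCACGCAACUGGCCGCUGUGGCCAGGAAGGCG	((((((.......((((.......))))....(((((.......))))))))))).
trnT	t_armless	UUCUUUAUUUUACAUCGUAAAUAAUACCAGUAAUUAAACGAUCUAUGUAAGGGAA	(((((((..(((.....))).((((.......))))...........))))))).
trnV	d_armless	UACUCAUUCCCACAACGGCUUGCCCCCGUUGCAUUCUCACCAAUAGAAAUGGGUGA	(((((((.......((((.......))))....((((.......))))))))))).
trnW	cloverleaf	UUAUUGCUGGCUAGGAUCUAGCAGAUAUAAAGUAGAUAUCUACGAGGAUAUAGCCCAUCCUGCAGUAAG	(((((((..((((.....)))).(((((.......)))))....(((((.......)))))))))))).
trnY	d_armless	UGAACUACUAGUAAUGUUGAAGGAAAACAUUGGGGCGUGGAAUCUACGCCUAGUUUGA	(((((((.......((((.......))))....(((((.......)))))))))))).
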
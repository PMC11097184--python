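operation	inputs	expected	tag	oracle
count_atom_types	CCO	C:2,O:1	TRIVIAL
count_atom_types	c1ccccc1	C:6	TRIVIAL
count_atom_types	FC(F)(F)F	C:1,F:4	TRIVIAL
count_atom_types	mol2_standin	n_Cl>n_O and n_Cl>n_N	PAPER
count_atom_types	mol1_standin	n_F=1	PAPER
atom_weight	n=1,k=1.0	0.6931471805599453	DERIVED	math.log high-precision evaluation of ln(2)
atom_weight	n=10,k=0.9	0.22925347571405444	DERIVED	math.log high-precision evaluation of ln(9.9)/10
atom_weight	n=1,k=0.8	0.47000362924573563	DERIVED	math.log high-precision evaluation of ln(1.6)
atom_weight	n=2,k=0.8	0.4377343686769499	DERIVED	math.log high-precision evaluation of ln(2.4)/2
expected_masked_counts	tc=C:7,O:2,N:1;M=2;k=0.9	C:1.1105567877808054,O:0.558772656213956,N:0.33067055600523865	DERIVED	normalization of math.log terms ln(7.2),ln(2.7),ln(1.8)
expected_masked_counts	tc=C:6;M<=6	m_C=M	TRIVIAL
expected_masked_counts	tc=C:3,O:3;M=2;k=1.0	m_C=m_O=1	TRIVIAL
inclusion_probabilities_bruteforce	weights=1,1,2;M=1	0.25,0.25,0.5	DERIVED	direct normalization of single-draw weights
inclusion_probabilities_bruteforce	equal weights;N=4;M=2	0.5 each	TRIVIAL
corpus_target	carbon fraction	0.74	PAPER
corpus_target	C+O+N fraction	0.96	PAPER
corpus_target	trace fraction	0.04	PAPER
scaffold_split	group sizes 5,2,2,1; fractions 80/10/10	train={5-group,2-group,1-group}, valid={2-group}, test={}	DERIVED	hand trace of the greedy fill rule
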
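# pKa sets, v1.
# Columns: set<TAB>group(side|nterm|cterm)<TAB>residue('*' = default)<TAB>pKa
# bjellqvist: the ExPASy-style table with residue-specific terminal pKas;
#   this is the default set and the one behind the classical theoretical
#   pI values printed for 2DE work.
# emboss: the EMBOSS iep defaults.
# lehninger: textbook free-amino-acid values, for sensitivity checks.
bjellqvist	side	C	9.0
bjellqvist	side	D	4.05
bjellqvist	side	E	4.45
bjellqvist	side	H	5.98
bjellqvist	side	K	10.0
bjellqvist	side	R	12.0
bjellqvist	side	Y	10.0
bjellqvist	nterm	*	7.5
bjellqvist	nterm	A	7.59
bjellqvist	nterm	E	7.7
bjellqvist	nterm	M	7.0
bjellqvist	nterm	P	8.36
bjellqvist	nterm	S	6.93
bjellqvist	nterm	T	6.82
bjellqvist	nterm	V	7.44
bjellqvist	cterm	*	3.55
bjellqvist	cterm	D	4.55
bjellqvist	cterm	E	4.75
emboss	side	C	8.5
emboss	side	D	3.9
emboss	side	E	4.1
emboss	side	H	6.5
emboss	side	K	10.8
emboss	side	R	12.5
emboss	side	Y	10.1
emboss	nterm	*	8.6
emboss	cterm	*	3.6
lehninger	side	C	8.18
lehninger	side	D	3.65
lehninger	side	E	4.25
lehninger	side	H	6.0
lehninger	side	K	10.53
lehninger	side	R	12.48
lehninger	side	Y	10.07
lehninger	nterm	*	9.69
lehninger	cterm	*	2.34
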
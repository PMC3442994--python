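group	pka	sign
n_terminus	7.50	+1
c_terminus	3.55	-1
D	4.05	-1
E	4.45	-1
C	9.00	-1
Y	10.00	-1
H	5.98	+1
K	10.00	+1
R	12.00	+1
tag_amine	7.60	+1
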
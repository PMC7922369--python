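# EMBOSS-style pK set used for net-charge / isoelectric-point calculation.
# "Nterm"/"Cterm" are the free termini; the remaining rows are ionizable
# side chains. sign +1 = positively charged when protonated (base),
# sign -1 = negatively charged when deprotonated (acid).
group	pk	sign
Nterm	8.6	1
Cterm	3.6	-1
C	8.5	-1
D	3.9	-1
E	4.1	-1
H	6.5	1
K	10.8	1
R	12.5	1
Y	10.1	-1
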
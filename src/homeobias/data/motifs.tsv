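# Promoter cis-element consensus patterns (IUPAC), editable.
# Approximate consensus strings for the common PlantCARE element names;
# these are literature consensi, not PlantCARE's internal matrices.
name	pattern
ABRE	ACGTGGC
CGTCA-motif	CGTCA
ARE	AAACCA
W box	TTGACC
MBS	CAACTG
LTR	CCGAAA
TC-rich repeats	GTTTTCTTAC
GCN4_motif	TGAGTCA
ERE	ATTTCAAA
O2-site	GATGACATGG
TGA-element	AACGAC
GARE-motif	TCTGTTG
DRE core	GCCGAC
WUN-motif	AAATTTCCT
box S	AGCCACC
RY-element	CATGCATG
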
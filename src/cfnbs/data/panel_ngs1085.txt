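# Synthetic stand-in for a hypothetical NGS panel of all CFTR2
# disease-causing variants routinely detectable by sequencing.
# Fictitious; deliberately excludes large deletions (e.g. whole-exon
# CFTRdele alleles), which routine NGS newborn-screening assays miss.
F508del
G542X
G551D
N1303K
W1282X
R553X
621+1G->T
1717-1G->A
3849+10kbC->T
3876delA
R117H
2789+5G->A
3120G->A
3271delGG
2184insA
711+3A->G
R347P
394delTT
1078delT
2143delT
3659delC
2307insA
1811+1634A->G
1898+5G->T
H199Y
Q1100P
R1066C
S466X
622-1G->C
A559T
405+3A->C
444delA
Y1092X
M1101K
c.4242+2T>C
2789+2insA
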
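# Synthetic stand-in for a 139-variant commercial CFTR assay.
# Fictitious superset of panel_core used for tests and examples.
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
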
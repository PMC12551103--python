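# Synthetic stand-in for a state 39-variant CFTR screening panel.
# Fictitious subset used for tests and examples; real panel contents are
# laboratory-specific and must be supplied by the user.
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
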
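gene	role
MAOA	query
MAOB	query
SLC63A	query
DRD2	query
CDH13	query
COMT	query
OXTR	query
SLC6A4	query
NR3C1	query
ADH1B	selected_ihs
SEC24B	selected_candidate
CTNNA1	selected_candidate
NCOA2	selected_candidate
ALDH3A2	selected_candidate
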
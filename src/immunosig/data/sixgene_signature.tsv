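# Frozen six-gene immune-related signature for PD-1-inhibitor + GemCis ICC
# cohorts. Provenance (contributing pathways) is not part of the public
# record for this signature and is left empty.
# Columns: gene <TAB> provenance (semicolon-joined pathway names, may be empty)
PSMB10
PSMB9
LAG3
CCL5
IFI35
SH2D1A
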
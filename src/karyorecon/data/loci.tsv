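# label	chromosome	band
# Locus table at cytoband resolution: FISH probe targets and genes of
# interest in the HEL erythroleukaemia cell line. Band placements follow
# the probe designations used to map them (e.g. D20S108 at 20q12).
MLL	11	q23.3
JAK2	9	p24.1
CDKN2A	9	p21.3
D20S108	20	q12
TET2	4	q24
TP53	17	p13.1
FHIT	3	p14.2
MECOM	3	q26.2
RUNX1	21	q22.12
MYB	6	q23.3
E2F1	20	q11.21
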
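# HEL subline aberration matrix: four independently maintained specimens of the
# HEL erythroleukaemia cell line (VCCS, DSMZ, ATCC, CGP) scored for presence (1)
# absence (0) or unknown/conflicting (?) of copy-number aberrations (CNA,
# reversible) and loss-of-heterozygosity regions (LOH, irreversible).
# Transcribed from the published SNP-array comparison of the four sublines;
# cells whose published scoring was footnoted as conflicting or could not be
# read unambiguously are encoded "?".
character,class,VCCS,DSMZ,ATCC,CGP
loh_4q,LOH,1,1,1,0
gain_der_4_20,CNA,1,1,1,0
gain_8q22_fourth_copy,CNA,1,1,1,0
gain_mll_fifth_copy,CNA,1,1,1,0
del_3p_der_3_18,CNA,1,0,1,?
del_18p_der_3_18,CNA,1,0,1,?
loh_18_ring_18,LOH,1,0,0,0
cap_18qter_der_9,CNA,1,0,0,0
gain_der_8_t4_8_13,CNA,1,0,0,0
gain_11q_der_9_breakpoint,CNA,1,0,0,0
gain_der_10_19_second_copy,CNA,1,?,1,?
gain_der_19,CNA,1,?,1,1
loh_9,LOH,1,1,1,1
loh_20q12,LOH,1,1,1,1
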
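"""Parse the bundled HEL karyotype and query it at band resolution.

The HEL erythroleukaemia cell line has a near-triploid genome with ~21
structured (derivative, ring, pseudodicentric) chromosomes.  This script
parses the published ISCN string and asks the questions a cytogeneticist
would: how many copies of MLL and JAK2, which abnormal chromosomes carry
chromosome-20 material, and which of those carry the chromosome 20
centromere.
"""

from importlib import resources

import karyorecon as kr

text = (resources.files("karyorecon") / "data" / "hel_vccs.txt").read_text()
line = [l for l in text.splitlines() if l.strip() and not l.startswith("#")][0]

model = kr.parse_karyotype(line)
print(f"chromosome count range : {model.count_range}")
print(f"ploidy baseline        : {model.ploidy}n")
print(f"structured chromosomes : {len(model.structured)}")

loci = kr.bundled_loci()
for name in ("MLL", "JAK2", "CDKN2A", "D20S108"):
    cn = kr.copy_number(model, loci[name])
    flag = " (lower bound; unspecified amplification)" if cn.uncertain else ""
    print(f"copies of {name:8s}      : {int(cn)}{flag}")
print(f"net MLL gain over {model.ploidy}n  : {int(kr.copy_number(model, loci['MLL'])) - model.ploidy}")

carriers = [sc for sc in model.structured if "20" in sc.chromosomes_present()]
print(f"\nabnormal chromosomes with chr20 material ({len(carriers)}):")
for sc in carriers:
    has_cen = any(s.interval.chrom == "20" and kr.spans_centromere(s.interval)
                  for s in sc.segments)
    print(f"  {sc.notation()[:60]:60s} 20cen={'yes' if has_cen else 'no'}")

# Expected: 5 copies of MLL (net gain 2 over triploid), 5 chr20-positive
# abnormal chromosomes of which 3 (der(4;20), der(20), r(20)) carry the 20
# centromere — the der(19) carries 20q11.1 material but a captured 19
# centromere instead.
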
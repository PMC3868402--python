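# karyorecon

Reconstructing complex cancer karyotypes from cytogenetic and SNP-array
evidence, built around the HEL erythroleukaemia cell line genome.

Cancer cell lines such as HEL carry dozens of structurally rearranged
chromosomes. No single assay resolves them: G-banding and ISCN karyotype
strings describe structure, SNP arrays measure copy number and homologue
ratios, and FISH (whole-chromosome paints, band-level M-BAND, centromere and
NOR probes) reveals which material sits on which abnormal chromosome — and,
critically, where the centromeres are. `karyorecon` turns the combined
interpretive procedure into a tested library:

- **`karyorecon.genome`** — a band-ordinal coordinate system over a bundled
  cytoband map, with interval algebra, centromere semantics
  (`spans_centromere`) and copy-number queries over parsed karyotypes.
- **`karyorecon.iscn`** — an ISCN 2013 parser/renderer covering the short
  form (`der(1)t(1;15)(p36.3;q22.31)`), whole-arm translocations
  (`der(5;17)(p10;q10)`), the detailed system
  (`der(20)(15qter->15q11.2::20q10->…)`), rings, pseudodicentrics,
  del/dup/amp modifiers, uncertainty marks (`?`, `∼`) and clone frequencies.
- **`karyorecon.observe`** — forward models: SNP-array probe tables where a
  site with homologue copies (n_A, n_B) has expected B-allele frequency
  BAF = n_B/(n_A+n_B) and log R ratio LRR = log2((n_A+n_B)/2) plus Gaussian
  noise; deterministic paint/M-BAND/centromere/NOR observations.
- **`karyorecon.reconstruct`** — the inversion: joint binary segmentation of
  the LRR and folded-BAF tracks, allele-specific copy-number calling
  (t = round(2·2^LRR), split by folded BAF), and exact backtracking
  assignment of segments to derivatives under paint, centromere-count and
  terminal-segment constraints.
- **`karyorecon.lineage`** — subline phylogeny by exhaustive rooted-tree
  parsimony with irreversible LOH characters (loss of heterozygosity cannot
  revert: a 1→0 change costs infinity), plus ploidy-logic event ordering
  (a rearrangement of one copy of a duplicated homologue postdates the
  doubling).
- **`karyorecon.bfb`** — breakage–fusion–bridge simulation on dicentric
  chromosomes: uniform bridge breaks between active centromeres,
  palindromic sister-chromatid fusion, and stabilisation by centromere
  inactivation, telomere/centromere capture or pericentromeric ring
  excision; per-band copy-number profiles and a BFB-consistency test.

## Worked example

```python
import karyorecon as kr
from importlib import resources

text = (resources.files("karyorecon") / "data" / "hel_vccs.txt").read_text()
line = [l for l in text.splitlines() if l and not l.startswith("#")][0]
model = kr.parse_karyotype(line)

loci = kr.bundled_loci()
print(len(model.structured))                      # 21 structured chromosomes
print(kr.copy_number(model, loci["MLL"]))         # CopyNumber(count=5, ...)
carriers = [sc for sc in model.structured
            if "20" in sc.chromosomes_present()]
print(len(carriers))                              # 5
```

Parsing the bundled HEL karyotype yields 21 structured chromosomes; the MLL
oncogene at 11q23.3 is present in 5 copies (the two remaining normal
chromosome-11 homologues plus the 11q23.2→11qter segments of the der(4;20),
der(19) and der(20)) — a net gain of 2 over the triploid baseline. Five
abnormal chromosomes carry chromosome-20 material but only three of them
(der(4;20), der(20), r(20)) carry the chromosome 20 centromere; the der(19)
instead carries a captured chromosome 19 centromere. The scripts in
`examples/` walk through each capability and print these numbers:

```
$ python examples/subline_tree.py
1 minimum-cost topology(ies), cost 14:
  (((ATCC,VCCS),DSMZ),CGP);
```

i.e. the CGP subline diverged first and VCCS/ATCC are the closest pair.

A thin CLI mirrors the library: `karyorecon parse|simulate|infer|lineage|bfb`.

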
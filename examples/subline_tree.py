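"""Infer the HEL subline evolutionary tree from CNA/LOH characters.

Four independently maintained HEL sublines (VCCS, DSMZ, ATCC, CGP) are
scored for shared copy-number aberrations (reversible) and LOH regions
(irreversible — heterozygosity cannot be regained, so shared LOH is strong
evidence of common ancestry).  All 15 rooted binary topologies are scored
by parsimony, rooted at the founding leukaemic clone with no derived
aberrations; LOH characters may never revert.
"""

from karyorecon.lineage import best_tree, bundled_character_matrix

matrix = bundled_character_matrix()
print(f"{len(matrix.characters)} characters x {len(matrix.taxa)} sublines "
      f"({sum(c.char_class == 'LOH' for c in matrix.characters)} irreversible LOH)")

trees = best_tree(matrix)
print(f"\n{len(trees)} minimum-cost topology(ies), cost {trees[0].cost:g}:")
for t in trees:
    print(f"  {t.newick()}")
    for clade, char, kind in sorted(t.edge_changes, key=lambda x: sorted(x[0])):
        members = ",".join(sorted(clade))
        print(f"    {char:28s} {kind}  on edge to {{{members}}}")

# The unique minimiser is (((ATCC,VCCS),DSMZ),CGP): CGP diverged first
# (it lacks chromosome-4 LOH and the der(4;20)), and VCCS/ATCC are the
# closest pair (they share the 3p/18p deletions the DSMZ specimen lacks).
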
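# Methods

## Coordinate system

All positions are *band ordinals*. Each chromosome's leaf cytobands are
numbered pter→qter, with `pter` below every band, `qter` above, and the
synthetic whole-arm markers `p10`/`q10` inserted between the arms so that
centromere questions reduce to ordinal algebra: an interval spans the
centromere iff its covered ordinal range touches `p10` or `q10` (which is
also what makes whole-arm `der(A;B)(p10;q10)` halves centromere-bearing by
construction). Base-pair columns of the cytoband file are carried as
metadata only; no internal logic uses them, because karyotype strings carry
no base-pair breakpoints.

The bundled `cytobands.tsv` is authored for this package: ISCN-style band
names at roughly 550-band resolution for all 24 chromosomes, with nominal
(uniform 3 Mb) base-pair widths. It is internally consistent, ordered
mechanically from the nomenclature (p-arm descending, q-arm ascending,
sub-bands by decimal value), and covers every band designator the bundled
karyotype uses. Any UCSC-dialect cytoBand file can be substituted.

Lower-resolution designators (`11q23`) resolve to the ordinal span of their
sub-bands; a locus written at parent-band resolution is contained in an
interval iff any sub-band is. Uncertain designators (`19p13.?`, `22p11∼2`,
`q1?0`) resolve conservatively to the widest consistent span and propagate
an `uncertain` flag into query results; the tilde shorthand substitutes
trailing digits (`p11∼2` = p11-to-p12).

## ISCN dialect and bookkeeping

The parser covers exactly the constructs a complex leukaemia karyotype
needs: counts and count ranges, ploidy markers (`<3n>`), sex designations,
numerical gains/losses, `der` in short form (two- and three-way `t()`,
applied left to right), whole-arm form, and the detailed system (`::`
junctions, stored exactly as written — the written order is the physical
order), `r`, `psu dic` (first-named centromere active), `dup`, `del`,
trailing `del`/`dup`/`amp` modifier clauses, uncertainty marks, and
bracketed clone frequencies. Everything else raises a parse error naming
the offending substring and offset; nothing is silently skipped.

Short-form expansion is canonicalised pter→qter along the derivative: a
breakpoint on the p arm sheds material toward the low-ordinal end and
receives the partner's distal fragment with its telomere outward. For a
three-way translocation, the named chromosome's breakpoint may be written
as a band pair (`der(8)t(4;8;13)(q32.1;p12q22.1;q21.31)`), in which case
the retained portion lies between the two breakpoints and receives the
previous list member's fragment on the first side and the next member's on
the second; this reproduces the detailed-system form printed for the same
derivative.

`normal_count` implements ISCN bookkeeping — ploidy baseline, ± numerical
events, minus one normal homologue per un-gained structured chromosome per
cited centromere chromosome. Clone frequencies are read as subclone sizes:
consumption is weighted by clone fraction relative to the modal clone and
rounded, so mutually exclusive alternatives written in one string (`-18[4]`
with `r(18)[7]` across 11 cells, or the two der(8) variants) do not
double-consume. A sex designation is taken as the literal present
complement; the `-X`/`-Y` tokens are stored but not double-counted.
Unspecified `amp` modifiers contribute a lower bound of 2 copies and mark
the result uncertain — the printed string genuinely underdetermines such
counts. Bare repeats (`+der(10;19)`) resolve against the matching defined
derivative anywhere in the string.

Rendering is canonical (events sorted by chromosome, numerical before
structural, then token text) and is a fixed point under re-parsing; model
equality compares canonical token multisets, so written order never
matters. `random_model` generates valid karyotypes (numerical events,
short-form/whole-arm/detailed derivatives, rings, dups) for the round-trip
corpus.

## Forward models

`assign_homologues` encodes the configuration seen throughout this genome:
rearranged segments come from homologue A and, for chromosomes involved in
structured events, the remaining normal copies are the duplicated
unrearranged homologue B; untouched chromosomes split normals evenly.
Truth at a band is (n_A, n_B) = normal split + labelled segment
multiplicities, with del/dup/amp modifiers applied on their own chromosome.

The array model is deliberately minimal: `density` probes per leaf band
(default 50) at jittered within-band pseudo-positions, germline
heterozygosity `h` = 0.35 per site, LRR = log2(t/2) + N(0, σ_lrr = 0.15)
referenced to diploid regardless of ploidy baseline (as diploid-referenced
array software reports near-triploid genomes — ploidy enters only at
calling), and BAF = n_B/t + N(0, σ_baf = 0.03) at heterozygous sites,
0/1 + noise at homozygous sites, truncated to [0,1] by clamping. Zero
total copies emit a NaN no-signal sentinel. The defaults are the package's
chosen operating point, not measured values; σ values are free parameters
and every test tolerance is stated against them. What this generator does
*not* emulate: GC waves and dye bias, probe-specific error, mosaicism,
tumour purity, X-inactivation — so passing inversion tests demonstrate
correctness of the inference machinery under the stated noise model, not
performance on raw array exports.

FISH observations are deterministic: per structured chromosome, the paint
source set (segment chromosomes restricted to the probe panel; the bundled
`XCYTE_PANEL` is {3,4,10,11,13,15,18,19,20}), ordered panel-visible band
blocks, centromere counts via `spans_centromere`, and a NOR count (segments
carrying acrocentric short-arm material).

## Inversion

Segmentation is greedy binary segmentation on the summed within-segment
squared error of two channels: LRR and folded BAF (|BAF−0.5|, computed over
probes inside the heterozygous window [0.08, 0.92]; probes outside it are
treated as germline-homozygous candidates and excluded, mirroring standard
BAF practice). A split is accepted when it reduces the total cost by more
than `penalty` (default 1.0, comfortably above the ≈0.4 expected spurious
reduction at the default noise level and far below the reduction of any
real copy-state junction at 50 probes/band) with at least `min_probes`
(default 10) on each side. Calling: t = round(2·2^meanLRR) capped at 8;
(n_A, n_B) minimises |meanFoldedBAF − (n_A/t − 0.5)| over n_A ≥ n_B, ties
toward balance; a segment with no heterozygous probes is an LOH call
(t, 0); t = 0 is homozygous deletion.

Phase (which side is homologue A) is not inferred from the array — the
folded convention n_A ≥ n_B is kept until derivative assignment, matching
the reliance on FISH for structure. Band accuracy therefore compares
unordered pairs {n_A, n_B}.

Assembly is exact backtracking (derivatives by decreasing paint-set size,
segments by decreasing span — fail fast): a complete assignment must give
each derivative exactly its panel-visible source set, match recorded
centromere-probe counts, place at most two terminal (pter/qter-reaching)
segments per linear derivative and none on rings, and match per-chromosome
M-BAND block counts where blocks are recorded (a band-level consistency
check; full block-order matching is not attempted at this resolution). All
solutions are returned in deterministic order — ambiguity is reported,
never silently resolved — and segments whose chromosome appears in no
paint are reported unplaced. `recover` scores two things against the
generating truth: band-level allele-specific accuracy from the array
pipeline, and derivative-composition accuracy by pooling the truth's
segments and re-deriving the jigsaw from the paint constraints alone.

## Lineage

Characters are binary aberration states with `?` for unknown or conflicting
cells. Reversible (CNA) characters change in either direction at unit
cost; irreversible (LOH) characters may never change 1→0 (infinite cost) —
the asymmetric-parsimony model appropriate for loss of heterozygosity. The
tree is rooted at the founding clone, which sits *above* the root node in
state 0 for every character, so an aberration shared by all sublines costs
exactly one gain. Scoring is Sankoff dynamic programming, verified against
exhaustive ancestral-state enumeration; search enumerates all rooted binary
topologies (15 at four taxa; capped at eight taxa) and returns every
minimiser with per-edge changes. Constant matrices are legal (every
topology ties at the same cost); `CharacterMatrix.informative` flags
whether any character varies.

The bundled subline matrix transcribes the published four-subline
SNP-array comparison into 14 characters; cells whose published scoring was
footnoted as conflicting, or whose column alignment could not be read
unambiguously from the source, are encoded `?` rather than guessed, and the
CSV carries row comments so the transcription can be audited without code
changes.

Event-order constraints come from ploidy logic: a homologue present in ≥2
copies of which exactly one is rearranged must have doubled before the
rearrangement; a derivative present in two identical copies must have
formed before its duplication; explicit parent→child derivations chain
formation ≺ duplication ≺ remodelling. The output is a conflict-checked
DAG.

## BFB simulation

Structures are ordered oriented blocks on a continuous axis (one unit per
leaf band, so breakpoints are sub-band and bands subdivide freely), with
per-block centromere sites carrying an active/inactive flag and explicit
end states. A bridge break draws uniformly between the two active
centromeres and yields two products, each with one centromere and a broken
end facing the break; sister fusion appends the mirror image, giving a
palindrome about the fusion junction. `run_bfb` iterates
break → segregate one product (left/right/random; the unfollowed product is
retained in the history) → fuse, then applies a stabilisation event:
centromere inactivation (pseudodicentric), telomere capture (donor
terminal segment caps the broken end; donors are explicit inputs, never
invented), centromere capture (the native centromere-bearing piece is shed
by a second cut and the remaining acentric fragment acquires a short
centromere-bearing donor — the der(19)/der(20) pattern), or ring excision
(cuts flanking one centromere, joined into a ring, emitting the acentric
remnants). Every stochastic draw is logged; histories replay to identical
structures.

Two properties deserve care. First, *confinement*: each sister fusion
duplicates the entire followed structure, telomeric arm included, so the
correct baseline for "amplification between the centromeres" is the
lineage's own telomeric-arm level (`arm_start_counts` reads it off the
non-fused arm's tip), against which elevation is confined to the
inter-centromeric arms for every seed and cycle count. Second, the
*staircase*: observed profiles like the der(9) form a single-peak
staircase at band resolution, and `bfb_consistent` checks that — but deep
simulated histories with alternating segregation can leave one
chromosome's material as interior cargo whose band-level counts are
multi-peaked, so the report separates `confined` (the hard condition) from
`staircase_ok` (a diagnostic, with the peak side reported). This is a
genuine property of the process, not an implementation artefact.

Scenario JSONs drive replays. The dic(9;22) scenario scripts its break
positions (as fractions of the inter-centromeric span) so that both 9p- and
22p-derived blocks survive into the stabilised product for any seed; under
strict sister-fusion mechanics the stabilised pseudodicentric necessarily
carries two copies of one founding centromere (one inactivated) rather
than one centromere from each chromosome — producing the latter would
require non-sister rejoining, which is outside the modelled operation set
and noted as a limitation. The replay's checked claims are amplification
restricted to 9p and 22p, zero 9q/22q elevation, and exactly one
inactivated centromere.

## Problem sizes and determinism

Defaults throughout are chosen so the full test suite and the acceptance
script each run in about a minute on one CPU: 50 probes/band over a
six-chromosome toy karyotype (~3 000 probes/chromosome), a 200-karyotype
round-trip corpus, 10-seed noise sweeps, 100-seed BFB sweeps with ≤6
cycles, and exhaustive enumeration at four taxa. Every random draw flows
from an explicit integer seed (`numpy.random.default_rng`); identical
inputs and seeds give byte-identical observations, assignments and
histories.

## Known limitations

- Band-ordinal resolution cannot express sub-band deletions (the homozygous
  CDKN2A deletion sits inside a band its derivative otherwise retains) or
  segment lengths; `amp` without a count stays a flagged lower bound.
- The ISCN dialect excludes constructs absent from the target genome
  (`ins`, `inv` short forms, `idic`, composite clones).
- The assembler's M-BAND check is per-chromosome block counts, not full
  order matching; multiple satisfying assignments are all returned.
- Lineage inference is unweighted parsimony on a hand-transcribed matrix;
  no branch lengths, no likelihood model.
- BFB scenarios are consistency demonstrations of proposed histories, not
  inference of a unique true history from data.
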
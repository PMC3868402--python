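"""Forward models of SNP-array and FISH observations.

A SNP array reports, per probe, a log-scale total-copy signal (LRR, log R
ratio) and the B-allele frequency (BAF) — the fraction of signal from one of
the two parental homologues.  For a site with ``nA`` copies of homologue A
and ``nB`` of homologue B, the expected BAF at a germline-heterozygous SNP is
``nB / (nA + nB)``; germline-homozygous sites sit at 0 or 1 regardless of
copy state.  Whole-chromosome paints (M-FISH), band-level multicolour
banding (M-BAND), centromere probes and the acrocentric NOR probe report the
source composition of each abnormal chromosome.

This module generates both kinds of observation from a homologue-labelled
karyotype, with seeded Gaussian probe noise — the statistical structure that
the :mod:`karyorecon.reconstruct` module inverts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import CytobandMap, Segment, bundled_map, spans_centromere, _norm_chrom
from .iscn import KaryotypeModel, StructuredChromosome

__all__ = [
    "HomologueAssignedKaryotype",
    "ProbeGrid",
    "ArrayObservation",
    "PaintObservation",
    "assign_homologues",
    "band_copy_table",
    "expected_baf",
    "simulate_array",
    "simulate_fish",
    "XCYTE_PANEL",
]

# chromosomes covered by the XCyte M-BAND probe set used on HEL
XCYTE_PANEL = frozenset({"3", "4", "10", "11", "13", "15", "18", "19", "20"})

_ACROCENTRIC = {"13", "14", "15", "21", "22"}


@dataclass
class HomologueAssignedKaryotype:
    """A karyotype whose material is attributed to parental homologues.

    ``normal_split`` maps chromosome -> (nA, nB) normal-copy counts; every
    structured-chromosome segment carries an A/B label.  The forward models
    are pure functions of this object.
    """

    model: KaryotypeModel
    normal_split: dict[str, tuple[int, int]]
    cmap: CytobandMap | None = None

    def __post_init__(self):
        self.cmap = self.cmap or bundled_map()
        for sc in self.model.structured:
            for seg in sc.segments:
                if seg.homologue not in ("A", "B"):
                    raise ValueError(
                        f"unlabelled segment {seg.interval} in {sc.notation()}")
        for c, (na, nb) in self.normal_split.items():
            if na < 0 or nb < 0:
                raise ValueError(f"negative homologue count for {c}")

    def counts_at(self, chrom: str, ordinal: int) -> tuple[int, int]:
        """(nA, nB) at one band ordinal, summing normal homologues and every
        structured segment covering the band."""
        c = _norm_chrom(chrom)
        na, nb = self.normal_split.get(c, (0, 0))
        for sc in self.model.structured:
            contrib = {"A": 0, "B": 0}
            for seg in sc.segments:
                if seg.interval.chrom != c:
                    continue
                span = seg.interval.covered_span(self.cmap)
                if span.lo <= ordinal <= span.hi:
                    contrib[seg.homologue] += seg.multiplicity
            for mod in sc.modifiers:
                if mod.interval.chrom != c:
                    continue
                span = mod.interval.covered_span(self.cmap)
                if not (span.lo <= ordinal <= span.hi):
                    continue
                lab = _modifier_label(sc, c)
                if mod.kind == "del":
                    contrib[lab] = max(contrib[lab] - 1, 0)
                elif mod.kind == "dup":
                    contrib[lab] += 1
                elif mod.kind == "amp":
                    contrib[lab] = max(contrib[lab], 2)
            na += contrib["A"]
            nb += contrib["B"]
        return na, nb


def _modifier_label(sc: StructuredChromosome, chrom: str) -> str:
    for seg in sc.segments:
        if seg.interval.chrom == chrom and seg.homologue in ("A", "B"):
            return seg.homologue
    return "A"


def assign_homologues(model: KaryotypeModel,
                      cmap: CytobandMap | None = None) -> HomologueAssignedKaryotype:
    """Default homologue attribution: every rearranged segment comes from
    homologue A, and for chromosomes involved in structured events the
    remaining normal copies are the duplicated unrearranged homologue B
    (the configuration seen throughout HEL); untouched chromosomes split
    their normal copies as evenly as possible."""
    cmap = cmap or bundled_map()
    touched: set[str] = set()
    for sc in model.structured:
        for seg in sc.segments:
            seg.homologue = "A"
        touched |= sc.chromosomes_present()
    split: dict[str, tuple[int, int]] = {}
    chroms = [str(i) for i in range(1, 23)] + ["X", "Y"]
    for c in chroms:
        try:
            n = model.normal_count(c)
        except ValueError:
            n = 0
        if c in touched:
            split[c] = (0, n)
        else:
            split[c] = (n - n // 2, n // 2)
    return HomologueAssignedKaryotype(model, split, cmap)


def band_copy_table(hk: HomologueAssignedKaryotype,
                    chromosomes: list[str] | None = None) -> pd.DataFrame:
    """Per-leaf-band truth table of (nA, nB) for a labelled karyotype."""
    cmap = hk.cmap
    rows = []
    for c in chromosomes or cmap.chromosomes:
        for b in cmap.bands(c):
            o = cmap._ordmap(c)[b.name]
            na, nb = hk.counts_at(c, o)
            rows.append((c, b.name, o, na, nb))
    return pd.DataFrame(rows, columns=["chrom", "band", "ordinal", "nA", "nB"])


# ---------------------------------------------------------------------------
# SNP array

@dataclass(frozen=True)
class ProbeGrid:
    """Probe positions on the band-ordinal axis.

    ``density`` probes per leaf band at jittered within-band fractions;
    ``het_fraction`` is the germline heterozygosity probability per probe
    site.  Position realisation is a pure function of the seed.
    """

    density: int = 50
    het_fraction: float = 0.35
    chromosomes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.density < 1:
            raise ValueError("density must be >= 1")
        if not 0.0 <= self.het_fraction <= 1.0:
            raise ValueError("het_fraction must lie in [0, 1]")

    def positions(self, cmap: CytobandMap) -> pd.DataFrame:
        """Realise the grid: one row per probe (chrom, band, ordinal, pos)."""
        rng = np.random.default_rng(self.seed)
        chroms = self.chromosomes or tuple(cmap.chromosomes)
        rows = []
        for c in chroms:
            omap = cmap._ordmap(c)
            for b in cmap.bands(c):
                o = omap[b.name]
                jitter = np.sort(rng.uniform(size=self.density))
                for k, u in enumerate(jitter):
                    rows.append((c, b.name, o, o + (k + u) / (self.density + 1)))
        df = pd.DataFrame(rows, columns=["chrom", "band", "ordinal", "pos"])
        df.insert(0, "probe_id", [f"p{i:06d}" for i in range(len(df))])
        return df


@dataclass
class ArrayObservation:
    """Simulated SNP-array probe table plus generation metadata.

    ``probes`` columns: probe_id, chrom, band, ordinal, pos, lrr, baf,
    het (germline zygosity truth), no_signal.  LRR is diploid-referenced
    (log2(t/2)) regardless of the karyotype's ploidy baseline, matching how
    array software reports near-triploid genomes.
    """

    probes: pd.DataFrame
    sigma_lrr: float
    sigma_baf: float
    seed: int
    baseline_ploidy: int

    def to_tsv(self, path) -> None:
        cols = ["probe_id", "chrom", "band", "pos", "lrr", "baf"]
        self.probes[cols].to_csv(path, sep="\t", index=False)


def expected_baf(nA: int, nB: int) -> float | None:
    """Expected B-allele frequency at a heterozygous site with homologue
    copy counts (nA, nB); None signals probe dropout (no copies at all)."""
    if nA < 0 or nB < 0:
        raise ValueError("negative homologue count")
    t = nA + nB
    if t == 0:
        return None
    return nB / t


def simulate_array(hk: HomologueAssignedKaryotype,
                   grid: ProbeGrid,
                   sigma_lrr: float = 0.15,
                   sigma_baf: float = 0.03,
                   seed: int = 0) -> ArrayObservation:
    """Generate a probe table from a labelled karyotype.

    Per probe at band b with truth (nA, nB), t = nA + nB:
    LRR = log2(t/2) + N(0, sigma_lrr); BAF = clamp[0,1] of nB/t + N(0,
    sigma_baf) at heterozygous sites and of the homozygous allele (0 or 1)
    plus noise otherwise.  Sites with t = 0 are emitted with the no-signal
    sentinel (NaN).  Identical inputs and seed give identical tables.
    """
    cmap = hk.cmap
    pos = grid.positions(cmap)
    rng = np.random.default_rng(seed)
    n = len(pos)
    truth = np.array([hk.counts_at(c, o)
                      for c, o in zip(pos["chrom"], pos["ordinal"])])
    na, nb = truth[:, 0].astype(float), truth[:, 1].astype(float)
    t = na + nb
    het = rng.random(n) < grid.het_fraction
    hom_allele = (rng.random(n) < 0.5).astype(float)  # 0 -> all-A, 1 -> all-B
    lrr_noise = rng.normal(0.0, sigma_lrr, n) if sigma_lrr > 0 else np.zeros(n)
    baf_noise = rng.normal(0.0, sigma_baf, n) if sigma_baf > 0 else np.zeros(n)

    with np.errstate(divide="ignore", invalid="ignore"):
        lrr = np.log2(t / 2.0) + lrr_noise
        exp_baf = np.where(het, nb / np.where(t > 0, t, np.nan), hom_allele)
    baf = np.clip(exp_baf + baf_noise, 0.0, 1.0)
    no_signal = t == 0
    lrr[no_signal] = np.nan
    baf[no_signal] = np.nan

    probes = pos.copy()
    probes["lrr"] = lrr
    probes["baf"] = baf
    probes["het"] = het
    probes["no_signal"] = no_signal
    probes["nA"] = truth[:, 0]
    probes["nB"] = truth[:, 1]
    return ArrayObservation(probes, sigma_lrr, sigma_baf, seed,
                            hk.model.ploidy)


# ---------------------------------------------------------------------------
# FISH

@dataclass
class PaintObservation:
    """Deterministic FISH read-out for one structured chromosome.

    ``source_set``: chromosomes contributing >=1 band, restricted to the
    M-FISH/M-BAND probe panel; ``mband_blocks``: panel-visible band blocks in
    physical order; ``centromere_counts``: per tested chromosome, the number
    of segments spanning its centromere; ``nor_count``: acrocentric
    short-arm (NOR-positive) segments.
    """

    name: str
    source_set: frozenset[str]
    mband_blocks: list[tuple[str, str, str]]
    centromere_counts: dict[str, int]
    nor_count: int
    ring: bool = False
    is_terminal_capped: bool = True

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "source_set": sorted(self.source_set),
            "mband_blocks": [list(b) for b in self.mband_blocks],
            "centromere_counts": dict(self.centromere_counts),
            "nor_count": self.nor_count,
            "ring": self.ring,
        }


def _nor_positive(seg: Segment, cmap: CytobandMap) -> bool:
    c = seg.interval.chrom
    if c not in _ACROCENTRIC:
        return False
    span = seg.interval.covered_span(cmap)
    p10, _ = cmap.centromere_span(c)
    # acrocentric p-arm material (p11.2-p13) sits below p11.1/p10
    return span.lo < p10 - 1 or (span.lo <= 1 <= span.hi)


def simulate_fish(model: KaryotypeModel | HomologueAssignedKaryotype,
                  panel: frozenset[str] | set[str] = XCYTE_PANEL,
                  centromere_probes: set[str] | None = None,
                  cmap: CytobandMap | None = None) -> list[PaintObservation]:
    """Forward-model M-FISH/M-BAND/centromere/NOR observations for every
    structured chromosome of a karyotype.  Deterministic."""
    if isinstance(model, HomologueAssignedKaryotype):
        cmap = model.cmap
        model = model.model
    cmap = cmap or bundled_map()
    panel = {_norm_chrom(c) for c in panel}
    paints = []
    for k, sc in enumerate(model.structured):
        sources = sc.chromosomes_present() & panel
        blocks = [(s.interval.chrom, s.interval.start, s.interval.end)
                  for s in sc.segments if s.interval.chrom in panel]
        tested = ({_norm_chrom(c) for c in centromere_probes}
                  if centromere_probes is not None
                  else sc.chromosomes_present())
        cen_counts = {
            c: sum(1 for s in sc.segments
                   if s.interval.chrom == c and spans_centromere(s.interval, cmap))
            for c in sorted(tested)
        }
        nor = sum(1 for s in sc.segments if _nor_positive(s, cmap))
        name = f"{k}:{sc.notation()}"
        paints.append(PaintObservation(
            name=name,
            source_set=frozenset(sources),
            mband_blocks=blocks,
            centromere_counts=cen_counts,
            nor_count=nor,
            ring=sc.ring,
        ))
    return paints
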
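"""Inverting SNP-array and FISH observations back to a karyotype.

The inversion mirrors the manual procedure used to untangle complex cancer
genomes: (1) segment each chromosome's LRR/BAF probe track into homogeneous
regions, (2) call total and allele-specific copy number per region from the
mean LRR and mean folded BAF, and (3) assign the resulting segments to
structured chromosomes under the constraints imposed by whole-chromosome
paints, M-BAND block content, centromere-probe counts and the
terminal-segment rule (a pter/qter-reaching segment can only occupy a
chromosome end; rings have no ends).

Segmentation is binary segmentation on the joint squared error of the LRR
and folded-BAF channels; a split is accepted when it lowers the total
within-segment squared error by more than ``penalty`` and leaves at least
``min_probes`` probes on each side.  Probes with BAF outside the
heterozygous window (default [0.08, 0.92]) are treated as
germline-homozygous candidates and excluded from folded-BAF means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BandInterval, CytobandMap, bundled_map
from .observe import (
    ArrayObservation,
    HomologueAssignedKaryotype,
    PaintObservation,
    band_copy_table,
)

__all__ = [
    "CalledSegment",
    "AssemblyProblem",
    "AssignmentResult",
    "RecoveryReport",
    "segment_baf_lrr",
    "call_allelic_cn",
    "call_segments",
    "assign_segments",
    "recover",
    "HET_WINDOW",
]

HET_WINDOW = (0.08, 0.92)


@dataclass
class CalledSegment:
    """One homogeneous region with its allele-specific copy-number call.

    (nA, nB) follows the folded-BAF convention nA >= nB until phase is
    assigned through derivative assembly.
    """

    interval: BandInterval
    n_probes: int
    mean_lrr: float
    mean_folded_baf: float
    total: int
    nA: int
    nB: int
    uncertain: bool = False
    terminal: bool = False

    def __post_init__(self):
        if self.nA + self.nB != self.total:
            raise ValueError("nA + nB must equal total copy number")
        if self.nA < self.nB:
            raise ValueError("folded-BAF convention requires nA >= nB")


# ---------------------------------------------------------------------------
# segmentation

def _sse(prefix: np.ndarray, prefix2: np.ndarray, counts: np.ndarray,
         i: int, j: int) -> float:
    """Within-segment squared error of a channel over probe slice [i, j),
    using prefix sums that skip NaN entries."""
    n = counts[j] - counts[i]
    if n == 0:
        return 0.0
    s = prefix[j] - prefix[i]
    s2 = prefix2[j] - prefix2[i]
    return float(s2 - s * s / n)


def _binary_segment(lrr: np.ndarray, fold: np.ndarray, penalty: float,
                    min_probes: int) -> list[int]:
    """Changepoint indices (split positions) for one chromosome."""
    n = len(lrr)
    l = np.nan_to_num(lrr)
    lc = np.concatenate([[0], np.cumsum(~np.isnan(lrr))])
    lp = np.concatenate([[0], np.cumsum(np.where(np.isnan(lrr), 0.0, l))])
    lp2 = np.concatenate([[0], np.cumsum(np.where(np.isnan(lrr), 0.0, l * l))])
    f = np.nan_to_num(fold)
    fc = np.concatenate([[0], np.cumsum(~np.isnan(fold))])
    fp = np.concatenate([[0], np.cumsum(np.where(np.isnan(fold), 0.0, f))])
    fp2 = np.concatenate([[0], np.cumsum(np.where(np.isnan(fold), 0.0, f * f))])

    def cost(i: int, j: int) -> float:
        return (_sse(lp, lp2, lc, i, j) + _sse(fp, fp2, fc, i, j))

    cps: list[int] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2 * min_probes:
            continue
        whole = cost(i, j)
        best_gain, best_k = penalty, None
        for k in range(i + min_probes, j - min_probes + 1):
            gain = whole - cost(i, k) - cost(k, j)
            if gain > best_gain:
                best_gain, best_k = gain, k
        if best_k is not None:
            cps.append(best_k)
            stack.append((i, best_k))
            stack.append((best_k, j))
    return sorted(cps)


def segment_baf_lrr(obs: ArrayObservation, penalty: float = 1.0,
                    min_probes: int = 10) -> dict[str, list[int]]:
    """Joint LRR/folded-BAF changepoints per chromosome.

    Returns, per chromosome, the sorted probe indices (within that
    chromosome's position-sorted probe list) at which a new segment starts.
    Chromosomes with fewer than 2*min_probes probes get no changepoints.
    Deterministic for fixed input.
    """
    out: dict[str, list[int]] = {}
    for chrom, sub in obs.probes.groupby("chrom", sort=False):
        sub = sub.sort_values("pos")
        lrr = sub["lrr"].to_numpy(float)
        baf = sub["baf"].to_numpy(float)
        het = (baf >= HET_WINDOW[0]) & (baf <= HET_WINDOW[1])
        fold = np.where(het, np.abs(baf - 0.5), np.nan)
        if len(sub) < 2 * min_probes:
            out[chrom] = []
            continue
        out[chrom] = _binary_segment(lrr, fold, penalty, min_probes)
    return out


# ---------------------------------------------------------------------------
# allele-specific calling

def call_allelic_cn(mean_lrr: float, mean_folded_baf: float,
                    baseline_ploidy: int = 2,
                    max_total: int = 8) -> tuple[int, int]:
    """(nA, nB) with nA >= nB from segment means.

    Total t = round(2 * 2^meanLRR) (diploid-referenced LRR), capped at
    ``max_total``; the split minimises |meanFoldedBAF - (nA/t - 0.5)| with
    ties broken toward the more balanced pair.  t = 0 is the
    homozygous-deletion call (0, 0).
    """
    if np.isnan(mean_lrr):
        return (0, 0)
    t = int(round(2.0 * 2.0 ** mean_lrr))
    t = max(0, min(t, max_total))
    if t == 0:
        return (0, 0)
    if np.isnan(mean_folded_baf):
        # no heterozygous probes: LOH region
        return (t, 0)
    best = None
    for nA in range((t + 1) // 2, t + 1):  # balanced first; ties keep first
        nB = t - nA
        err = abs(mean_folded_baf - (nA / t - 0.5))
        if best is None or err < best[0] - 1e-12:
            best = (err, nA, nB)
    return best[1], best[2]


def call_segments(obs: ArrayObservation, penalty: float = 1.0,
                  min_probes: int = 10, max_total: int = 8,
                  cmap: CytobandMap | None = None) -> list[CalledSegment]:
    """Segment every chromosome of an observation and call (nA, nB) per
    segment, returning band-resolved CalledSegments."""
    cmap = cmap or bundled_map()
    cps = segment_baf_lrr(obs, penalty, min_probes)
    segments: list[CalledSegment] = []
    for chrom, sub in obs.probes.groupby("chrom", sort=False):
        sub = sub.sort_values("pos").reset_index(drop=True)
        bounds = [0] + cps.get(chrom, []) + [len(sub)]
        qter = cmap.qter_ordinal(chrom)
        for i, j in zip(bounds[:-1], bounds[1:]):
            piece = sub.iloc[i:j]
            lrr = piece["lrr"].to_numpy(float)
            baf = piece["baf"].to_numpy(float)
            het = (baf >= HET_WINDOW[0]) & (baf <= HET_WINDOW[1])
            mean_lrr = float(np.nanmean(lrr)) if np.any(~np.isnan(lrr)) else float("nan")
            fold = np.abs(baf[het] - 0.5)
            mean_fold = float(np.mean(fold)) if fold.size else float("nan")
            nA, nB = call_allelic_cn(mean_lrr, mean_fold,
                                     max_total=max_total)
            start_band = piece.iloc[0]["band"]
            end_band = piece.iloc[-1]["band"]
            start = "pter" if piece.iloc[0]["ordinal"] == 1 else start_band
            end = "qter" if piece.iloc[-1]["ordinal"] == qter - 1 else end_band
            segments.append(CalledSegment(
                interval=BandInterval(chrom, start, end),
                n_probes=j - i,
                mean_lrr=mean_lrr,
                mean_folded_baf=mean_fold,
                total=nA + nB, nA=nA, nB=nB,
                uncertain=bool(np.isnan(mean_lrr)),
                terminal=(start == "pter" or end == "qter"),
            ))
    return segments


# ---------------------------------------------------------------------------
# derivative assembly

@dataclass
class AssemblyProblem:
    """Segments to place, paints to satisfy, and the probe panel in force."""

    segments: list
    paints: list[PaintObservation]
    panel: frozenset[str]
    cmap: CytobandMap | None = None

    def __post_init__(self):
        self.cmap = self.cmap or bundled_map()


@dataclass
class AssignmentResult:
    """All satisfying assignments (segment index -> paint name), plus the
    explicitly unplaced segments; if none, the violated constraint."""

    solutions: list[dict[int, str]]
    unplaced: list[int]
    infeasible_reason: str | None = None

    @property
    def feasible(self) -> bool:
        return bool(self.solutions)


def _segment_chrom(seg) -> str:
    return seg.interval.chrom


def _is_terminal(seg) -> bool:
    t = getattr(seg, "terminal", None)
    if t is not None:
        return t
    return seg.interval.start in ("pter", "qter") or seg.interval.end in ("pter", "qter")


def _seg_spans_cen(seg, cmap) -> bool:
    from .genome import spans_centromere
    return spans_centromere(seg.interval, cmap)


def assign_segments(problem: AssemblyProblem) -> AssignmentResult:
    """Exact backtracking assignment of segments to structured chromosomes.

    A complete assignment must satisfy, per derivative: (i) the set of
    panel-visible chromosomes among its segments equals its M-FISH source
    set; (ii) per tested chromosome, the number of centromere-spanning
    segments equals the centromere-probe count; (iii) at most two terminal
    (pter/qter-reaching) segments — zero for rings; (iv) the per-chromosome
    segment count matches the M-BAND block count when blocks are recorded.
    All solutions are returned in deterministic order; segments whose
    chromosome appears in no paint are reported unplaced.
    """
    cmap = problem.cmap
    paints = sorted(problem.paints, key=lambda p: (-len(p.source_set), p.name))
    seg_order = sorted(
        range(len(problem.segments)),
        key=lambda i: (-_span_size(problem.segments[i], cmap), i))
    placeable = [i for i in seg_order
                 if any(_segment_chrom(problem.segments[i]) in p.source_set
                        for p in paints)]
    unplaced = [i for i in seg_order if i not in placeable]

    block_counts = {}
    for p in paints:
        if p.mband_blocks:
            counts: dict[str, int] = {}
            for c, _, _ in p.mband_blocks:
                counts[c] = counts.get(c, 0) + 1
            block_counts[p.name] = counts

    solutions: list[dict[int, str]] = []
    assignment: dict[int, str] = {}
    state = {p.name: {"chroms": {}, "terminals": 0, "cen": {}} for p in paints}
    fail: dict[str, str] = {"reason": "no segments"}

    def ok_final() -> str | None:
        for p in paints:
            st = state[p.name]
            seen = {c for c in st["chroms"] if st["chroms"][c] > 0 and c in problem.panel}
            if seen != set(p.source_set):
                missing = set(p.source_set) - seen
                return (f"{p.name}: source set mismatch"
                        + (f" (no segment from chromosome {sorted(missing)})"
                           if missing else ""))
            for c, want in p.centromere_counts.items():
                if st["cen"].get(c, 0) != want:
                    return f"{p.name}: centromere count for chromosome {c}"
            if p.name in block_counts:
                for c, want in block_counts[p.name].items():
                    if st["chroms"].get(c, 0) != want:
                        return f"{p.name}: M-BAND block count for chromosome {c}"
        return None

    def backtrack(k: int) -> None:
        if k == len(placeable):
            reason = ok_final()
            if reason is None:
                solutions.append(dict(assignment))
            else:
                fail["reason"] = reason
            return
        i = placeable[k]
        seg = problem.segments[i]
        c = _segment_chrom(seg)
        term = _is_terminal(seg)
        cen = _seg_spans_cen(seg, cmap)
        for p in paints:
            if c not in p.source_set:
                continue
            st = state[p.name]
            if term and (p.ring or st["terminals"] >= 2):
                fail["reason"] = (f"{p.name}: terminal segment {seg.interval} "
                                  "cannot occupy an interior position")
                continue
            if cen and c in p.centromere_counts and \
                    st["cen"].get(c, 0) + 1 > p.centromere_counts[c]:
                fail["reason"] = f"{p.name}: centromere count for chromosome {c}"
                continue
            if p.name in block_counts and \
                    st["chroms"].get(c, 0) + 1 > block_counts[p.name].get(c, 0):
                fail["reason"] = f"{p.name}: M-BAND block count for chromosome {c}"
                continue
            assignment[i] = p.name
            st["chroms"][c] = st["chroms"].get(c, 0) + 1
            st["terminals"] += term
            if cen:
                st["cen"][c] = st["cen"].get(c, 0) + 1
            backtrack(k + 1)
            st["chroms"][c] -= 1
            st["terminals"] -= term
            if cen:
                st["cen"][c] -= 1
            del assignment[i]

    backtrack(0)
    if solutions:
        return AssignmentResult(solutions, unplaced)
    return AssignmentResult([], unplaced, fail["reason"])


def _span_size(seg, cmap) -> int:
    span = seg.interval.covered_span(cmap)
    return span.hi - span.lo + 1


# ---------------------------------------------------------------------------
# end-to-end recovery

@dataclass
class RecoveryReport:
    """Accuracy of an end-to-end inversion against the generating truth."""

    band_accuracy: float
    composition_accuracy: float
    n_solutions: int
    called_segments: list[CalledSegment]
    n_bands: int
    mismatched_bands: list[tuple[str, str]] = field(default_factory=list)


def recover(obs: ArrayObservation, paints: list[PaintObservation],
            truth: HomologueAssignedKaryotype,
            penalty: float = 1.0, min_probes: int = 10,
            panel: frozenset[str] | None = None) -> RecoveryReport:
    """Run segmentation -> calling -> assignment and score against truth.

    Band-level allele-specific accuracy is the fraction of probed leaf bands
    whose called {nA, nB} (unordered — phase is not knowable from the array
    alone) equals the truth.  Composition accuracy re-solves the derivative
    jigsaw: the truth's structured segments are pooled and reassigned from
    the paint constraints alone; a derivative scores when its recovered
    chromosome multiset matches the truth.
    """
    cmap = truth.cmap
    called = call_segments(obs, penalty, min_probes, cmap=cmap)

    # band-level allele-specific copy-number accuracy
    chroms = sorted(obs.probes["chrom"].unique(),
                    key=lambda c: (len(c), c))
    truth_tab = band_copy_table(truth, chroms)
    truth_map = {(r.chrom, r.ordinal): (r.nA, r.nB)
                 for r in truth_tab.itertuples()}
    call_map: dict[tuple[str, int], tuple[int, int]] = {}
    for seg in called:
        span = seg.interval.covered_span(cmap)
        for o in range(span.lo, span.hi + 1):
            call_map[(seg.interval.chrom, o)] = (seg.nA, seg.nB)
    hits, total = 0, 0
    mism: list[tuple[str, str]] = []
    probed = {(c, o) for c, o in
              zip(obs.probes["chrom"], obs.probes["ordinal"])}
    for key in sorted(probed):
        t = truth_map.get(key)
        g = call_map.get(key, (0, 0))
        if t is None:
            continue
        total += 1
        if tuple(sorted(t, reverse=True)) == tuple(sorted(g, reverse=True)):
            hits += 1
        else:
            mism.append((key[0], str(key[1])))
    band_acc = hits / total if total else float("nan")

    # derivative composition: reassemble the truth's parts from paints alone
    parts = [seg for sc in truth.model.structured for seg in sc.segments]
    truth_owner = [k for k, sc in enumerate(truth.model.structured)
                   for _ in sc.segments]
    panel = panel or frozenset().union(*[p.source_set for p in paints]) \
        if paints else frozenset()
    problem = AssemblyProblem(parts, paints, panel, cmap)
    result = assign_segments(problem)
    comp_acc = 0.0
    if result.feasible:
        sol = result.solutions[0]
        per_paint_true: dict[str, list[str]] = {p.name: [] for p in paints}
        per_paint_got: dict[str, list[str]] = {p.name: [] for p in paints}
        for i, seg in enumerate(parts):
            pname = f"{truth_owner[i]}:{truth.model.structured[truth_owner[i]].notation()}"
            if pname in per_paint_true:
                per_paint_true[pname].append(seg.interval.chrom)
            if i in sol:
                per_paint_got[sol[i]].append(seg.interval.chrom)
        match = sum(1 for name in per_paint_true
                    if sorted(per_paint_true[name]) == sorted(per_paint_got[name]))
        comp_acc = match / len(paints) if paints else float("nan")
    return RecoveryReport(band_acc, comp_acc, len(result.solutions),
                          called, total, mism)
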
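"""Band-level genome coordinate system.

Cytogenetic data locate events at the resolution of chromosome bands
("11q23.3"), not base pairs.  This module provides the coordinate system the
rest of the package works in: an ordered cytoband map per chromosome, band
interval algebra (containment, orientation, centromere spanning) and
copy-number queries over a parsed karyotype.

Coordinates are *ordinal*: each leaf band of a chromosome gets an integer
position in pter->qter order, with ``pter`` below all bands and ``qter`` above
all bands, and the synthetic centromeric markers ``p10``/``q10`` sitting
between the two arms.  Base-pair intervals from the cytoband file are carried
along as optional metadata only; all logic works at band resolution.

Band designators written at lower resolution ("11q23") resolve to the ordinal
span of their sub-bands; uncertain designators ("19p13.?", "22p11~2") resolve
conservatively to the widest consistent span and propagate an ``uncertain``
flag to query results.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "CytobandMap",
    "Locus",
    "BandInterval",
    "Segment",
    "TermSpan",
    "CopyNumber",
    "BandLookupError",
    "load_cytoband_map",
    "load_locus_table",
    "bundled_map",
    "bundled_loci",
    "band_index",
    "contains",
    "spans_centromere",
    "copy_number",
]


class BandLookupError(KeyError):
    """Unknown chromosome or band designator."""


_BAND_RE = re.compile(r"^([pq])(\d+)(?:\.(\d*))?(?:[∼~](\d+))?$")


def _norm_chrom(chrom: str) -> str:
    c = str(chrom)
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.lstrip("?")
    return c.upper() if c in ("x", "y") else c


def _band_sort_key(name: str) -> tuple[int, float]:
    m = _BAND_RE.match(name)
    if m is None:
        raise ValueError(f"unparseable band name: {name!r}")
    major = int(m.group(2))
    frac = m.group(3) or ""
    return major, (int(frac) / 10 ** len(frac) if frac else 0.0)


@dataclass(frozen=True)
class Band:
    """One leaf record of the cytoband map."""

    chrom: str
    name: str          # e.g. "q23.3" (arm-prefixed, chromosome-relative)
    arm: str           # "p" or "q"
    ordinal: int       # pter->qter position; pter is 0
    start: int | None = None   # optional base-pair interval
    end: int | None = None
    stain: str | None = None


@dataclass(frozen=True)
class TermSpan:
    """Resolved ordinal span of a band designator or terminus.

    A leaf band resolves to a single ordinal (lo == hi); a parent band or an
    uncertain designator resolves to the ordinal span of all consistent leaf
    bands.
    """

    lo: int
    hi: int
    uncertain: bool = False

    @property
    def mid(self) -> float:
        return (self.lo + self.hi) / 2.0


class CytobandMap:
    """Ordered band lists per chromosome with ordinal lookup.

    Bands are stored strictly pter->qter.  The synthetic markers ``p10`` and
    ``q10`` are inserted at the p/q junction so that centromere semantics
    (whole-arm translocations, ring spans) fall out of plain ordinal algebra.
    """

    def __init__(self, bands: Iterable[Band]):
        self._bands: dict[str, list[Band]] = {}
        for b in bands:
            self._bands.setdefault(b.chrom, []).append(b)
        self._ord: dict[str, dict[str, int]] = {}
        self._qter: dict[str, int] = {}
        for chrom, blist in self._bands.items():
            blist.sort(key=lambda b: b.ordinal)
            seen: dict[str, int] = {}
            prev_arm = "p"
            for b in blist:
                if b.name in seen:
                    raise ValueError(f"duplicate band {chrom}{b.name}")
                if b.arm == "p" and prev_arm == "q":
                    raise ValueError(f"band order violation at {chrom}{b.name}")
                prev_arm = b.arm
                seen[b.name] = b.ordinal
            np_ = sum(1 for b in blist if b.arm == "p")
            # re-index: pter=0, p bands 1..np, p10, q10, q bands, qter
            omap: dict[str, int] = {"pter": 0}
            k = 0
            for b in blist:
                if b.arm == "p":
                    k += 1
                    omap[b.name] = k
            omap["p10"] = np_ + 1
            omap["q10"] = np_ + 2
            k = np_ + 2
            for b in blist:
                if b.arm == "q":
                    k += 1
                    omap[b.name] = k
            omap["qter"] = k + 1
            self._ord[chrom] = omap
            self._qter[chrom] = k + 1

    @property
    def chromosomes(self) -> list[str]:
        return list(self._bands)

    def bands(self, chrom: str) -> list[Band]:
        c = _norm_chrom(chrom)
        try:
            return self._bands[c]
        except KeyError:
            raise BandLookupError(f"unknown chromosome: {chrom!r}") from None

    def centromere_span(self, chrom: str) -> tuple[int, int]:
        """Ordinals of (p10, q10) for a chromosome."""
        o = self._ordmap(chrom)
        return o["p10"], o["q10"]

    def qter_ordinal(self, chrom: str) -> int:
        c = _norm_chrom(chrom)
        if c not in self._qter:
            raise BandLookupError(f"unknown chromosome: {chrom!r}")
        return self._qter[c]

    def _ordmap(self, chrom: str) -> dict[str, int]:
        c = _norm_chrom(chrom)
        try:
            return self._ord[c]
        except KeyError:
            raise BandLookupError(f"unknown chromosome: {chrom!r}") from None

    def resolve(self, chrom: str, token: str) -> TermSpan:
        """Resolve a band designator or terminus to its ordinal span.

        Accepts pter/qter/p10/q10/cen, leaf bands ("q23.3"), parent bands
        ("q23"), uncertain bands ("p13.?", "q1?0") and tilde ranges
        ("p11~2" meaning p11-to-p12).
        """
        omap = self._ordmap(chrom)
        tok = token.strip()
        uncertain = "?" in tok or "∼" in tok or "~" in tok
        if tok in ("pter", "qter", "p10", "q10"):
            o = omap[tok]
            return TermSpan(o, o)
        if tok == "cen":
            return TermSpan(omap["p10"], omap["q10"])
        clean = tok.replace("?", "")
        m = _BAND_RE.match(clean)
        if m is None:
            raise BandLookupError(f"unknown band designator: {chrom}{token!r}")
        arm, major, frac, tilde = m.group(1), m.group(2), m.group(3), m.group(4)
        majors = [major]
        if tilde is not None:
            # "p11∼2" means p11-to-p12: tilde digits substitute the trailing
            # digits of the first designator
            lo = int(major)
            hi = int(tilde)
            if hi < lo and len(tilde) < len(major):
                hi = int(major[: len(major) - len(tilde)] + tilde)
            if hi < lo:
                lo, hi = hi, lo
            majors = [str(v) for v in range(lo, hi + 1)]
        prefixes = []
        for mj in majors:
            prefixes.append(f"{arm}{mj}" + (f".{frac}" if frac else ""))
        hits = []
        for name, o in omap.items():
            if name in ("pter", "qter", "p10", "q10"):
                continue
            for p in prefixes:
                if name == p or _nests(name, p):
                    hits.append(o)
                    break
        if not hits:
            raise BandLookupError(f"unknown band designator: {chrom}{token!r}")
        lo, hi = min(hits), max(hits)
        return TermSpan(lo, hi, uncertain)

    def has_band(self, chrom: str, token: str) -> bool:
        try:
            self.resolve(chrom, token)
            return True
        except BandLookupError:
            return False


def _nests(leaf: str, parent: str) -> bool:
    """True if leaf band name nests inside a lower-resolution designator.

    "q23.1" nests in "q23"; "q13.11" nests in "q13.1"; "q21" does not nest
    in "q2".
    """
    lm = _BAND_RE.match(leaf)
    pm = _BAND_RE.match(parent)
    if lm is None or pm is None or lm.group(1) != pm.group(1):
        return False
    if lm.group(2) != pm.group(2):
        return False
    lf, pf = lm.group(3) or "", pm.group(3) or ""
    return lf.startswith(pf)


@dataclass(frozen=True)
class Locus:
    """A named locus placed at band resolution (e.g. MLL at 11q23.3)."""

    chrom: str
    band: str
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))


@dataclass(frozen=True)
class BandInterval:
    """An oriented band interval as written in a karyotype segment.

    ``start``/``end`` are band designators or termini (pter/qter/p10/q10) on
    one chromosome.  An interval whose start lies qter-ward of its end is a
    legal inverted-orientation interval (the written order is the physical
    order along the derivative).
    """

    chrom: str
    start: str
    end: str

    def __post_init__(self):
        object.__setattr__(self, "chrom", _norm_chrom(self.chrom))

    def resolve(self, cmap: CytobandMap) -> tuple[TermSpan, TermSpan]:
        return cmap.resolve(self.chrom, self.start), cmap.resolve(self.chrom, self.end)

    def covered_span(self, cmap: CytobandMap) -> TermSpan:
        """Widest ordinal span covered by the interval (orientation-free)."""
        s, e = self.resolve(cmap)
        return TermSpan(min(s.lo, e.lo), max(s.hi, e.hi), s.uncertain or e.uncertain)

    def inverted(self, cmap: CytobandMap) -> bool:
        s, e = self.resolve(cmap)
        return s.mid > e.mid

    @property
    def uncertain_written(self) -> bool:
        return any(c in self.start + self.end for c in "?∼~")

    def __str__(self) -> str:
        return f"{self.chrom}{self.start}->{self.chrom}{self.end}"


@dataclass
class Segment:
    """One oriented piece of a structured chromosome.

    ``homologue`` tracks which parental homologue the material came from
    (assigned during simulation or reconstruction, "unknown" otherwise);
    ``multiplicity`` is the copy count of the piece within the chromosome,
    flagged unspecified for bare "amp" notation.
    """

    interval: BandInterval
    homologue: str = "unknown"
    multiplicity: int = 1
    multiplicity_unspecified: bool = False
    as_written: str | None = None

    def __post_init__(self):
        if self.multiplicity < 1:
            raise ValueError("segment multiplicity must be >= 1")
        if self.homologue not in ("A", "B", "unknown"):
            raise ValueError(f"bad homologue label: {self.homologue!r}")


@dataclass(frozen=True)
class CopyNumber:
    """A copy-number query result; ``uncertain`` marks unspecified-amp input."""

    count: int
    uncertain: bool = False

    def __int__(self) -> int:
        return self.count

    def __eq__(self, other) -> bool:
        if isinstance(other, CopyNumber):
            return (self.count, self.uncertain) == (other.count, other.uncertain)
        if isinstance(other, int):
            return self.count == other
        return NotImplemented

    def __hash__(self):
        return hash((self.count, self.uncertain))


# ---------------------------------------------------------------------------
# readers

def load_cytoband_map(path: str | Path) -> CytobandMap:
    """Read a UCSC cytoBand-style tab-delimited file (chrom, start, end, band,
    stain); chromosome names accepted with or without a "chr" prefix.  File
    order must be pter->qter per chromosome."""
    records: list[Band] = []
    counters: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed cytoband line: {line!r}")
            chrom = _norm_chrom(parts[0])
            name = parts[3]
            arm = name[0]
            if arm not in "pq":
                raise ValueError(f"band name without arm: {line!r}")
            counters[chrom] = counters.get(chrom, 0) + 1
            records.append(
                Band(chrom, name, arm, counters[chrom],
                     int(parts[1]), int(parts[2]),
                     parts[4] if len(parts) > 4 else None)
            )
    return CytobandMap(records)


def load_locus_table(path: str | Path) -> dict[str, Locus]:
    """Read a tab-delimited locus table (label, chromosome, band)."""
    out: dict[str, Locus] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, chrom, band = line.split("\t")[:3]
            out[label] = Locus(chrom, band, label)
    return out


def _data_path(name: str) -> Path:
    return Path(resources.files("karyorecon") / "data" / name)


_BUNDLED_MAP: CytobandMap | None = None
_BUNDLED_LOCI: dict[str, Locus] | None = None


def bundled_map() -> CytobandMap:
    """The cytoband map shipped with the package (band-name resolution;
    nominal base-pair coordinates)."""
    global _BUNDLED_MAP
    if _BUNDLED_MAP is None:
        _BUNDLED_MAP = load_cytoband_map(_data_path("cytobands.tsv"))
    return _BUNDLED_MAP


def bundled_loci() -> dict[str, Locus]:
    global _BUNDLED_LOCI
    if _BUNDLED_LOCI is None:
        _BUNDLED_LOCI = load_locus_table(_data_path("loci.tsv"))
    return _BUNDLED_LOCI


# ---------------------------------------------------------------------------
# operations

def band_index(cmap: CytobandMap, chrom: str, token: str) -> int:
    """Ordinal position of a band or terminus; parent/uncertain designators
    return the midpoint-rounded ordinal of their span."""
    span = cmap.resolve(chrom, token)
    return span.lo if span.lo == span.hi else int(span.mid)


def contains(interval: BandInterval, locus: Locus, cmap: CytobandMap | None = None) -> bool:
    """True iff the locus band lies within the interval's ordinal range.

    Orientation-independent; a locus on another chromosome is simply not
    contained.  A locus given at parent-band resolution is contained iff any
    of its sub-bands is.
    """
    cmap = cmap or bundled_map()
    if _norm_chrom(locus.chrom) != interval.chrom:
        return False
    span = interval.covered_span(cmap)
    loc = cmap.resolve(locus.chrom, locus.band)
    return loc.lo <= span.hi and loc.hi >= span.lo


def spans_centromere(interval: BandInterval, cmap: CytobandMap | None = None) -> bool:
    """True iff the interval includes the centromere (touches p10/q10 or has
    termini on opposite arms)."""
    cmap = cmap or bundled_map()
    p10, q10 = cmap.centromere_span(interval.chrom)
    span = interval.covered_span(cmap)
    return span.lo <= p10 <= span.hi or span.lo <= q10 <= span.hi


def copy_number(karyotype, locus: Locus, cmap: CytobandMap | None = None) -> CopyNumber:
    """Total copies of a locus implied by a parsed karyotype.

    Normal-homologue count (see ``KaryotypeModel.normal_count``) plus the
    multiplicity of every structured-chromosome segment containing the locus,
    adjusted by trailing del/dup/amp modifier clauses.  Unspecified "amp"
    multiplicities contribute a lower bound and set the ``uncertain`` flag.
    """
    cmap = cmap or bundled_map()
    chrom = _norm_chrom(locus.chrom)
    cmap.resolve(chrom, locus.band)  # raises BandLookupError if unknown
    total = karyotype.normal_count(chrom)
    uncertain = False
    for sc in karyotype.structured:
        contrib = 0
        for seg in sc.segments:
            if contains(seg.interval, locus, cmap):
                contrib += seg.multiplicity
                if seg.multiplicity_unspecified:
                    uncertain = True
        for mod in sc.modifiers:
            if _norm_chrom(mod.interval.chrom) != chrom:
                continue
            if not contains(mod.interval, locus, cmap):
                continue
            if mod.kind == "del":
                contrib = max(contrib - 1, 0)
            elif mod.kind == "dup":
                contrib += 1
            elif mod.kind == "amp":
                # region asserted present in >=2 copies, exact count unknown
                contrib = max(contrib, 2)
                uncertain = True
        total += contrib
    return CopyNumber(total, uncertain)
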
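"""ISCN 2013 karyotype parsing and rendering.

Parses single-clone karyotype strings written in the ISCN short form
(``der(1)t(1;15)(p36.3;q22.31)``), whole-arm form (``der(5;17)(p10;q10)``)
and detailed system (``der(20)(15qter->15q11.2::20q10->...)``) into a
:class:`KaryotypeModel`, and renders models back to canonical strings.

Supported dialect: chromosome-count ranges, ploidy markers (``<3n>``), sex
designations, numerical gains/losses, ``der`` (short-form t() including
three-way, whole-arm, detailed system), ``r`` (ring), ``psu dic``, ``dup``,
``del``, trailing del/dup/amp modifier clauses, ``?`` and ``∼`` uncertainty,
and per-event clone frequencies (``[11]``).  Anything else raises
:class:`IscnParseError` naming the offending substring — never a silent skip.

Both the Unicode tilde ``∼`` and ASCII ``~`` are accepted, as are ``->`` and
``→``.  Detailed-system segments are stored exactly as written (the written
order is the physical order); short-form expansions are canonicalised
pter->qter along the derivative.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

from .genome import (
    BandInterval,
    BandLookupError,
    CytobandMap,
    Segment,
    bundled_map,
    _norm_chrom,
)

__all__ = [
    "KaryotypeModel",
    "StructuredChromosome",
    "NumericalEvent",
    "Modifier",
    "IscnParseError",
    "parse_karyotype",
    "expand_short_form",
    "render",
    "random_model",
]

_CHROMS = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_ORDER = {c: i for i, c in enumerate(_CHROMS)}


class IscnParseError(ValueError):
    """Malformed or unsupported ISCN construct."""

    def __init__(self, message: str, token: str = "", offset: int | None = None):
        self.token = token
        self.offset = offset
        loc = f" at offset {offset}" if offset is not None else ""
        tok = f" in {token!r}" if token else ""
        super().__init__(f"{message}{tok}{loc}")


@dataclass
class Modifier:
    """A trailing del/dup/amp clause attached to a structured chromosome."""

    kind: str                   # "del" | "dup" | "amp"
    interval: BandInterval
    multiplicity_unspecified: bool = False

    def __post_init__(self):
        if self.kind not in ("del", "dup", "amp"):
            raise ValueError(f"bad modifier kind {self.kind!r}")


@dataclass
class NumericalEvent:
    """A whole-chromosome gain (+N) or loss (-N)."""

    chrom: str
    delta: int                  # +1 or -1
    clone_freq: int | None = None
    sex_deviation: bool = False  # bookkeeping token relative to ploidy, see docs

    def notation(self) -> str:
        return ("+" if self.delta > 0 else "-") + self.chrom


@dataclass
class StructuredChromosome:
    """A derivative, ring, pseudodicentric, dup or del chromosome."""

    kind: str                           # "der" | "r" | "psu dic" | "dup" | "del"
    cited: tuple[str, ...]              # centromere chromosomes as named
    segments: list[Segment] = field(default_factory=list)
    gained: bool = False
    ring: bool = False
    modifiers: list[Modifier] = field(default_factory=list)
    # (chromosome, active) for each centromere named; one active for psu dic
    centromere_states: list[tuple[str, bool]] = field(default_factory=list)
    clone_freq: int | None = None
    cited_uncertain: bool = False
    _raw: str | None = None             # original token text, for rendering

    def __post_init__(self):
        if self.kind == "r":
            self.ring = True
        if self.kind == "psu dic":
            active = [c for c, a in self.centromere_states if a]
            if self.centromere_states and len(active) != 1:
                raise ValueError("psu dic must have exactly one active centromere")

    def notation(self) -> str:
        if self._raw is not None:
            return self._raw
        return self._synthesise()

    def _synthesise(self) -> str:
        cited = ";".join(self.cited)
        body = "::".join(s.as_written or str(s.interval) for s in self.segments)
        prefix = "+" if self.gained else ""
        if self.kind == "r":
            return f"{prefix}r({cited})(::{body}::)"
        name = self.kind
        return f"{prefix}{name}({cited})({body})"

    def chromosomes_present(self) -> set[str]:
        return {s.interval.chrom for s in self.segments}


def expand_short_form(event: StructuredChromosome) -> list[Segment]:
    """The ordered segment list of a structured chromosome.

    Short-form derivatives are expanded at parse time following ISCN
    derivative semantics (the named chromosome keeps its centromere;
    translocated partner tails replace the exchanged telomeric portions);
    this accessor returns a copy of the expansion.
    """
    return [Segment(s.interval, s.homologue, s.multiplicity,
                    s.multiplicity_unspecified, s.as_written)
            for s in event.segments]


@dataclass
class KaryotypeModel:
    """A parsed single-clone karyotype.

    ``ploidy`` is the baseline homologue count implied by the ploidy marker
    (3 for ``<3n>``, else 2); ``events`` holds numerical gains/losses and
    structured chromosomes, each with its bracketed clone frequency.
    """

    count_range: tuple[int, int]
    ploidy: int
    sex: str
    events: list = field(default_factory=list)
    cmap: CytobandMap | None = None

    def __post_init__(self):
        if not 1 <= self.ploidy <= 8:
            raise ValueError(f"ploidy baseline {self.ploidy} outside 1..8")
        self.events.sort(key=_event_sort_key)

    @property
    def structured(self) -> list[StructuredChromosome]:
        return [e for e in self.events if isinstance(e, StructuredChromosome)]

    @property
    def numerical(self) -> list[NumericalEvent]:
        return [e for e in self.events if isinstance(e, NumericalEvent)]

    def normal_count(self, chrom: str) -> int:
        """Copies of the normal (unrearranged) chromosome implied by ISCN
        bookkeeping: ploidy baseline, +/- numerical events, minus one per
        un-gained structured chromosome citing this chromosome as a
        centromere chromosome.

        Clone frequencies mark subclonal events (e.g. ``-18[4]`` and
        ``r(18)[7]`` are alternatives across 11 cells); consumption is
        therefore weighted by clone fraction and the count reported for the
        modal cell, rounded to the nearest integer.
        """
        c = _norm_chrom(chrom)
        freqs = [e.clone_freq for e in self.events if e.clone_freq is not None]
        mode = max(freqs) if freqs else 1

        def w(e) -> float:
            return 1.0 if e.clone_freq is None else e.clone_freq / mode

        if c in ("X", "Y"):
            # sex designation is the literal present complement; the +/-
            # bookkeeping tokens are recorded but not double-counted
            n = float(self.sex.count(c))
            for e in self.numerical:
                if e.chrom == c and not e.sex_deviation:
                    n += e.delta * w(e)
        else:
            n = float(self.ploidy)
            for e in self.numerical:
                if e.chrom == c:
                    n += e.delta * w(e)
        for sc in self.structured:
            if not sc.gained:
                n -= sum(w(sc) for cc in sc.cited if cc == c)
        count = int(round(n))
        if count < 0:
            raise ValueError(
                f"model inconsistency: normal count of chromosome {c} is {count}")
        return count

    def __eq__(self, other) -> bool:
        if not isinstance(other, KaryotypeModel):
            return NotImplemented
        return _canonical_tokens(self) == _canonical_tokens(other) and (
            self.count_range, self.ploidy, self.sex
        ) == (other.count_range, other.ploidy, other.sex)

    def to_dict(self) -> dict:
        return {
            "count_range": list(self.count_range),
            "ploidy": self.ploidy,
            "sex": self.sex,
            "events": [
                {
                    "kind": "numerical",
                    "chrom": e.chrom,
                    "delta": e.delta,
                    "clone_freq": e.clone_freq,
                }
                if isinstance(e, NumericalEvent)
                else {
                    "kind": e.kind,
                    "cited": list(e.cited),
                    "gained": e.gained,
                    "ring": e.ring,
                    "clone_freq": e.clone_freq,
                    "segments": [
                        {
                            "chrom": s.interval.chrom,
                            "start": s.interval.start,
                            "end": s.interval.end,
                            "multiplicity": s.multiplicity,
                        }
                        for s in e.segments
                    ],
                    "modifiers": [
                        {"kind": m.kind, "chrom": m.interval.chrom,
                         "start": m.interval.start, "end": m.interval.end}
                        for m in e.modifiers
                    ],
                    "centromeres": [list(c) for c in e.centromere_states],
                }
                for e in self.events
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _event_sort_key(e):
    if isinstance(e, NumericalEvent):
        chrom, rank, tok = e.chrom, 0, e.notation()
    else:
        chrom, rank, tok = e.cited[0], 1, e.notation()
    return (_CHROM_ORDER.get(chrom, 99), rank, tok)


def _canonical_tokens(model: KaryotypeModel) -> list[tuple[str, int | None]]:
    out = []
    for e in model.events:
        out.append((e.notation(), e.clone_freq))
    return sorted(out)


# ---------------------------------------------------------------------------
# tokeniser helpers

_ARROW = "->"
_FREQ_RE = re.compile(r"\[(\d+)\]$")
_COUNT_RE = re.compile(r"^(\d+)(?:∼(\d+))?$")
_PLOIDY_RE = re.compile(r"^<(\d)n>$")
_NUMERIC_RE = re.compile(r"^([+-])(\d+|X|Y)$")
_CLAUSE_RE = re.compile(r"\s*([a-z][a-z ]*)?\(")
_SEG_TOKEN_RE = re.compile(r"^(\d+|X|Y|\?\d+)?(.+)$")


def _normalise(text: str) -> str:
    return text.replace("→", _ARROW).replace("~", "∼").strip()


def _split_clauses(text: str, token: str, offset: int):
    """Split e.g. "der(4)t(4;14)(p15.33;q23.3)del(4)(p15.32p15.32)" into
    [(name, content), ...] with unnamed parentheticals getting name ""."""
    clauses = []
    i = 0
    while i < len(text):
        m = _CLAUSE_RE.match(text, i)
        if m is None:
            raise IscnParseError("unparseable clause", token, offset + i)
        name = (m.group(1) or "").strip()
        j = m.end()  # position after "("
        depth = 1
        k = j
        while k < len(text) and depth:
            if text[k] == "(":
                depth += 1
            elif text[k] == ")":
                depth -= 1
            k += 1
        if depth:
            raise IscnParseError("unbalanced parentheses", token, offset + i)
        clauses.append((name, text[j:k - 1]))
        i = k
    return clauses


def _parse_chrom(tok: str, token: str, offset: int) -> tuple[str, bool]:
    uncertain = tok.startswith("?")
    c = _norm_chrom(tok)
    if c not in _CHROM_ORDER:
        raise IscnParseError(f"unknown chromosome {tok!r}", token, offset)
    return c, uncertain


def _split_band_run(text: str) -> list[str]:
    """Split a concatenated band-range like "p11.1q11.21" or "q21.1qter"
    into its two band tokens."""
    hits = [m.start() for m in re.finditer(r"[pq](?=\d|ter|10)", text)]
    if len(hits) == 2 and hits[0] == 0:
        return [text[: hits[1]], text[hits[1]:]]
    return [text]


def _parse_seg_token(tok: str, default_chrom: str | None, token: str, offset: int):
    """Parse one side of a detailed-system segment ("20q11.21", "15qter",
    "p11.23") into (chrom, band)."""
    m = _SEG_TOKEN_RE.match(tok)
    if m is None or not m.group(2):
        raise IscnParseError(f"unparseable segment terminus {tok!r}", token, offset)
    chrom = m.group(1)
    band = m.group(2)
    if chrom is None:
        if default_chrom is None:
            raise IscnParseError(
                f"segment terminus {tok!r} has no chromosome", token, offset)
        chrom = default_chrom
    else:
        chrom, _ = _parse_chrom(chrom, token, offset)
    if band[0] not in "pq":
        raise IscnParseError(f"unparseable band {band!r}", token, offset)
    return chrom, band


def _check_band(cmap: CytobandMap, chrom: str, band: str, token: str, offset: int):
    try:
        cmap.resolve(chrom, band)
    except BandLookupError as exc:
        raise IscnParseError(str(exc), token, offset) from None


def _parse_detailed_segments(content: str, default_chrom: str | None,
                             cmap: CytobandMap, token: str, offset: int,
                             ring: bool) -> list[Segment]:
    inner = content
    if ring:
        if not (inner.startswith("::") and inner.endswith("::")):
            raise IscnParseError("ring body must be written ::…::", token, offset)
        inner = inner[2:-2]
    parts = [p for p in inner.split("::") if p]
    if not parts:
        raise IscnParseError("empty detailed segment list", token, offset)
    segs: list[Segment] = []
    for part in parts:
        if _ARROW in part:
            left, right = part.split(_ARROW, 1)
            c1, b1 = _parse_seg_token(left, default_chrom, token, offset)
            c2, b2 = _parse_seg_token(right, c1, token, offset)
            if c1 != c2:
                raise IscnParseError(
                    f"segment {part!r} crosses chromosomes", token, offset)
        else:
            m = _SEG_TOKEN_RE.match(part)
            chrom = m.group(1) if m else None
            body = m.group(2) if chrom else part
            if chrom is not None:
                chrom, _ = _parse_chrom(chrom, token, offset)
            else:
                chrom = default_chrom
            bands = _split_band_run(body)
            if len(bands) != 2 or chrom is None:
                raise IscnParseError(
                    f"unparseable segment {part!r}", token, offset)
            c1, (b1, b2) = chrom, bands
        _check_band(cmap, c1, b1, token, offset)
        _check_band(cmap, c1, b2, token, offset)
        if ring and ("ter" in b1 or "ter" in b2):
            raise IscnParseError("ring segment may not reach a telomere",
                                 token, offset)
        segs.append(Segment(BandInterval(c1, b1, b2), as_written=part))
    return segs


# ---------------------------------------------------------------------------
# short-form expansion

def _arm(band: str) -> str:
    return band[0]


def _whole_arm_segments(cited, bands, cmap, token, offset) -> list[Segment]:
    """der(A;B)(p10;q10) whole-arm translocation semantics."""
    if len(cited) != 2 or len(bands) != 2:
        raise IscnParseError("whole-arm der needs two chromosomes and two "
                             "arm designators", token, offset)
    (a, b), (ba, bb) = cited, bands
    ivA = BandInterval(a, "pter", "p10") if _arm(ba) == "p" else BandInterval(a, "qter", "q10")
    ivB = BandInterval(b, "q10", "qter") if _arm(bb) == "q" else BandInterval(b, "p10", "pter")
    return [Segment(ivA), Segment(ivB)]


def _dic_segments(cited, bands, cmap, token, offset) -> list[Segment]:
    """dic/psu dic fusion: each chromosome keeps its centromeric side of the
    breakpoint, fused at the breakpoints."""
    (a, b), (ba, bb) = cited, bands
    ivA = BandInterval(a, "qter", ba) if _arm(ba) == "p" else BandInterval(a, "pter", ba)
    ivB = BandInterval(b, bb, "qter") if _arm(bb) == "p" else BandInterval(b, bb, "pter")
    return [Segment(ivA), Segment(ivB)]


def _partner_fragment(chrom: str, band: str, attach_left: bool) -> Segment:
    """Telomeric fragment of a translocation partner distal to its breakpoint,
    oriented with the telomere at the free (outer) end."""
    ter = "pter" if _arm(band) == "p" else "qter"
    if attach_left:
        return Segment(BandInterval(chrom, ter, band))
    return Segment(BandInterval(chrom, band, ter))


def _find_anchor(segments: list[Segment], pairs, cmap, token, offset):
    """Locate which (chrom, band) of a t() lies on the current derivative."""
    for idx, (c, b) in enumerate(pairs):
        span = cmap.resolve(c, b)
        for si, seg in enumerate(segments):
            if seg.interval.chrom != c:
                continue
            cov = seg.interval.covered_span(cmap)
            if cov.lo <= span.hi and cov.hi >= span.lo:
                return idx, si
    raise IscnParseError("translocation breakpoint not on derivative",
                         token, offset)


def _apply_translocation(segments, tchroms, tbands, cmap, token, offset):
    """Apply one t(a;b)(x;y) to the current derivative segment list."""
    pairs = list(zip(tchroms, tbands))
    anchor_idx, si = _find_anchor(segments, pairs, cmap, token, offset)
    c, b = pairs[anchor_idx]
    partner_idx = 1 - anchor_idx if len(pairs) == 2 else None
    if partner_idx is None:
        raise IscnParseError("three-way t() must anchor the named chromosome",
                             token, offset)
    mc, mb = pairs[partner_idx]
    seg = segments[si]
    p10, q10 = cmap.centromere_span(c)
    span = cmap.resolve(c, b)
    inverted = seg.interval.inverted(cmap)
    # direction away from the centromere at the breakpoint, in derivative
    # coordinates: p-arm breakpoints shed material toward lower ordinals
    toward_low = span.mid < p10
    replace_left = toward_low != inverted
    if replace_left:
        new = [_partner_fragment(mc, mb, attach_left=True),
               Segment(BandInterval(c, b, seg.interval.end))]
        return new + segments[si + 1:]
    new = [Segment(BandInterval(c, seg.interval.start, b)),
           _partner_fragment(mc, mb, attach_left=False)]
    return segments[:si] + new


def _apply_three_way(segments, tchroms, tbands, cmap, token, offset):
    """Cyclic three-way translocation applied to the named derivative.

    The named chromosome's breakpoint entry may be a band pair (e.g.
    "p12q22.1"), in which case the retained portion lies between the two
    breakpoints and receives the previous list member's distal fragment on
    the first side and the next member's on the second side.
    """
    anchor = None
    for i, (c, b) in enumerate(zip(tchroms, tbands)):
        if any(s.interval.chrom == c for s in segments):
            anchor = i
            break
    if anchor is None:
        raise IscnParseError("three-way t() does not involve the derivative",
                             token, offset)
    c = tchroms[anchor]
    bands = _split_band_run(tbands[anchor])
    prev_c = tchroms[anchor - 1]
    prev_b = tbands[anchor - 1]
    if len(bands) == 2:
        b1, b2 = bands
        next_c = tchroms[(anchor + 1) % len(tchroms)]
        next_b = tbands[(anchor + 1) % len(tchroms)]
        core = Segment(BandInterval(c, b1, b2))
        return [_partner_fragment(prev_c, prev_b, attach_left=True), core,
                _partner_fragment(next_c, next_b, attach_left=False)]
    b = bands[0]
    if _arm(b) == "p":
        core = Segment(BandInterval(c, b, "qter"))
        return [_partner_fragment(prev_c, prev_b, attach_left=True), core]
    core = Segment(BandInterval(c, "pter", b))
    return [core, _partner_fragment(prev_c, prev_b, attach_left=False)]


# ---------------------------------------------------------------------------
# event parsing

def _is_breakpoint_list(content: str) -> bool:
    return (_ARROW not in content and "::" not in content
            and all(p and p[0] in "pq" or p[:1] == "?" or "?" in p
                    for p in content.split(";")))


def _clean_band(band: str, token: str, offset: int) -> str:
    """Normalise a written breakpoint band, keeping uncertainty markers.
    "q1?0" (uncertain centromere designator) becomes "q10" flagged by the
    retained "?" handling in genome.resolve; here we just reorder stray "?"."""
    if "?" in band and not band.endswith("?"):
        stripped = band.replace("?", "")
        return stripped + "?" if stripped[-1] != "." else stripped + "?"
    return band


def _parse_structured(token: str, offset: int, cmap: CytobandMap,
                      gained: bool, clone_freq, raw: str,
                      earlier: list[StructuredChromosome]) -> StructuredChromosome:
    clauses = _split_clauses(token, token, offset)
    name = clauses[0][0]
    if name not in ("der", "r", "psu dic", "dup", "del", "dic"):
        raise IscnParseError(f"unsupported construct {name!r}", token, offset)
    cited_toks = clauses[0][1].split(";")
    cited, cflags = [], False
    for ct in cited_toks:
        c, unc = _parse_chrom(ct, token, offset)
        cited.append(c)
        cflags = cflags or unc
    cited = tuple(cited)
    rest = clauses[1:]

    # "+der(10;19)" with no further clauses: second copy of an earlier event
    if not rest:
        for prev in earlier:
            if prev.cited == cited and prev.kind == name:
                return StructuredChromosome(
                    kind=prev.kind, cited=cited,
                    segments=expand_short_form(prev), gained=gained,
                    ring=prev.ring,
                    modifiers=list(prev.modifiers),
                    centromere_states=list(prev.centromere_states),
                    clone_freq=clone_freq, cited_uncertain=cflags, _raw=raw)
        raise IscnParseError("bare derivative with no earlier definition",
                             token, offset)

    segments: list[Segment] = []
    modifiers: list[Modifier] = []
    centromeres: list[tuple[str, bool]] = []
    kind = name
    i = 0

    def _mod_interval(chrom: str, content: str) -> BandInterval:
        bands = _split_band_run(content)
        if len(bands) == 1:
            bands = bands * 2
        for b in bands:
            _check_band(cmap, chrom, b, token, offset)
        return BandInterval(chrom, bands[0], bands[1])

    first_name, first_content = rest[0]
    if name == "r":
        segments = _parse_detailed_segments(first_content, cited[0], cmap,
                                            token, offset, ring=True)
        centromeres = [(cited[0], True)]
        i = 1
    elif name in ("dup", "del"):
        iv = _mod_interval(cited[0], first_content)
        segments = [Segment(BandInterval(cited[0], "pter", "qter"))]
        modifiers.append(Modifier(name, iv))
        centromeres = [(cited[0], True)]
        kind = name
        i = 1
    elif name in ("psu dic", "dic"):
        bands = [_clean_band(b, token, offset) for b in first_content.split(";")]
        for c, b in zip(cited, bands):
            _check_band(cmap, c, b, token, offset)
        segments = _dic_segments(cited, bands, cmap, token, offset)
        active0 = name == "dic"
        centromeres = [(cited[0], True), (cited[1], active0)]
        if name == "psu dic":
            centromeres = [(cited[0], True), (cited[1], False)]
        kind = name
        i = 1
    elif name == "der":
        if first_name == "" and (_ARROW in first_content or "::" in first_content):
            segments = _parse_detailed_segments(first_content, None, cmap,
                                                token, offset, ring=False)
            centromeres = [(c, True) for c in cited]
            i = 1
        elif first_name == "" and len(cited) == 2 and _is_breakpoint_list(first_content):
            bands = [_clean_band(b, token, offset) for b in first_content.split(";")]
            if all(b.replace("?", "").rstrip(".") in ("p10", "q10") for b in bands):
                segments = _whole_arm_segments(cited, [b.replace("?", "") for b in bands],
                                               cmap, token, offset)
            else:
                segments = _dic_segments(cited, bands, cmap, token, offset)
            centromeres = [(c, True) for c in cited]
            i = 1
        else:
            # short form: sequence of t()(...) applied left to right
            segments = [Segment(BandInterval(cited[0], "pter", "qter"))]
            centromeres = [(cited[0], True)]

    # remaining clauses: t()() pairs and del/dup/amp modifiers
    while i < len(rest):
        cname, ccontent = rest[i]
        if cname == "t":
            if i + 1 >= len(rest) or rest[i + 1][0] != "":
                raise IscnParseError("t() without breakpoint list", token, offset)
            tchroms = [
                _parse_chrom(c, token, offset)[0] for c in ccontent.split(";")]
            tbands = [_clean_band(b, token, offset)
                      for b in rest[i + 1][1].split(";")]
            if len(tchroms) != len(tbands):
                raise IscnParseError(
                    "breakpoint arity mismatch with t() chromosome list",
                    token, offset)
            for c, b in zip(tchroms, tbands):
                for bb in _split_band_run(b):
                    _check_band(cmap, c, bb, token, offset)
            if len(tchroms) == 2:
                segments = _apply_translocation(segments, tchroms, tbands,
                                                cmap, token, offset)
            elif len(tchroms) == 3:
                segments = _apply_three_way(segments, tchroms, tbands,
                                            cmap, token, offset)
            else:
                raise IscnParseError("unsupported t() arity", token, offset)
            i += 2
        elif cname in ("del", "dup", "amp"):
            if i + 1 >= len(rest) or rest[i + 1][0] != "":
                raise IscnParseError(f"{cname}() without band list", token, offset)
            mchrom, _ = _parse_chrom(ccontent, token, offset)
            iv = _mod_interval(mchrom, rest[i + 1][1])
            modifiers.append(Modifier(cname, iv,
                                      multiplicity_unspecified=cname == "amp"))
            i += 2
        else:
            raise IscnParseError(f"unsupported construct {cname!r}", token, offset)

    return StructuredChromosome(
        kind=kind, cited=cited, segments=segments, gained=gained,
        ring=(name == "r"), modifiers=modifiers,
        centromere_states=centromeres, clone_freq=clone_freq,
        cited_uncertain=cflags, _raw=raw)


def parse_karyotype(text: str, cmap: CytobandMap | None = None) -> KaryotypeModel:
    """Parse a single-clone ISCN karyotype string into a model.

    Every comma-separated token is consumed; malformed or unsupported tokens
    raise :class:`IscnParseError` with the offending substring and offset.
    """
    cmap = cmap or bundled_map()
    text = _normalise(text)
    tokens: list[tuple[str, int]] = []
    pos = 0
    for tok in text.split(","):
        tokens.append((tok.strip(), pos))
        pos += len(tok) + 1
    if not tokens:
        raise IscnParseError("empty karyotype", text, 0)

    m = _COUNT_RE.match(tokens[0][0])
    if m is None:
        raise IscnParseError("karyotype must start with a chromosome count",
                             tokens[0][0], 0)
    lo = int(m.group(1))
    hi = int(m.group(2)) if m.group(2) else lo
    idx = 1
    ploidy = 2
    if idx < len(tokens):
        pm = _PLOIDY_RE.match(tokens[idx][0])
        if pm:
            ploidy = int(pm.group(1))
            idx += 1
    sex = ""
    if idx < len(tokens) and re.fullmatch(r"[XY]+", tokens[idx][0]):
        sex = tokens[idx][0]
        idx += 1

    events: list = []
    structured_events: list[tuple[str, int, bool, int | None, str]] = []
    for tok, off in tokens[idx:]:
        if not tok:
            raise IscnParseError("empty token", text, off)
        freq = None
        fm = _FREQ_RE.search(tok)
        if fm:
            freq = int(fm.group(1))
            tok = tok[: fm.start()]
        nm = _NUMERIC_RE.match(tok)
        if nm:
            sign, chrom = nm.group(1), nm.group(2)
            chrom, _ = _parse_chrom(chrom, tok, off)
            events.append(NumericalEvent(
                chrom, +1 if sign == "+" else -1, freq,
                sex_deviation=bool(sex) and chrom in ("X", "Y")))
            continue
        gained = tok.startswith("+")
        body = tok[1:] if gained else tok
        structured_events.append((body, off, gained, freq, tok))
    # two-pass: bare tokens like "+der(10;19)" reference an event defined
    # elsewhere in the string, regardless of ordering
    deferred = []
    for body, off, gained, freq, tok in structured_events:
        if _split_clauses(body, tok, off)[1:]:
            events.append(_parse_structured(body, off, cmap, gained, freq,
                                            tok, []))
        else:
            deferred.append((body, off, gained, freq, tok))
    defined = [e for e in events if isinstance(e, StructuredChromosome)]
    for body, off, gained, freq, tok in deferred:
        events.append(_parse_structured(body, off, cmap, gained, freq, tok,
                                        defined))
    return KaryotypeModel((lo, hi), ploidy, sex, events, cmap)


# ---------------------------------------------------------------------------
# rendering

def render(model: KaryotypeModel) -> str:
    """Render a model to a canonical ISCN string (deterministic event order:
    by chromosome, numerical before structural).  ``parse(render(m)) == m``."""
    lo, hi = model.count_range
    head = str(lo) if lo == hi else f"{lo}∼{hi}"
    parts = [head]
    if model.ploidy != 2:
        parts.append(f"<{model.ploidy}n>")
    if model.sex:
        parts.append(model.sex)
    for e in model.events:
        tok = e.notation()
        if e.clone_freq is not None:
            tok += f"[{e.clone_freq}]"
        parts.append(tok)
    return ",".join(parts)


# ---------------------------------------------------------------------------
# synthetic corpus

def random_model(rng, cmap: CytobandMap | None = None,
                 max_events: int = 8) -> KaryotypeModel:
    """Generate a random valid karyotype model (for round-trip testing and
    the bundled corpus).  Draws numerical gains/losses, short-form and
    detailed-system derivatives, whole-arm translocations, rings and dups
    over the bundled cytoband map."""
    cmap = cmap or bundled_map()
    ploidy = int(rng.choice([2, 2, 3]))
    sex = str(rng.choice(["XX", "XY"]))
    autosomes = [str(i) for i in range(1, 23)]
    free = list(autosomes)
    rng.shuffle(free)
    events: list = []

    def _rand_band(chrom: str) -> str:
        bands = cmap.bands(chrom)
        b = bands[int(rng.integers(len(bands)))]
        return b.name

    def _rand_interval(chrom: str) -> BandInterval:
        b1, b2 = _rand_band(chrom), _rand_band(chrom)
        return BandInterval(chrom, b1, b2)

    n_ev = int(rng.integers(1, max_events + 1))
    for _ in range(n_ev):
        if len(free) < 2:
            break
        kind = rng.choice(["num", "short", "whole", "detail", "ring", "dup"])
        if kind == "num":
            c = free.pop()
            delta = -1 if (rng.random() < 0.5 and ploidy > 1) else +1
            events.append(NumericalEvent(c, delta))
            continue
        if kind == "short":
            a, b = free.pop(), free.pop()
            free.append(b)  # partner chromosome is not consumed
            ba, bb = _rand_band(a), _rand_band(b)
            events.append(_parse_structured(
                f"der({a})t({a};{b})({ba};{bb})", 0, cmap, False, None,
                f"der({a})t({a};{b})({ba};{bb})", []))
            continue
        if kind == "whole":
            a, b = free.pop(), free.pop()
            events.append(_parse_structured(
                f"der({a};{b})(p10;q10)", 0, cmap, False, None,
                f"der({a};{b})(p10;q10)", []))
            continue
        if kind == "detail":
            a = free.pop()
            partner = str(rng.choice(autosomes))
            b1 = _rand_band(partner)
            body = (f"{partner}qter->{partner}{b1}::"
                    f"{a}p10->{a}qter")
            tok = f"der({a})({body})"
            events.append(_parse_structured(tok, 0, cmap, False, None, tok, []))
            continue
        if kind == "ring":
            a = free.pop()
            pb = [b.name for b in cmap.bands(a) if b.arm == "p"][-1]
            qb = [b.name for b in cmap.bands(a) if b.arm == "q"][0]
            tok = f"r({a})(::{a}{pb}->{a}{qb}::)"
            events.append(_parse_structured(tok, 0, cmap, True, None,
                                            "+" + tok, []))
            continue
        if kind == "dup":
            a = free.pop()
            qb = _rand_band(a)
            if qb.startswith("p"):
                qb = [b.name for b in cmap.bands(a) if b.arm == "q"][0]
            tok = f"dup({a})({qb}qter)"
            events.append(_parse_structured(tok, 0, cmap, False, None, tok, []))
    count = ploidy * 23 + sum(
        e.delta if isinstance(e, NumericalEvent) else (1 if e.gained else 0)
        for e in events)
    return KaryotypeModel((count, count), ploidy, sex, events, cmap)
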
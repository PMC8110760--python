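"""Degenerate CYP motif scanning and chaining.

Cytochrome P450 proteins carry four short conserved motifs in a fixed order:
the I-helix ``[AG]G-x-[DE]T[TS]`` (proton delivery), the K-helix ``E-x-x-R``
(core salt bridge), the meander coil around ``FDPER``, and the heme loop
``F-x-x-G-x-R-x-C-x-G`` whose cysteine is the axial heme-thiolate ligand.
Real family members deviate from the consensus at the weakly conserved
positions, so matches are scored by how many *anchor* positions (the residues
that stay conserved across the superfamily) they satisfy, with a per-motif
minimum for a reportable hit and mandatory anchors (the K-helix E/R pair and
the heme cysteine) that may never fail.  CYP20-family proteins carry a
single-residue indel in the heme loop, which the scanner tolerates for that
motif only.

``chain_motifs`` selects at most one match per motif maximizing the summed
anchor score subject to canonical order and start-to-start spacing bounds; a
motif may be left absent rather than forcing a sub-threshold window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .formats import AMINO_ACIDS

MOTIF_ORDER = ("ihelix", "khelix", "meander", "heme")

PATTERN_SPECS = {
    "ihelix": "[AG]G-x-[DE]T[TS]",
    "khelix": "E-x-x-R",
    "meander": "FDPER",
    "heme": "F-x-x-G-x-R-x-C-x-G",
}

#: 1-based indices of anchor positions (scored) per motif
ANCHORS = {
    "ihelix": (1, 2, 4, 5, 6),
    "khelix": (1, 4),
    "meander": (1, 3, 5),
    "heme": (1, 4, 6, 8, 10),
}

#: anchors that must match for any reportable hit
MANDATORY = {
    "ihelix": (),
    "khelix": (1, 4),
    "meander": (),
    "heme": (8,),
}

#: minimum matched-anchor count for a reportable hit
MIN_ANCHOR_SCORE = {"ihelix": 3, "khelix": 2, "meander": 2, "heme": 4}

#: start-to-start spacing bounds for canonically adjacent motif pairs,
#: an envelope of the spacings observed in curated CYPomes plus a margin
SPACING_BOUNDS = {
    ("ihelix", "khelix"): (38, 75),
    ("khelix", "meander"): (40, 65),
    ("meander", "heme"): (18, 35),
}


class PatternError(ValueError):
    """Raised for malformed motif pattern text."""


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate motif: per-position residue sets plus anchors.

    ``positions[i] is None`` means wildcard.  Anchor indices are 1-based.
    """

    name: str
    positions: tuple[frozenset[str] | None, ...]
    anchors: tuple[int, ...]
    mandatory_anchors: tuple[int, ...] = ()

    def __post_init__(self):
        if not set(self.mandatory_anchors) <= set(self.anchors):
            raise PatternError(f"{self.name}: mandatory anchors not a subset of anchors")
        if not set(self.anchors) <= set(range(1, len(self.positions) + 1)):
            raise PatternError(f"{self.name}: anchor index out of range")

    @property
    def length(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotifMatch:
    motif: str
    start: int  # 1-based
    matched: str  # '-' marks a tolerated deletion
    anchor_score: int
    strict: bool
    indel_variant: bool = False


@dataclass
class MotifChain:
    """Best consistent set of motif matches for one sequence."""

    matches: dict[str, MotifMatch | None]
    total_score: int
    ordered: bool = True

    def present(self) -> list[str]:
        return [m for m in MOTIF_ORDER if self.matches.get(m) is not None]

    def start(self, motif: str) -> int | None:
        m = self.matches.get(motif)
        return m.start if m else None


def compile_pattern(spec: str, *, name: str = "", anchors=(),
                    mandatory_anchors=()) -> MotifPattern:
    """Compile pattern text like ``[AG]G-x-[DE]T[TS]`` into a MotifPattern.

    Elements are bracketed residue sets, single residues, or ``x`` wildcards;
    '-' separators are optional.
    """
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(spec):
        ch = spec[i]
        if ch == "-":
            i += 1
        elif ch == "[":
            j = spec.find("]", i)
            if j < 0:
                raise PatternError(f"unclosed '[' at offset {i}")
            group = spec[i + 1:j]
            if not group or not set(group) <= set(AMINO_ACIDS):
                raise PatternError(f"bad residue set {group!r} at offset {i}")
            positions.append(frozenset(group))
            i = j + 1
        elif ch == "x":
            positions.append(None)
            i += 1
        elif ch in AMINO_ACIDS:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise PatternError(f"unknown character {ch!r} at offset {i}")
    if not positions:
        raise PatternError("empty pattern")
    if not anchors:
        anchors = tuple(i + 1 for i, p in enumerate(positions) if p is not None)
    return MotifPattern(name=name or spec, positions=tuple(positions),
                        anchors=tuple(anchors),
                        mandatory_anchors=tuple(mandatory_anchors))


def canonical_patterns() -> dict[str, MotifPattern]:
    return {
        name: compile_pattern(PATTERN_SPECS[name], name=name,
                              anchors=ANCHORS[name],
                              mandatory_anchors=MANDATORY[name])
        for name in MOTIF_ORDER
    }


@dataclass
class MotifConfig:
    """Tunables for scanning and chaining (defaults per the canonical motifs)."""

    patterns: dict[str, MotifPattern] = field(default_factory=canonical_patterns)
    min_anchor_score: dict[str, int] = field(
        default_factory=lambda: dict(MIN_ANCHOR_SCORE))
    spacing_bounds: dict[tuple[str, str], tuple[int, int]] = field(
        default_factory=lambda: dict(SPACING_BOUNDS))
    allow_single_indel: bool = True  # heme loop only

    def composed_bounds(self, a: str, b: str) -> tuple[int, int]:
        """Start-to-start bounds between motifs a and b (canonical order),
        summing the per-step bounds across any skipped intermediate motifs."""
        ia, ib = MOTIF_ORDER.index(a), MOTIF_ORDER.index(b)
        lo = hi = 0
        for k in range(ia, ib):
            slo, shi = self.spacing_bounds[(MOTIF_ORDER[k], MOTIF_ORDER[k + 1])]
            lo += slo
            hi += shi
        return lo, hi


def _residue_matches(res: str, allowed: frozenset[str] | None) -> bool:
    if res == "-":
        return False
    if allowed is None:  # wildcard: anything except a gap; X allowed here only
        return True
    return res in allowed  # X never satisfies a literal set


def score_window(pattern: MotifPattern, window: str,
                 min_score: int | None = None) -> MotifMatch | None:
    """Score one window of exactly ``pattern.length`` residues.

    Returns no-match if any mandatory anchor fails or the anchor score falls
    below ``min_score`` (defaults to the canonical per-motif minimum).
    """
    if len(window) != pattern.length:
        raise ValueError(
            f"window length {len(window)} != pattern length {pattern.length}")
    if min_score is None:
        min_score = MIN_ANCHOR_SCORE.get(pattern.name, 1)
    score = 0
    strict = True
    for i, allowed in enumerate(pattern.positions):
        ok = _residue_matches(window[i], allowed)
        if not ok:
            strict = False
        if (i + 1) in pattern.anchors:
            if ok:
                score += 1
            elif (i + 1) in pattern.mandatory_anchors:
                return None
    if score < min_score:
        return None
    return MotifMatch(motif=pattern.name, start=1, matched=window,
                      anchor_score=score, strict=strict)


def _score_variant(pattern: MotifPattern, effective: str) -> tuple[int, bool] | None:
    """Anchor score of a gapped/shrunk effective window; None if mandatory fails."""
    score = 0
    for i, allowed in enumerate(pattern.positions):
        ok = _residue_matches(effective[i], allowed)
        if (i + 1) in pattern.anchors:
            if ok:
                score += 1
            elif (i + 1) in pattern.mandatory_anchors:
                return None
    return score, False


def _best_deletion(pattern: MotifPattern, window: str) -> tuple[int, str] | None:
    """Best single-gap placement for a window one residue short."""
    best = None
    for g in range(pattern.length):
        effective = window[:g] + "-" + window[g:]
        res = _score_variant(pattern, effective)
        if res is not None and (best is None or res[0] > best[0]):
            best = (res[0], effective)
    return best


def _best_insertion(pattern: MotifPattern, window: str) -> tuple[int, str] | None:
    """Best single-residue drop for a window one residue long."""
    best = None
    for d in range(len(window)):
        effective = window[:d] + window[d + 1:]
        res = _score_variant(pattern, effective)
        if res is not None and (best is None or res[0] > best[0]):
            best = (res[0], window)  # report the full matched substring
    return best


def scan(sequence: str, pattern: MotifPattern, *,
         allow_single_indel: bool = False,
         min_score: int | None = None) -> list[MotifMatch]:
    """All reportable matches of ``pattern`` in ``sequence`` (1-based starts).

    With ``allow_single_indel`` (heme loop only), windows one residue shorter
    or longer are additionally evaluated under the best single gap placement
    and flagged ``indel_variant``; a same-start exact-length match wins.
    """
    if min_score is None:
        min_score = MIN_ANCHOR_SCORE.get(pattern.name, 1)
    L = pattern.length
    out: list[MotifMatch] = []
    starts: set[int] = set()
    n = len(sequence)
    for s in range(n - L + 1):
        m = score_window(pattern, sequence[s:s + L], min_score)
        if m is not None:
            out.append(MotifMatch(pattern.name, s + 1, m.matched,
                                  m.anchor_score, m.strict))
            starts.add(s + 1)
    if allow_single_indel and pattern.name == "heme":
        exact_score = {m.start: m.anchor_score for m in out}
        for s in range(n - (L - 1) + 1):
            if s + 1 in starts:
                continue
            variants = []
            if s + L - 1 <= n:
                d = _best_deletion(pattern, sequence[s:s + L - 1])
                if d is not None and d[0] >= min_score:
                    variants.append(d)
            if s + L + 1 <= n:
                ins = _best_insertion(pattern, sequence[s:s + L + 1])
                if ins is not None and ins[0] >= min_score:
                    variants.append(ins)
            if not variants:
                continue
            score, matched = max(variants, key=lambda v: (v[0], -len(v[1])))
            # an adjacent exact-length match scoring at least as well makes
            # this variant a shifted re-reading of the same site, not a hit
            if any(exact_score.get(s + 1 + d, -1) >= score for d in (-1, 0, 1)):
                continue
            out.append(MotifMatch(pattern.name, s + 1, matched, score,
                                  strict=False, indel_variant=True))
        out.sort(key=lambda m: m.start)
    return out


_ABSENT = math.inf


def chain_motifs(sequence: str, config: MotifConfig | None = None) -> MotifChain:
    """Best-scoring ordered chain of at most one match per motif.

    Maximizes total anchor score subject to canonical motif order and
    start-to-start spacing bounds (summed across skipped motifs); ties break
    to the leftmost I-helix start, then K-helix, etc., with absent treated as
    rightmost.  Deterministic for identical inputs.
    """
    if config is None:
        config = MotifConfig()
    candidates: dict[str, list[MotifMatch]] = {}
    for name in MOTIF_ORDER:
        pat = config.patterns[name]
        candidates[name] = scan(
            sequence, pat,
            allow_single_indel=config.allow_single_indel and name == "heme",
            min_score=config.min_anchor_score.get(name))

    # DP over motifs in canonical order; value = (score, tie_key, assignment)
    # where tie_key is the tuple of starts so far (absent = +inf) -- prefixes
    # compare lexicographically, so the optimum has optimal substructure.
    best_ending: dict[tuple[int, int], tuple[float, tuple, dict]] = {}
    overall: tuple[float, tuple, dict] = (0, (_ABSENT,) * 4, {})

    for j, name in enumerate(MOTIF_ORDER):
        for ci, cand in enumerate(candidates[name]):
            # option 1: chain starts here (all earlier motifs absent)
            key = tuple([_ABSENT] * j + [cand.start])
            state = (cand.anchor_score, key, {name: cand})
            # option 2: extend a chain ending at an earlier motif
            for i in range(j):
                prev_name = MOTIF_ORDER[i]
                lo, hi = config.composed_bounds(prev_name, name)
                for pi, prev in enumerate(candidates[prev_name]):
                    pstate = best_ending.get((i, pi))
                    if pstate is None:
                        continue
                    gap = cand.start - prev.start
                    if not (lo <= gap <= hi):
                        continue
                    score = pstate[0] + cand.anchor_score
                    key = pstate[1] + tuple([_ABSENT] * (j - i - 1) + [cand.start])
                    if (score, _neg(key)) > (state[0], _neg(state[1])):
                        state = (score, key, {**pstate[2], name: cand})
            best_ending[(j, ci)] = state
            full_key = state[1] + (_ABSENT,) * (4 - len(state[1]))
            if (state[0], _neg(full_key)) > (overall[0], _neg(overall[1])):
                overall = (state[0], full_key, state[2])

    score, _, assignment = overall
    matches = {name: assignment.get(name) for name in MOTIF_ORDER}
    return MotifChain(matches=matches, total_score=int(score), ordered=True)


def _neg(key: tuple) -> tuple:
    """Invert a start tuple so that max() prefers the lexicographically
    smallest (leftmost-first) key."""
    return tuple(-k for k in key)
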
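"""Seeded synthetic CYPomes with known truth.

The generator emulates the statistical structure the annotation pipeline
assumes: ~500-residue CYP-like proteins carrying the four conserved motifs at
realistic spacings, families at controlled pairwise identity, clan-structured
divergence (independent clan ancestors guarantee separability), and
truncation-derived partials and fragments.  All randomness flows from a
single seed, so two runs with equal specs are bit-for-bit identical.

Planted motif instances keep their anchor residues fixed under mutation, and
every emitted sequence is scrubbed of *spurious* motif windows (background
windows that would qualify as matches) so that chain recovery — and hence
status recovery — is exact by construction.  Because anchor preservation
biases identity upward, achieved identities are measured, not assumed, and
reported alongside the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import AMINO_ACIDS, ProteinRecord
from .motif_engine import (MOTIF_ORDER, MotifConfig, _best_deletion,
                           _best_insertion, scan, score_window)

#: strict canonical instances used for planting
CANONICAL_INSTANCES = {
    "ihelix": "AGLDTT",
    "khelix": "EGLR",
    "meander": "FDPER",
    "heme": "FSAGPRNCIG",
}

#: residues that satisfy no anchor set of any canonical motif; used when
#: disrupting spurious windows so fixes rarely seed new ones
_QUIET = "HIKLMNQVWY"

#: clan labels handed to generated references, echoing the metazoan clans
CLAN_LABELS = ("clan 2", "clan 3", "clan 4", "mitochondrial", "clan 7",
               "clan 19", "clan 20", "clan 26", "clan 46", "clan 51",
               "clan 16", "clan 74")


@dataclass
class SyntheticSpec:
    n_clans: int = 4
    families_per_clan: int = 3
    genes_per_family: int = 4
    target_within_family_identity: float = 65.0
    target_between_family_identity: float = 25.0
    partial_fraction: float = 0.15
    fragment_fraction: float = 0.15
    decoy_count: int = 10
    length_mean: int = 500
    seed: int = 0

    def __post_init__(self):
        for frac in (self.partial_fraction, self.fragment_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")
        if self.length_mean < 200:
            raise ValueError("length_mean must be >= 200")
        if self.target_within_family_identity <= self.target_between_family_identity:
            raise ValueError("within-family identity target must exceed "
                             "between-family target")
        if self.n_clans > len(CLAN_LABELS):
            raise ValueError(f"at most {len(CLAN_LABELS)} clans supported")


@dataclass
class TruthRecord:
    id: str
    clan: str
    family: str
    subfamily: str
    status: str
    motif_positions: dict[str, int | None]


@dataclass
class SyntheticCypome:
    records: list[ProteinRecord]
    references: list[ProteinRecord]
    reference_clans: dict[str, str]
    outgroup_id: str
    truth: list[TruthRecord]
    aligned: list[ProteinRecord]  # complete+partial queries, refs, outgroup
    achieved: pd.DataFrame

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = {"id": t.id, "clan": t.clan, "family": t.family,
                   "subfamily": t.subfamily, "status": t.status}
            for m in MOTIF_ORDER:
                row[f"{m}_pos"] = t.motif_positions.get(m) or ""
            rows.append(row)
        return pd.DataFrame(rows)


def random_background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _anchor_positions(truth_positions: dict[str, int | None],
                      config: MotifConfig) -> set[int]:
    """0-based sequence indices of anchor residues of the planted motifs."""
    out: set[int] = set()
    for motif, start in truth_positions.items():
        if start is None:
            continue
        for a in config.patterns[motif].anchors:
            out.add(start - 1 + a - 1)
    return out


def _planted_spans(truth_positions: dict[str, int | None],
                   strings: dict[str, str], ) -> set[int]:
    out: set[int] = set()
    for motif, start in truth_positions.items():
        if start is None:
            continue
        for k in range(len(strings[motif])):
            out.add(start - 1 + k)
    return out


def _qualifies_at(chars: list[str], pattern, start: int, min_score: int,
                  allow_indel: bool) -> bool:
    """Does any reportable match of ``pattern`` (incl. indel variants) still
    begin at 1-based ``start``?"""
    s = start - 1
    L = pattern.length
    seg = "".join(chars[s:s + L + 1])
    if len(seg) >= L and score_window(pattern, seg[:L], min_score) is not None:
        return True
    if allow_indel and pattern.name == "heme":
        if len(seg) >= L - 1:
            d = _best_deletion(pattern, seg[:L - 1])
            if d is not None and d[0] >= min_score:
                return True
        if len(seg) >= L + 1:
            ins = _best_insertion(pattern, seg[:L + 1])
            if ins is not None and ins[0] >= min_score:
                return True
    return False


def disrupt_spurious(seq: str, allowed_starts: dict[str, set[int]],
                     protected: set[int], rng: np.random.Generator,
                     config: MotifConfig | None = None,
                     max_rounds: int = 60) -> str:
    """Mutate background residues until no motif window outside
    ``allowed_starts`` qualifies as a reportable match.

    Each disruption is verified to actually kill its window (mutate a span
    position to a quiet residue, re-score, revert if the match survives).
    Windows whose disruptable positions are all protected (e.g. shifted
    re-readings living entirely inside a planted motif) are left alone —
    they are part of the planted signal.  Deterministic for a given rng
    state.
    """
    if config is None:
        config = MotifConfig()
    chars = list(seq)
    unfixable: set[tuple[str, int]] = set()
    for _ in range(max_rounds):
        pending = []
        for motif in MOTIF_ORDER:
            pattern = config.patterns[motif]
            allow_indel = config.allow_single_indel and motif == "heme"
            min_score = config.min_anchor_score.get(motif, 1)
            for m in scan("".join(chars), pattern,
                          allow_single_indel=allow_indel,
                          min_score=min_score):
                if (m.start in allowed_starts.get(motif, set())
                        or (motif, m.start) in unfixable):
                    continue
                pending.append((pattern, m, min_score, allow_indel))
        if not pending:
            return "".join(chars)
        for pattern, m, min_score, allow_indel in pending:
            consumed = len(m.matched.replace("-", ""))
            span = [m.start - 1 + k for k in range(consumed)]
            candidates = [p for p in span if p not in protected]
            # anchor offsets first: only they can lower the score
            candidates.sort(
                key=lambda p: (p - (m.start - 1) + 1) not in pattern.anchors)
            # quiet residues satisfy no anchor set, so cumulative mutations
            # along the span can only lower the window's score
            killed = False
            for pos in candidates:
                chars[pos] = str(rng.choice(list(_QUIET)))
                if not _qualifies_at(chars, pattern, m.start, min_score,
                                     allow_indel):
                    killed = True
                    break
            if not killed:
                unfixable.add((pattern.name, m.start))
    raise RuntimeError("could not scrub spurious motif windows")


def plant_motifs(background: str, placements: dict[str, tuple[int, str]],
                 ) -> str:
    """Overwrite ``background`` with motif strings at 1-based positions.

    Placement strings may contain '-' (a deletion relative to the consensus);
    gap characters are not written — the remaining residues are planted
    contiguously.
    """
    chars = list(background)
    for motif, (start, s) in placements.items():
        s = s.replace("-", "")
        if start < 1 or start - 1 + len(s) > len(chars):
            raise ValueError(f"{motif} placement at {start} exceeds sequence")
        chars[start - 1:start - 1 + len(s)] = list(s)
    return "".join(chars)


def plan_placements(positions: dict[str, int | None],
                    strings: dict[str, str | None],
                    ) -> dict[str, tuple[int, str]]:
    """Keep placements that respect canonical order and do not overlap an
    earlier-planted motif; drop the rest (handles survey rows whose printed
    coordinates collide, a known printing artifact)."""
    placements: dict[str, tuple[int, str]] = {}
    prev_end = -1
    for motif in MOTIF_ORDER:
        pos, s = positions.get(motif), strings.get(motif)
        if pos is None or s is None:
            continue
        start0 = pos - 1
        if start0 <= prev_end:
            continue
        placements[motif] = (pos, s)
        prev_end = start0 + len(s.replace("-", "")) - 1
    return placements


def plant_fixture_row(length: int, positions: dict[str, int | None],
                      strings: dict[str, str | None],
                      rng: np.random.Generator,
                      config: MotifConfig | None = None,
                      ) -> tuple[str, dict[str, tuple[int, str]]]:
    """Seeded random background of ``length`` with the given motif strings
    planted at their stated positions, scrubbed of competing windows.

    Returns (sequence, placements actually planted).
    """
    if config is None:
        config = MotifConfig()
    placements = plan_placements(positions, strings)
    background = random_background(rng, length)
    seq = plant_motifs(background, placements)
    protected = set()
    for motif, (pos, s) in placements.items():
        protected |= {pos - 1 + k for k in range(len(s.replace("-", "")))}
    allowed = {m: {p[0]} for m, p in placements.items()}
    seq = disrupt_spurious(seq, allowed, protected, rng, config)
    return seq, placements


# ---------------------------------------------------------------------------
# Generator
# ---------------------------------------------------------------------------

def make_ancestor(rng: np.random.Generator, length: int,
                  config: MotifConfig | None = None,
                  ) -> tuple[str, dict[str, int]]:
    """Random CYP-like ancestor: leading M, strict canonical motifs planted
    at spacings drawn uniformly from the configured bounds, background
    scrubbed of competing windows.  Returns (residues, truth positions)."""
    if config is None:
        config = MotifConfig()
    gaps = [int(rng.integers(lo, hi + 1))
            for lo, hi in (config.spacing_bounds[("ihelix", "khelix")],
                           config.spacing_bounds[("khelix", "meander")],
                           config.spacing_bounds[("meander", "heme")])]
    span = sum(gaps) + len(CANONICAL_INSTANCES["heme"])
    tail = 3
    latest = length - span - tail
    if latest < 2:
        raise ValueError(f"length {length} below minimal motif span {span + tail + 2}")
    target = int(0.6 * length)
    ihelix = min(max(2, target - span // 2), latest) + 1  # 1-based
    positions = {"ihelix": ihelix,
                 "khelix": ihelix + gaps[0],
                 "meander": ihelix + gaps[0] + gaps[1],
                 "heme": ihelix + gaps[0] + gaps[1] + gaps[2]}
    background = "M" + random_background(rng, length - 1)
    seq = plant_motifs(background,
                       {m: (p, CANONICAL_INSTANCES[m])
                        for m, p in positions.items()})
    protected = _planted_spans(positions, CANONICAL_INSTANCES) | {0}
    seq = disrupt_spurious(seq, {m: {p} for m, p in positions.items()},
                           protected, rng, config)
    return seq, positions


def mutate_preserving_anchors(seq: str, substitution_rate: float,
                              rng: np.random.Generator,
                              truth_positions: dict[str, int | None],
                              config: MotifConfig | None = None) -> str:
    """Independent substitutions at the given rate to a uniformly random
    *different* residue; motif anchor positions and the terminal residues are
    untouched."""
    if not 0 <= substitution_rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if config is None:
        config = MotifConfig()
    protected = _anchor_positions(truth_positions, config) | {0, len(seq) - 1}
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < substitution_rate)[0]
    for i in hits:
        if int(i) in protected:
            continue
        alternatives = [a for a in AMINO_ACIDS if a != chars[i]]
        chars[i] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(chars)


def degrade(seq: str, mode: str, rng: np.random.Generator,
            truth_positions: dict[str, int],
            ) -> tuple[str, dict[str, int | None], str, int]:
    """Truncate a complete synthetic gene into a partial or fragment.

    partial: removes the N- or C-terminus outside the motif-spanning core
    (start Met or stop evidence lost, motifs intact).  fragment: truncation
    removes at least one mandatory motif.  Returns (residues, updated truth
    positions, expected status, leading offset removed).
    """
    heme_end = truth_positions["heme"] + 9  # 1-based inclusive
    first_motif = min(p for p in truth_positions.values() if p)
    if mode == "partial":
        if rng.random() < 0.5 and first_motif > 30:
            k = int(rng.integers(10, first_motif - 10))
            while seq[k] == "M":  # keep inferred has_start = no
                k += 1
            new = seq[k:]
            pos = {m: p - k for m, p in truth_positions.items()}
            return new, pos, "partial", k
        tail = int(rng.integers(2, 10))
        new = seq[:heme_end + tail]
        return new, dict(truth_positions), "partial", 0
    if mode == "fragment":
        if rng.random() < 0.5:
            # drop the heme loop and everything after it
            new = seq[:truth_positions["heme"] - 1]
            pos: dict[str, int | None] = dict(truth_positions)
            pos["heme"] = None
            return new, pos, "fragment", 0
        # drop the N-terminus through the K-helix
        cut = truth_positions["khelix"] + 3  # past the K-helix end
        while seq[cut] == "M":
            cut += 1
        new = seq[cut:]
        pos = {"ihelix": None, "khelix": None,
               "meander": truth_positions["meander"] - cut,
               "heme": truth_positions["heme"] - cut}
        return new, pos, "fragment", cut
    raise ValueError(f"unknown degrade mode {mode!r}")


def _rate_for_identity(target_percent: float) -> float:
    """Substitution rate per lineage so two independently mutated copies of a
    common ancestor land near the target identity (each differing site
    matches by chance with probability 1/20)."""
    t = target_percent / 100.0
    q2 = (t - 0.05) / 0.95
    q = float(np.sqrt(max(q2, 1e-6)))
    return min(0.95, (1.0 - q) / 0.95)


def _hamming_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    same = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return 100.0 * same / n


def generate_cypome(spec: SyntheticSpec,
                    config: MotifConfig | None = None) -> SyntheticCypome:
    """Generate a full synthetic CYPome with truth.

    Clans descend from independent ancestors (guaranteed separability),
    families within a clan from strongly diverged founder copies, genes
    within a family from lightly diverged copies; statuses are applied per
    the configured fractions and decoys are motif-free random sequences.
    """
    if config is None:
        config = MotifConfig()
    rng = np.random.default_rng(spec.seed)
    L = spec.length_mean
    r_family = _rate_for_identity(spec.target_between_family_identity)
    r_gene = _rate_for_identity(spec.target_within_family_identity)

    references: list[ProteinRecord] = []
    reference_clans: dict[str, str] = {}
    genes: list[tuple[str, str, str, str, dict[str, int]]] = []
    # (id, clan, family, residues, truth positions)
    for c in range(spec.n_clans):
        clan = CLAN_LABELS[c]
        anc, anc_pos = make_ancestor(rng, L, config)
        ref_id = f"REF_clan{c + 1}"
        references.append(ProteinRecord(id=ref_id, residues=anc,
                                        species="reference",
                                        has_start="yes", has_stop="yes"))
        reference_clans[ref_id] = clan
        for f in range(spec.families_per_clan):
            founder = mutate_preserving_anchors(anc, r_family, rng, anc_pos,
                                                config)
            family = f"fam_c{c + 1}_{f + 1}"
            for g in range(spec.genes_per_family):
                gene = mutate_preserving_anchors(founder, r_gene, rng,
                                                 anc_pos, config)
                gid = f"syn_c{c + 1}f{f + 1}g{g + 1}"
                genes.append((gid, clan, family, gene, dict(anc_pos)))

    # scrub every gene of windows that could compete with its planted motifs
    scrubbed = []
    for gid, clan, family, gene, pos in genes:
        protected = _anchor_positions(pos, config) | {0, len(gene) - 1}
        gene = disrupt_spurious(gene, {m: {p} for m, p in pos.items()},
                                protected, rng, config)
        scrubbed.append((gid, clan, family, gene, pos))
    genes = scrubbed

    # status assignment
    n = len(genes)
    n_partial = int(round(spec.partial_fraction * n))
    n_fragment = int(round(spec.fragment_fraction * n))
    order = rng.permutation(n)
    status_of = {}
    for idx in order[:n_partial]:
        status_of[idx] = "partial"
    for idx in order[n_partial:n_partial + n_fragment]:
        status_of[idx] = "fragment"

    records: list[ProteinRecord] = []
    aligned: list[ProteinRecord] = []
    truth: list[TruthRecord] = []
    for idx, (gid, clan, family, gene, pos) in enumerate(genes):
        status = status_of.get(idx, "complete")
        if status == "complete":
            residues, tpos, offset = gene, dict(pos), 0
            rec = ProteinRecord(id=gid, residues=residues, species="synthetic",
                                has_start="yes", has_stop="yes")
        else:
            residues, tpos, status, offset = degrade(gene, status, rng, pos)
            has_start = "yes" if residues.startswith("M") else "no"
            has_stop = "yes" if len(residues) + offset == len(gene) else "no"
            rec = ProteinRecord(id=gid, residues=residues, species="synthetic",
                                has_start=has_start, has_stop=has_stop)
        records.append(rec)
        truth.append(TruthRecord(id=gid, clan=clan, family=family,
                                 subfamily="A", status=status,
                                 motif_positions=tpos))
        if status in ("complete", "partial"):
            row = "-" * offset + residues
            row = row + "-" * (L - len(row))
            aligned.append(ProteinRecord(id=gid, residues=row,
                                         species="synthetic",
                                         has_start=rec.has_start,
                                         has_stop=rec.has_stop))

    # decoys: motif-free random sequences
    for d in range(spec.decoy_count):
        length = int(rng.integers(250, 551))
        seq = disrupt_spurious(random_background(rng, length), {}, set(), rng,
                               config)
        did = f"decoy_{d + 1}"
        records.append(ProteinRecord(id=did, residues=seq, species="synthetic"))
        truth.append(TruthRecord(id=did, clan="", family="", subfamily="",
                                 status="non_cyp", motif_positions={}))

    out_seq, _ = make_ancestor(rng, L, config)
    outgroup = ProteinRecord(id="REF_outgroup", residues=out_seq,
                             species="reference", has_start="yes",
                             has_stop="yes")
    references.append(outgroup)
    for ref in references:
        aligned.append(ProteinRecord(id=ref.id, residues=ref.residues,
                                     species="reference",
                                     has_start="yes", has_stop="yes"))

    achieved = _achieved_stats(genes)
    return SyntheticCypome(records=records, references=references,
                           reference_clans=reference_clans,
                           outgroup_id=outgroup.id, truth=truth,
                           aligned=aligned, achieved=achieved)


def _achieved_stats(genes) -> pd.DataFrame:
    within, between_fam, between_clan = [], [], []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            _, ci, fi, si, _ = genes[i]
            _, cj, fj, sj, _ = genes[j]
            pid = _hamming_identity(si, sj)
            if fi == fj:
                within.append(pid)
            elif ci == cj:
                between_fam.append(pid)
            else:
                between_clan.append(pid)
    rows = [
        {"pair_class": "within_family", "n_pairs": len(within),
         "mean_identity": float(np.mean(within)) if within else float("nan")},
        {"pair_class": "between_family_within_clan", "n_pairs": len(between_fam),
         "mean_identity": float(np.mean(between_fam)) if between_fam else float("nan")},
        {"pair_class": "between_clan", "n_pairs": len(between_clan),
         "mean_identity": float(np.mean(between_clan)) if between_clan else float("nan")},
    ]
    return pd.DataFrame(rows)
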
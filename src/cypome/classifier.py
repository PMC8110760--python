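"""Curation-status classification of candidate CYP sequences.

Statuses follow genome-annotation practice for the superfamily:

* ``complete`` — full length (roughly 500 residues), start and stop evidence,
  and all mandatory motifs present in order.
* ``partial`` — all mandatory motifs present and ordered, but at least one
  completeness condition (length window, start, stop, optional HMM evidence)
  fails; such genes are presumed functional but unresolved in the assembly.
* ``fragment`` — at least one motif detected but not all mandatory ones
  (or the motifs are disordered).
* ``non_cyp`` — no motif at all.

The I-helix is not mandatory by default: the CYP20 family carries a
degenerate I-helix yet is a bona fide CYP lineage across metazoans.
External HMM-match evidence is ingested as a boolean flag, never computed;
an explicit ``hmm_match=False`` fails the completeness check (a complete call
requires an HMM match), and absent evidence changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats import ProteinRecord
from .motif_engine import MOTIF_ORDER, MotifChain, MotifConfig, chain_motifs

STATUSES = ("complete", "partial", "fragment", "non_cyp")


@dataclass
class ClassifierConfig:
    full_length_min: int = 440
    full_length_max: int = 650
    mandatory_motifs: frozenset[str] = frozenset({"khelix", "meander", "heme"})
    min_motifs_for_fragment: int = 1
    core_region_min: int = 120
    motif_config: MotifConfig = field(default_factory=MotifConfig)

    def __post_init__(self):
        if self.full_length_min >= self.full_length_max:
            raise ValueError("full_length_min must be < full_length_max")
        if not set(self.mandatory_motifs) <= set(MOTIF_ORDER):
            raise ValueError(f"mandatory_motifs must be within {MOTIF_ORDER}")


@dataclass
class ClassifiedSequence:
    record: ProteinRecord
    chain: MotifChain
    status: str
    reasons: list[str] = field(default_factory=list)


def classify_sequence(record: ProteinRecord,
                      config: ClassifierConfig | None = None,
                      chain: MotifChain | None = None) -> ClassifiedSequence:
    """Assign a curation status, evaluating complete → partial → fragment →
    non_cyp.  ``reasons`` lists every failed completeness condition for
    partials and every missing mandatory motif for fragments."""
    if config is None:
        config = ClassifierConfig()
    if chain is None:
        chain = chain_motifs(record.ungapped, config.motif_config)

    present = set(chain.present())
    missing_mandatory = sorted(config.mandatory_motifs - present,
                               key=MOTIF_ORDER.index)

    if not present:
        return ClassifiedSequence(record, chain, "non_cyp", ["no_motifs"])

    if missing_mandatory or not chain.ordered:
        reasons = [f"missing_{m}" for m in missing_mandatory]
        if not chain.ordered:
            reasons.append("disordered_motifs")
        if len(present) < config.min_motifs_for_fragment:
            return ClassifiedSequence(record, chain, "non_cyp", reasons)
        return ClassifiedSequence(record, chain, "fragment", reasons)

    # all mandatory motifs present & ordered: complete unless a completeness
    # condition fails (unknown start/stop evidence counts as failed --
    # conservative: partial, not complete)
    reasons: list[str] = []
    n = len(record.ungapped)
    if n < config.full_length_min:
        reasons.append("short_length")
    elif n > config.full_length_max:
        reasons.append("long_length")
    if record.has_start != "yes":
        reasons.append("missing_start")
    if record.has_stop != "yes":
        reasons.append("missing_stop")
    if record.evidence.get("hmm_match") is False:
        reasons.append("no_hmm_match")

    status = "complete" if not reasons else "partial"
    return ClassifiedSequence(record, chain, status, reasons)


def classify_set(records: list[ProteinRecord],
                 config: ClassifierConfig | None = None,
                 evidence: dict[str, dict[str, bool]] | None = None,
                 ) -> tuple[dict[str, int], list[ClassifiedSequence]]:
    """Classify a collection; returns (tallies per status, per-record results
    in input order).  ``evidence`` optionally merges external flags
    (e.g. ``{"gene1": {"hmm_match": True}}``) into each record."""
    if config is None:
        config = ClassifierConfig()
    seen: set[str] = set()
    results: list[ClassifiedSequence] = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r}")
        seen.add(rec.id)
        if evidence and rec.id in evidence:
            rec.evidence.update(evidence[rec.id])
        results.append(classify_sequence(rec, config))
    tallies = {s: 0 for s in STATUSES}
    for r in results:
        tallies[r.status] += 1
    return tallies, results
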
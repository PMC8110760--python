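"""CYPome composition summaries and tabular report writers.

A species' CYPome is summarized as: counts per curation status, clan counts
and proportions over the complete + partial (presumed functional) genes, a
three-state clan presence call (present in complete/partial genes, fragment
evidence only, or absent), and the minimum functional gene count
(complete + partial).  Clans 16, 20 and 46 plus unplaced genes are pooled as
"Other" in proportions but broken out individually in presence states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .classifier import STATUSES, ClassifiedSequence
from .formats import MOTIF_NAMES
from .nomenclature import FamilyAssignment
from .phylo_clan import ClanAssignment

#: clans reported individually in proportions; everything else pools as Other
MAJOR_CLANS = ("clan 2", "clan 3", "clan 4", "mitochondrial")

#: the twelve metazoan clans tracked in presence/absence reporting
METAZOAN_CLANS = ("clan 2", "clan 3", "clan 4", "clan 7", "clan 16",
                  "clan 19", "clan 20", "clan 26", "clan 46", "clan 51",
                  "clan 74", "mitochondrial")

PRESENT, FRAGMENT_ONLY, ABSENT = "present_in_genes", "fragment_only", "absent"


@dataclass
class CypomeSummary:
    species: str
    counts: dict[str, int] = field(default_factory=dict)
    clan_counts: dict[str, int] = field(default_factory=dict)
    clan_proportions: dict[str, float] = field(default_factory=dict)
    presence: dict[str, str] = field(default_factory=dict)

    @property
    def minimum_functional(self) -> int:
        return self.counts.get("complete", 0) + self.counts.get("partial", 0)


def _proportion_bucket(clan: str) -> str:
    return clan if clan in MAJOR_CLANS else "Other"


def summarize(classified: list[ClassifiedSequence],
              clans: list[ClanAssignment] | None = None,
              species_of: dict[str, str] | None = None,
              ) -> dict[str, CypomeSummary]:
    """Per-species composition summaries.

    ``species_of`` overrides each record's own species tag; every classified
    id must resolve to a species.  Clan assignments must cover the complete
    and partial genes (fragment assignments are optional and feed only the
    presence matrix).
    """
    clan_of = {c.id: c.clan for c in (clans or [])}
    by_species: dict[str, list[ClassifiedSequence]] = {}
    for cs in classified:
        sp = (species_of or {}).get(cs.record.id) or cs.record.species
        if not sp and "_" in cs.record.id:
            sp = cs.record.id.split("_", 1)[0]  # prefix fallback
        if not sp:
            raise ValueError(f"{cs.record.id}: no species tag")
        by_species.setdefault(sp, []).append(cs)

    out: dict[str, CypomeSummary] = {}
    for sp, members in by_species.items():
        counts = {s: 0 for s in STATUSES}
        clan_counts: dict[str, int] = {}
        fragment_clans: set[str] = set()
        for cs in members:
            counts[cs.status] += 1
            clan = clan_of.get(cs.record.id)
            if clan is None:
                continue
            if cs.status in ("complete", "partial"):
                clan_counts[clan] = clan_counts.get(clan, 0) + 1
            elif cs.status == "fragment":
                fragment_clans.add(clan)
        total = sum(clan_counts.values())
        proportions: dict[str, float] = {}
        for clan, k in clan_counts.items():
            bucket = _proportion_bucket(clan)
            proportions[bucket] = proportions.get(bucket, 0.0) + k / total if total else 0.0
        presence: dict[str, str] = {}
        seen_clans = set(clan_counts) | fragment_clans | set(METAZOAN_CLANS)
        for clan in sorted(seen_clans):
            if clan_counts.get(clan, 0) > 0:
                presence[clan] = PRESENT
            elif clan in fragment_clans:
                presence[clan] = FRAGMENT_ONLY
            else:
                presence[clan] = ABSENT
        out[sp] = CypomeSummary(species=sp, counts=counts,
                                clan_counts=clan_counts,
                                clan_proportions=proportions,
                                presence=presence)
    return out


def summarize_counts(counts_table: pd.DataFrame) -> dict[str, CypomeSummary]:
    """Summaries from a per-species status-count table (columns complete /
    partial / fragment), e.g. published curation tallies."""
    out = {}
    for sp, row in counts_table.iterrows():
        counts = {s: int(row.get(s, 0)) for s in STATUSES}
        out[sp] = CypomeSummary(species=str(sp), counts=counts)
    return out


def motif_table(classified: list[ClassifiedSequence]) -> pd.DataFrame:
    """Motif report shaped like the published survey tables: one row per
    gene, (position, matched string, strict flag) per motif, '–' where
    undetected; rows sorted by gene name."""
    rows = []
    for cs in sorted(classified, key=lambda c: c.record.id):
        row: dict[str, object] = {"gene_name": cs.record.id,
                                  "length": len(cs.record.ungapped)}
        for motif in MOTIF_NAMES:
            m = cs.chain.matches.get(motif)
            if m is None:
                row[f"{motif}_pos"] = "–"
                row[f"{motif}_str"] = "–"
                row[f"{motif}_strict"] = ""
            else:
                row[f"{motif}_pos"] = m.start
                row[f"{motif}_str"] = m.matched
                row[f"{motif}_strict"] = str(bool(m.strict)).lower()
        rows.append(row)
    cols = ["gene_name", "length"] + [f"{m}_{f}" for m in MOTIF_NAMES
                                      for f in ("pos", "str", "strict")]
    return pd.DataFrame(rows, columns=cols)


def classification_table(classified: list[ClassifiedSequence]) -> pd.DataFrame:
    rows = []
    for cs in classified:
        row = {"id": cs.record.id, "species": cs.record.species,
               "length": len(cs.record.ungapped), "status": cs.status,
               "reasons": ";".join(cs.reasons)}
        for motif in MOTIF_NAMES:
            m = cs.chain.matches.get(motif)
            row[f"{motif}_pos"] = m.start if m else "–"
        rows.append(row)
    return pd.DataFrame(rows)


def family_census(assignments: dict[str, FamilyAssignment],
                  species_of: dict[str, str]) -> pd.DataFrame:
    """family x species gene-count matrix with an exclusivity flag (family
    present in exactly one species)."""
    rows = [{"family": a.family, "species": species_of[a.id]}
            for a in assignments.values()]
    if not rows:
        return pd.DataFrame(columns=["exclusive_to"])
    df = pd.DataFrame(rows)
    census = df.groupby(["family", "species"]).size().unstack(fill_value=0)
    present = census > 0
    census["exclusive_to"] = [
        present.columns[present.loc[f]].tolist()[0] if present.loc[f].sum() == 1
        else "" for f in census.index]
    return census


def summary_frame(summaries: dict[str, CypomeSummary]) -> pd.DataFrame:
    rows = []
    for sp in sorted(summaries):
        s = summaries[sp]
        row = {"species": sp, **{f"n_{k}": v for k, v in s.counts.items()},
               "minimum_functional": s.minimum_functional}
        for clan, frac in sorted(s.clan_proportions.items()):
            row[f"prop_{clan}"] = round(frac, 6)
        rows.append(row)
    return pd.DataFrame(rows)
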
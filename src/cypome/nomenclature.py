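"""Percent-identity nomenclature: family (>40%) and subfamily (>55%) naming.

CYP names encode relatedness tiers: genes sharing greater than 40% amino-acid
identity belong to one family (a number), greater than 55% to one subfamily
(a letter), and each gene gets a number within its subfamily — CYP17A1 is the
first gene of subfamily A of family CYP17.  Both thresholds are strict
("greater than"): a pair at exactly 40.0% is *not* same-family.

Identity is computed over mutually aligned (both non-gap) columns of a global
Needleman–Wunsch alignment, with a separate coverage gate (aligned fraction
of the shorter sequence) so that short fragments cannot inflate identity.
Families and subfamilies are single-linkage components over reliable pairs;
queries anchor to the family of their highest-identity named reference when
one clears the threshold, and the remainder are minted as novel families
numbered from a configurable sentinel (official registry numbers are
committee-assigned and not computable).
"""

from __future__ import annotations

import re
import string
import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats import ProteinRecord


@dataclass
class NomenclatureConfig:
    family_threshold: float = 40.0
    subfamily_threshold: float = 55.0
    min_coverage: float = 0.5
    novel_family_start: int = 9001
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self):
        if self.family_threshold >= self.subfamily_threshold:
            raise ValueError("family_threshold must be < subfamily_threshold")


@dataclass
class FamilyAssignment:
    id: str
    family: str  # e.g. "CYP4" or "CYP9001"
    subfamily: str = ""
    gene_number: int = 0
    novel_family: bool = False
    anchor: str | None = None
    anchor_identity: float = 0.0

    @property
    def full_name(self) -> str:
        return f"{self.family}{self.subfamily}{self.gene_number or ''}"


def _aligner(config: NomenclatureConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(
        config.substitution_matrix)
    aligner.mode = "global"
    aligner.open_gap_score = -abs(config.gap_open)
    aligner.extend_gap_score = -abs(config.gap_extend)
    return aligner


def global_align(a: str, b: str,
                 config: NomenclatureConfig | None = None) -> tuple[str, str]:
    """Optimal global alignment of two residue strings -> two gapped strings.

    Tie-breaking is the aligner's deterministic first-reported path.
    """
    if config is None:
        config = NomenclatureConfig()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    aligner = _aligner(config)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    bad = (set(a) | set(b)) - alphabet
    if bad:
        raise ValueError(f"residues outside {config.substitution_matrix} "
                         f"alphabet: {sorted(bad)}")
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    return ga, gb


def percent_identity(alignment: tuple[str, str],
                     config: NomenclatureConfig | None = None,
                     ) -> tuple[float, float]:
    """(identity %, coverage) of a pairwise alignment.

    identity = 100 x identical pairs / mutually non-gap columns;
    coverage = mutually non-gap columns / min(raw lengths).
    An all-gap overlap reports (0, 0).
    """
    ga, gb = alignment
    if len(ga) != len(gb) or not ga:
        raise ValueError("alignment rows must be equal, non-zero length")
    both = same = 0
    for x, y in zip(ga, gb):
        if x != "-" and y != "-":
            both += 1
            if x == y:
                same += 1
    la = len(ga.replace("-", ""))
    lb = len(gb.replace("-", ""))
    if both == 0 or min(la, lb) == 0:
        return 0.0, 0.0
    return 100.0 * same / both, both / min(la, lb)


def identity_matrix(records: list[ProteinRecord],
                    config: NomenclatureConfig | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Symmetric (identity %, coverage) matrices over all record pairs.

    Entries with coverage below ``min_coverage`` are the caller's to gate;
    both raw matrices are returned along with the id order.
    """
    if config is None:
        config = NomenclatureConfig()
    if not records:
        raise ValueError("need at least one record")
    ids = [r.id for r in records]
    n = len(records)
    ident = np.full((n, n), 100.0)
    cov = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pid, c = percent_identity(
                global_align(records[i].ungapped, records[j].ungapped, config),
                config)
            ident[i, j] = ident[j, i] = pid
            cov[i, j] = cov[j, i] = c
    return ident, cov, ids


def _components(ids: list[str], linked) -> list[list[str]]:
    """Single-linkage connected components; each sorted, listed by smallest
    member id."""
    index = {x: i for i, x in enumerate(ids)}
    parent = list(range(len(ids)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in linked:
        ra, rb = find(index[a]), find(index[b])
        if ra != rb:
            parent[ra] = rb
    groups: dict[int, list[str]] = {}
    for x in ids:
        groups.setdefault(find(index[x]), []).append(x)
    comps = [sorted(g) for g in groups.values()]
    comps.sort(key=lambda g: g[0])
    return comps


def _reliable(i: int, j: int, ident: np.ndarray, cov: np.ndarray,
              config: NomenclatureConfig) -> bool:
    return cov[i, j] >= config.min_coverage


def assign_families(ident: np.ndarray, cov: np.ndarray, ids: list[str],
                    references: dict[str, str],
                    config: NomenclatureConfig | None = None,
                    ) -> dict[str, FamilyAssignment]:
    """Family assignment for query ids.

    ``references`` maps reference id -> family label (e.g. ``"CYP4"``); the
    matrices must cover queries and references together (ids gives the order).
    A query joins the family of its highest-identity reference above the
    (strict) family threshold with reliable coverage — ties go to the
    lexicographically smallest family label.  Remaining queries are clustered
    by single linkage at the threshold; each component becomes a novel family
    numbered consecutively from ``novel_family_start`` in order of smallest
    member id.
    """
    if config is None:
        config = NomenclatureConfig()
    index = {x: i for i, x in enumerate(ids)}
    queries = [x for x in ids if x not in references]
    out: dict[str, FamilyAssignment] = {}

    unanchored: list[str] = []
    for q in queries:
        qi = index[q]
        best: tuple[float, str, str] | None = None  # (identity, family, ref)
        for ref, family in references.items():
            ri = index.get(ref)
            if ri is None:
                raise ValueError(f"reference {ref!r} missing from matrix ids")
            pid = ident[qi, ri]
            if pid > config.family_threshold and _reliable(qi, ri, ident, cov,
                                                           config):
                cand = (pid, family, ref)
                if best is None or pid > best[0] or (pid == best[0]
                                                    and family < best[1]):
                    best = cand
        if best is not None:
            out[q] = FamilyAssignment(id=q, family=best[1], anchor=best[2],
                                      anchor_identity=best[0])
        else:
            unanchored.append(q)

    linked = [(a, b) for a in unanchored for b in unanchored if a < b
              and ident[index[a], index[b]] > config.family_threshold
              and _reliable(index[a], index[b], ident, cov, config)]
    for k, comp in enumerate(_components(unanchored, linked)):
        label = f"CYP{config.novel_family_start + k}"
        _warn_on_chaining(comp, index, ident, config.family_threshold, label)
        for q in comp:
            out[q] = FamilyAssignment(id=q, family=label, novel_family=True)
    return out


def _warn_on_chaining(comp, index, ident, threshold, label) -> None:
    for a in comp:
        for b in comp:
            if a < b and ident[index[a], index[b]] <= threshold:
                warnings.warn(
                    f"{label}: members {a}/{b} below {threshold}% "
                    f"(single-linkage chaining)", stacklevel=2)
                return


def _letters():
    """A, B, ... Z, AA, AB, ..."""
    for ch in string.ascii_uppercase:
        yield ch
    for a in string.ascii_uppercase:
        for b in string.ascii_uppercase:
            yield a + b


def _split_reference_name(name: str) -> tuple[str, int] | None:
    """'CYP4V2' -> ('V', 2); None if the name has no subfamily suffix."""
    m = re.fullmatch(r"(?:CYP)?\d+([A-Z]+)(\d+)?", name)
    if not m:
        return None
    return m.group(1), int(m.group(2) or 0)


def assign_subfamilies_and_numbers(
        assignments: dict[str, FamilyAssignment],
        ident: np.ndarray, cov: np.ndarray, ids: list[str],
        config: NomenclatureConfig | None = None,
        reference_names: dict[str, str] | None = None,
        ) -> dict[str, FamilyAssignment]:
    """Within each family, single-linkage components at the (strict) subfamily
    threshold become subfamilies lettered A, B, C... in order of smallest
    member id; gene numbers run 1..n within a subfamily by member id order.

    For reference-anchored families, letters already used by the named
    references (``reference_names``: ref id -> full name like ``CYP4V2``) are
    skipped so new subfamilies never collide with committee-assigned ones.
    """
    if config is None:
        config = NomenclatureConfig()
    index = {x: i for i, x in enumerate(ids)}
    by_family: dict[str, list[str]] = {}
    for q, a in assignments.items():
        by_family.setdefault(a.family, []).append(q)

    taken_letters: dict[str, set[str]] = {}
    if reference_names:
        for ref, full in reference_names.items():
            parsed = _split_reference_name(full)
            if parsed:
                fam_label = re.match(r"(?:CYP)?(\d+)", full)
                if fam_label:
                    taken_letters.setdefault(f"CYP{fam_label.group(1)}",
                                             set()).add(parsed[0])

    for family, members in sorted(by_family.items()):
        linked = [(a, b) for a in members for b in members if a < b
                  and ident[index[a], index[b]] > config.subfamily_threshold
                  and _reliable(index[a], index[b], ident, cov, config)]
        comps = _components(members, linked)
        used = taken_letters.get(family, set())
        letters = (ch for ch in _letters() if ch not in used)
        for comp, letter in zip(comps, letters):
            for num, member in enumerate(sorted(comp), start=1):
                assignments[member].subfamily = letter
                assignments[member].gene_number = num
    return assignments


def name_cypome(queries: list[ProteinRecord],
                references: list[ProteinRecord] | None = None,
                reference_families: dict[str, str] | None = None,
                config: NomenclatureConfig | None = None,
                ) -> dict[str, FamilyAssignment]:
    """End-to-end naming: identity matrix, family assignment, subfamily
    letters and gene numbers.  ``reference_families`` maps reference id ->
    family label; defaults to the family prefix of each reference id."""
    if config is None:
        config = NomenclatureConfig()
    references = references or []
    ref_fams = dict(reference_families or {})
    for ref in references:
        if ref.id not in ref_fams:
            m = re.search(r"(CYP\d+)", ref.id)
            ref_fams[ref.id] = m.group(1) if m else ref.id
    ident, cov, ids = identity_matrix(list(queries) + list(references), config)
    assignments = assign_families(ident, cov, ids, ref_fams, config)
    ref_names = {r.id: r.id.split("_")[-1] for r in references}
    return assign_subfamilies_and_numbers(assignments, ident, cov, ids,
                                          config, reference_names=ref_names)
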
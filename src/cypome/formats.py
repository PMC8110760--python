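"""File formats and core records: protein FASTA, Newick trees, fixture tables.

Protein headers carry optional whitespace-separated ``key=value`` tokens after
the id (``species=``, ``has_start=``, ``has_stop=``, and arbitrary boolean
evidence such as ``hmm_match=true``), which keeps the files plain FASTA while
preserving start/stop-codon evidence that amino-acid sequence alone cannot
encode.  All coordinates in fixtures and reports are 1-based inclusive.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues legal in a ProteinRecord (X = unknown, '-' = gap, '*' = stop)
ALPHABET = set(AMINO_ACIDS) | {"X", "-", "*"}

TRI_STATE = ("yes", "no", "unknown")

#: canonical motif column order used throughout
MOTIF_NAMES = ("ihelix", "khelix", "meander", "heme")

#: absent-marker variants accepted in fixture tables (en-dash as printed, or ASCII)
ABSENT_MARKERS = {"–", "-", ""}


class FormatError(ValueError):
    """Raised for malformed input files."""


@dataclass
class ProteinRecord:
    """One candidate or reference protein sequence with start/stop evidence."""

    id: str
    residues: str
    species: str = ""
    has_start: str = "unknown"
    has_stop: str = "unknown"
    evidence: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("record id must be non-empty")
        if not self.residues:
            raise FormatError(f"{self.id}: empty sequence")
        bad = sorted(set(self.residues) - ALPHABET)
        if bad:
            raise FormatError(f"{self.id}: non-amino-acid characters {bad}")
        if "*" in self.residues[:-1]:
            raise FormatError(f"{self.id}: '*' may appear only as final character")
        if self.has_start not in TRI_STATE or self.has_stop not in TRI_STATE:
            raise FormatError(f"{self.id}: start/stop flags must be one of {TRI_STATE}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")


@dataclass
class FixtureRow:
    """One gene row of a motif-survey table (lengths, per-motif positions/strings)."""

    gene_name: str
    species: str
    length: int
    motif_positions: dict[str, int | None]
    motif_strings: dict[str, str | None]
    status: str = ""


def _parse_bool(token: str) -> bool:
    return token.lower() in {"true", "yes", "1"}


def _record_from_entry(name: str, description: str, seq: str,
                       strip_gaps: bool) -> ProteinRecord:
    tokens = description.split()[1:] if description else []
    meta = {}
    for tok in tokens:
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    seq = seq.upper()
    if strip_gaps:
        seq = seq.replace("-", "")
    has_stop = "yes" if seq.endswith("*") else None
    seq = seq.rstrip("*")
    if not seq:
        raise FormatError(f"{name}: empty sequence")
    has_start = "yes" if seq.startswith("M") else "no"
    if has_stop is None:
        has_stop = "unknown"
    # explicit header tokens override inference
    has_start = meta.pop("has_start", has_start)
    has_stop = meta.pop("has_stop", has_stop)
    species = meta.pop("species", "")
    evidence = {k: _parse_bool(v) for k, v in meta.items()}
    return ProteinRecord(id=name, residues=seq, species=species,
                         has_start=has_start, has_stop=has_stop,
                         evidence=evidence)


def read_fasta(path: str | Path, *, strip_gaps: bool = True) -> list[ProteinRecord]:
    """Read protein FASTA into records.

    Header ``key=value`` tokens populate flags; otherwise ``has_start`` is
    inferred from a leading 'M' and ``has_stop`` from a trailing '*'.  Gap
    characters are stripped unless ``strip_gaps=False`` (alignment files).
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise FormatError(f"duplicate id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(_record_from_entry(entry.id, entry.description,
                                          str(entry.seq), strip_gaps))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 70) -> None:
    """Write records with explicit flag tokens so a round-trip is lossless."""
    with open(path, "w") as fh:
        for rec in records:
            toks = [rec.id]
            if rec.species:
                toks.append(f"species={rec.species}")
            toks.append(f"has_start={rec.has_start}")
            toks.append(f"has_stop={rec.has_stop}")
            for k in sorted(rec.evidence):
                toks.append(f"{k}={'true' if rec.evidence[k] else 'false'}")
            fh.write(">" + " ".join(toks) + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Phylogenetic trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a :class:`PhyloTree`; edge attributes (length, support) belong
    to the edge above the node."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float | None = None,
                 support: float | None = None):
        self.name = name
        self.length = length
        self.support = support
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def traverse(self):
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.traverse() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())


@dataclass
class PhyloTree:
    """Rooted or unrooted tree with optional branch lengths and per-edge
    bootstrap supports (stored on the child node of each internal edge)."""

    root: TreeNode
    rooted: bool = False

    def leaves(self) -> list[TreeNode]:
        return self.root.leaves()

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def find(self, name: str) -> TreeNode:
        for n in self.root.traverse():
            if n.name == name and n.is_leaf:
                return n
        raise KeyError(name)

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions of the leaf set (unrooted sense)."""
        all_leaves = self.leaf_names()
        out = set()
        for node in self.root.traverse():
            if node is self.root or node.is_leaf:
                continue
            side = node.leaf_names()
            other = all_leaves - side
            if len(side) > 1 and len(other) > 1:
                out.add(frozenset({side, other}))
        return out

    def newick(self, *, include_support: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_support and node.support is not None:
                    s += _fmt_num(node.support)
                elif node.name:
                    s += node.name
            if node.length is not None:
                s += ":" + _fmt_num(node.length)
            return s

        return fmt(self.root) + ";"

    def copy(self) -> "PhyloTree":
        def cp(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length, node.support)
            for c in node.children:
                new.add(cp(c))
            return new

        return PhyloTree(cp(self.root), rooted=self.rooted)


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def read_newick(path_or_text: str | Path) -> PhyloTree:
    """Parse a Newick tree; numeric internal-node labels become supports.

    Raises :class:`FormatError` with the character offset for unbalanced
    parentheses.
    """
    if isinstance(path_or_text, Path) or (isinstance(path_or_text, str)
                                          and not path_or_text.lstrip().startswith("(")
                                          and Path(path_or_text).exists()):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    depth = 0
    for i, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(f"unbalanced ')' at character {i}")
    if depth != 0:
        raise FormatError(f"unbalanced '(': {depth} unclosed at end of input "
                          f"(length {len(text)})")
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy error classes vary
        raise FormatError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        name = None
        support = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                name = dnode.label
        node = TreeNode(name=name, length=dnode.edge.length, support=support)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root, rooted=len(root.children) == 2)


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


# ---------------------------------------------------------------------------
# Fixture tables
# ---------------------------------------------------------------------------

def _fixture_cell(value) -> int | None:
    if pd.isna(value) or str(value).strip() in ABSENT_MARKERS:
        return None
    return int(value)


def load_fixture_table(path: str | Path) -> list[FixtureRow]:
    """Load a motif-survey TSV (one row per gene) validating coordinates."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str,
                     keep_default_na=False)
    required = {"gene_name", "species", "length"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    rows: list[FixtureRow] = []
    for _, r in df.iterrows():
        length = int(r["length"])
        positions: dict[str, int | None] = {}
        strings: dict[str, str | None] = {}
        for motif in MOTIF_NAMES:
            pos = _fixture_cell(r.get(f"{motif}_pos", ""))
            s = str(r.get(f"{motif}_str", "")).strip()
            strings[motif] = None if s in ABSENT_MARKERS else s
            if pos is not None:
                if pos < 1 or pos > length:
                    raise FormatError(
                        f"{path}: row {r['gene_name']}: {motif} position {pos} "
                        f"outside 1..{length}")
            positions[motif] = pos
        rows.append(FixtureRow(gene_name=r["gene_name"], species=r["species"],
                               length=length, motif_positions=positions,
                               motif_strings=strings,
                               status=str(r.get("status", "")).strip()))
    return rows


def fixture_path(name: str) -> Path:
    """Path of a TSV shipped with the package (motif tables, curation counts)."""
    return Path(str(resources.files("cypome") / "data" / name))


def load_shipped_motif_tables() -> list[FixtureRow]:
    """All rows of the three shipped motif-survey tables, in table order."""
    rows: list[FixtureRow] = []
    for name in ("table1_hvul_motifs.tsv", "table2_adig_motifs.tsv",
                 "table3_aaur_motifs.tsv"):
        rows.extend(load_fixture_table(fixture_path(name)))
    return rows


def load_results_counts() -> pd.DataFrame:
    """Published per-species complete/partial/fragment tallies."""
    return pd.read_csv(fixture_path("results_counts.tsv"), sep="\t",
                       comment="#").set_index("species")
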
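"""Ranked taxonomy trees with LCA and rank roll-up.

Reads and writes the NCBI taxdump dialect (``nodes.dmp`` / ``names.dmp``,
fields separated by ``\\t|\\t`` and records terminated by ``\\t|``) and
provides the two ancestry primitives that protein k-mer classification is
built on: the lowest common ancestor (LCA) of a taxon set, and the roll-up
of read assignments to a fixed rank (e.g. genus) for count tables.

The rank vocabulary is fixed to the eight canonical ranks below; any other
rank string found in the input maps to ``no_rank``.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Tuple

CANONICAL_RANKS: Tuple[str, ...] = (
    "root",
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)
NO_RANK = "no_rank"

# common synonyms seen in taxdump files
_RANK_ALIASES = {"domain": "superkingdom", "kingdom": "superkingdom"}


class TaxdumpParseError(ValueError):
    """A taxdump line could not be parsed (message names the line number)."""


class TaxonomyStructureError(ValueError):
    """The node set violates a tree invariant (orphan parent, cycle, ...)."""


class UnknownTaxidError(KeyError):
    """A queried taxid is not present in the tree."""


def _canonical_rank(rank: str) -> str:
    rank = rank.strip().lower().replace(" ", "_")
    rank = _RANK_ALIASES.get(rank, rank)
    return rank if rank in CANONICAL_RANKS else NO_RANK


@dataclass(frozen=True)
class TaxNode:
    taxid: int
    parent: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """A rooted, ranked taxonomy supporting LCA and rank aggregation.

    Invariants enforced at construction: exactly one root (a node that is
    its own parent), unique taxids, every parent present, no cycles.
    """

    def __init__(self, nodes: Iterable[TaxNode]):
        nodes = list(nodes)
        self._nodes: dict[int, TaxNode] = {}
        for n in nodes:
            if n.taxid in self._nodes:
                raise TaxonomyStructureError(f"duplicate taxid {n.taxid}")
            if n.taxid <= 0:
                raise TaxonomyStructureError(f"non-positive taxid {n.taxid}")
            self._nodes[n.taxid] = n
        roots = [n.taxid for n in nodes if n.parent == n.taxid]
        if len(roots) != 1:
            raise TaxonomyStructureError(
                f"expected exactly one root node, found {len(roots)}"
            )
        self.root: int = roots[0]
        # force the canonical root rank regardless of input spelling
        rn = self._nodes[self.root]
        if rn.rank != "root":
            self._nodes[self.root] = TaxNode(rn.taxid, rn.parent, "root", rn.name)
        self._children: dict[int, list[int]] = {t: [] for t in self._nodes}
        for n in nodes:
            if n.parent not in self._nodes:
                raise TaxonomyStructureError(
                    f"taxid {n.taxid} has unknown parent {n.parent}"
                )
            if n.taxid != self.root:
                self._children[n.parent].append(n.taxid)
        self._paths: dict[int, tuple[int, ...]] = {self.root: (self.root,)}
        for t in self._nodes:  # materialise all root-paths; also detects cycles
            self.path(t)

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __iter__(self):
        return iter(self._nodes)

    def node(self, taxid: int) -> TaxNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def parent(self, taxid: int) -> int:
        return self.node(taxid).parent

    def children(self, taxid: int) -> list[int]:
        self.node(taxid)
        return self._children[taxid]

    def path(self, taxid: int) -> tuple[int, ...]:
        """Root-to-node taxid path (inclusive at both ends)."""
        cached = self._paths.get(taxid)
        if cached is not None:
            return cached
        chain = []
        seen = set()
        t = taxid
        while t not in self._paths:
            if t in seen:
                raise TaxonomyStructureError(f"cycle through taxid {t}")
            seen.add(t)
            chain.append(t)
            t = self.node(t).parent
        prefix = self._paths[t]
        for i in range(len(chain) - 1, -1, -1):
            prefix = prefix + (chain[i],)
            self._paths[chain[i]] = prefix
        return self._paths[taxid]

    # -- ancestry primitives ---------------------------------------------

    def lca(self, taxa: Iterable[int]) -> int:
        """Lowest common ancestor: the deepest node that is an
        ancestor-or-self of every input taxon."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("lca of an empty taxon set is undefined")
        paths = [self.path(t) for t in taxa]
        lca = self.root
        for level in range(min(len(p) for p in paths)):
            node = paths[0][level]
            if all(p[level] == node for p in paths):
                lca = node
            else:
                break
        return lca

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The ancestor-or-self of ``taxid`` at ``rank``, or None."""
        for t in self.path(taxid):
            if self.rank(t) == rank:
                return t
        return None

    def is_ancestor(self, ancestor: int, taxid: int) -> bool:
        return ancestor in self.path(taxid)

    def roll_up_to_rank(
        self, assignments: Mapping[int, int] | Iterable[int], rank: str
    ) -> tuple[dict[int, int], int]:
        """Aggregate taxon assignments at ``rank``.

        Each assignment at-or-below ``rank`` is counted at its ``rank``
        ancestor; assignments above ``rank`` (no ancestor-or-self at that
        rank) are excluded.  Returns ``(counts_at_rank, n_excluded)``;
        counted + excluded equals the input multiset size.
        """
        if rank not in CANONICAL_RANKS:
            raise ValueError(f"not a canonical rank: {rank!r}")
        multiset = (
            assignments if isinstance(assignments, Mapping) else Counter(assignments)
        )
        counts: Counter[int] = Counter()
        excluded = 0
        for taxid, n in multiset.items():
            anc = self.ancestor_at_rank(taxid, rank)
            if anc is None:
                excluded += n
            else:
                counts[anc] += n
        return dict(counts), excluded

    # -- taxdump IO ------------------------------------------------------

    @classmethod
    def from_taxdump(cls, nodes_source, names_source=None) -> "TaxonomyTree":
        """Load a tree from taxdump-dialect ``nodes.dmp``/``names.dmp``.

        Sources may be paths or open text handles.  Names are attached
        where present (``scientific name`` class preferred).
        """
        nodes: dict[int, TaxNode] = {}
        for lineno, fields in _iter_taxdump(nodes_source):
            if len(fields) < 3:
                raise TaxdumpParseError(
                    f"nodes line {lineno}: expected >= 3 fields, got {len(fields)}"
                )
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError:
                raise TaxdumpParseError(
                    f"nodes line {lineno}: non-integer taxid field"
                ) from None
            nodes[taxid] = TaxNode(taxid, parent, _canonical_rank(fields[2]))
        names: dict[int, str] = {}
        if names_source is not None:
            for lineno, fields in _iter_taxdump(names_source):
                if len(fields) < 2:
                    raise TaxdumpParseError(
                        f"names line {lineno}: expected >= 2 fields"
                    )
                try:
                    taxid = int(fields[0])
                except ValueError:
                    raise TaxdumpParseError(
                        f"names line {lineno}: non-integer taxid"
                    ) from None
                name_class = fields[3] if len(fields) > 3 else "scientific name"
                if taxid not in names or name_class == "scientific name":
                    names[taxid] = fields[1]
        return cls(
            TaxNode(n.taxid, n.parent, n.rank, names.get(n.taxid, ""))
            for n in nodes.values()
        )

    def to_taxdump(self, nodes_path, names_path) -> None:
        """Write the tree back out in the taxdump dialect."""
        with open(nodes_path, "w") as fh:
            for t in sorted(self._nodes):
                n = self._nodes[t]
                rank = "no rank" if n.rank == NO_RANK else n.rank
                fh.write(f"{n.taxid}\t|\t{n.parent}\t|\t{rank}\t|\n")
        with open(names_path, "w") as fh:
            for t in sorted(self._nodes):
                n = self._nodes[t]
                if n.name:
                    fh.write(f"{n.taxid}\t|\t{n.name}\t|\t\t|\tscientific name\t|\n")


def _iter_taxdump(source):
    """Yield (lineno, fields) for a taxdump-dialect source (path or handle)."""
    if isinstance(source, (str, Path)):
        fh = open(source, "r")
        close = True
    elif isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        fh = source
        close = False
    else:
        raise TypeError(f"unsupported taxdump source: {type(source)!r}")
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            elif line.endswith("|"):
                line = line[:-1].rstrip("\t")
            yield lineno, line.split("\t|\t")
    finally:
        if close:
            fh.close()
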
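"""Amino-acid k-mer index mapping peptides to taxa.

The index maps each k-length (default 9) window over a set of reference
proteins to a single taxid: the lowest common ancestor of every reference
protein that contains the window.  This is the Unipept-style memory
contract — one LCA per k-mer rather than the full contributing taxon list —
and it is the input the read-level consensus aggregation operates on.

Windows containing non-standard residues (B, J, O, U, X, Z, or ``*``) are
skipped at build time and yield no hit at query time; I and L are treated
as distinct residues.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Tuple

from .taxonomy import TaxonomyTree, UnknownTaxidError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

_MAGIC = "#chitomics-kmer-index"
_VERSION = "v1"


class IndexFormatError(ValueError):
    """A saved index file has the wrong magic string or version."""


def _valid_windows(peptide: str, k: int) -> Iterator[Tuple[int, str]]:
    """Yield (offset, kmer) for windows made only of standard residues."""
    n = len(peptide)
    if n < k:
        return
    # index of the most recent invalid character, -1 if none seen yet
    last_bad = -1
    for i, ch in enumerate(peptide):
        if ch not in _AA_SET:
            last_bad = i
        if i >= k - 1 and last_bad <= i - k:
            yield i - k + 1, peptide[i - k + 1 : i + 1]


class KmerIndex:
    """Map from amino-acid k-mer to the LCA taxid of its source proteins."""

    __slots__ = ("k", "entries")

    def __init__(self, k: int = 9, entries: dict[str, int] | None = None):
        if k < 2:
            raise ValueError("k must be >= 2")
        self.k = k
        self.entries: dict[str, int] = entries if entries is not None else {}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def query_kmers(self, peptide: str) -> list[tuple[int, int]]:
        """All indexed windows of ``peptide`` as (offset, taxid), in offset
        order.  Windows with stops or non-standard residues yield nothing."""
        entries = self.entries
        hits = []
        for off, kmer in _valid_windows(peptide, self.k):
            taxid = entries.get(kmer)
            if taxid is not None:
                hits.append((off, taxid))
        return hits

    def n_windows(self, peptide: str) -> int:
        """Number of queryable (all-standard-residue) windows in a peptide."""
        return sum(1 for _ in _valid_windows(peptide, self.k))

    # -- serialization ---------------------------------------------------

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{_MAGIC}\t{_VERSION}\tk={self.k}\n")
            for kmer in sorted(self.entries):
                fh.write(f"{kmer}\t{self.entries[kmer]}\n")

    @classmethod
    def load(cls, path) -> "KmerIndex":
        with open(path, "r") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if len(header) != 3 or header[0] != _MAGIC:
                raise IndexFormatError(f"not a k-mer index file: {path}")
            if header[1] != _VERSION:
                raise IndexFormatError(
                    f"unsupported index version {header[1]!r} (expected {_VERSION})"
                )
            k = int(header[2].removeprefix("k="))
            entries: dict[str, int] = {}
            for line in fh:
                kmer, taxid = line.rstrip("\n").split("\t")
                entries[kmer] = int(taxid)
        return cls(k=k, entries=entries)


def build_index(
    proteins: Iterable[tuple[str, int]], tree: TaxonomyTree, k: int = 9
) -> KmerIndex:
    """Build a k-mer → LCA-taxid index from ``(peptide, taxid)`` pairs.

    Adding a protein can only move an existing key's value toward the root
    (LCA aggregation is monotone).
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("cannot build an index from an empty protein list")
    index = KmerIndex(k=k)
    entries = index.entries
    for peptide, taxid in proteins:
        if taxid not in tree:
            raise UnknownTaxidError(taxid)
        for _, kmer in _valid_windows(peptide.upper(), k):
            prev = entries.get(kmer)
            if prev is None:
                entries[kmer] = taxid
            elif prev != taxid:
                entries[kmer] = tree.lca((prev, taxid))
    return index


def save_index(index: KmerIndex, path) -> None:
    index.save(path)


def load_index(path) -> KmerIndex:
    return KmerIndex.load(path)


def read_protein_fasta(path) -> list[tuple[str, int]]:
    """Read reference proteins from FASTA whose headers carry ``taxid=<int>``."""
    from Bio import SeqIO

    proteins = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxid = None
        for token in rec.description.split():
            if token.startswith("taxid="):
                taxid = int(token.removeprefix("taxid="))
        if taxid is None:
            raise ValueError(f"FASTA record {rec.id!r} lacks a taxid= token")
        proteins.append((str(rec.seq).upper(), taxid))
    return proteins
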
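"""Read-level taxonomic classification via six-frame translation and
9-mer consensus aggregation.

Each merged read is translated in all six reading frames; every
amino-acid 9-mer of every frame is looked up in the reference
:class:`~chitomics.peptide_index.KmerIndex`; the per-k-mer taxon hits are
pooled across frames and aggregated into a single consensus taxon per
read.  Per-sample assignments are rolled up to genus to form the count
table the differential-abundance statistics run on.

The consensus rule: hits at the taxonomy root are discarded (they carry
no information); starting at the root, descend into the child whose
subtree carries at least a fraction ``f`` (default 0.8) of the current
node's hit weight, stopping when no child qualifies.  ``f = 1.0`` reduces
exactly to the LCA of the surviving hits; ``f <= 0.5`` is rejected because
two children could then qualify simultaneously.
"""

from __future__ import annotations

import gzip
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .peptide_index import KmerIndex
from .tables import CountTable
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)

#: Sentinel for reads with no surviving taxon hits.
UNCLASSIFIED = None

_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_SET = frozenset("ACGTN")


def _codon_table() -> dict[str, str]:
    from Bio.Data.CodonTable import standard_dna_table

    table = dict(standard_dna_table.forward_table)
    for codon in standard_dna_table.stop_codons:
        table[codon] = "*"
    return table


_CODON = _codon_table()


def reverse_complement(dna: str) -> str:
    return dna.translate(_DNA_COMPLEMENT)[::-1]


def _translate_frame(dna: str, offset: int) -> str:
    get = _CODON.get
    # codons with any ambiguous base (N) fall through to 'X'
    return "".join(
        get(dna[i : i + 3], "X") for i in range(offset, len(dna) - 2, 3)
    )


def six_frame_translate(dna: str) -> tuple[str, str, str, str, str, str]:
    """Translate ``dna`` in frames +1, +2, +3, -1, -2, -3 (standard code).

    Stops are rendered ``*``, codons containing N render ``X``, trailing
    partial codons are dropped.  Raises ``ValueError`` on characters
    outside ACGTN.
    """
    dna = dna.upper()
    if not _DNA_SET.issuperset(dna):
        bad = sorted(set(dna) - _DNA_SET)
        raise ValueError(f"non-IUPAC nucleotide characters: {bad}")
    rc = reverse_complement(dna)
    return (
        _translate_frame(dna, 0),
        _translate_frame(dna, 1),
        _translate_frame(dna, 2),
        _translate_frame(rc, 0),
        _translate_frame(rc, 1),
        _translate_frame(rc, 2),
    )


def consensus_taxon(
    hits: Iterable[int] | Mapping[int, int],
    tree: TaxonomyTree,
    f: float = 0.8,
) -> int | None:
    """Aggregate a multiset of per-k-mer taxon hits into one consensus taxon.

    Returns :data:`UNCLASSIFIED` (None) when no hits survive root-level
    filtering.
    """
    if not (0.5 < f <= 1.0):
        raise ValueError(f"consensus fraction f must be in (0.5, 1.0], got {f}")
    multiset = hits if isinstance(hits, Mapping) else Counter(hits)
    weights: Counter[int] = Counter()
    total = 0
    for taxid, n in multiset.items():
        if taxid == tree.root:  # the "filtered" step: root hits are noise
            continue
        total += n
        for anc in tree.path(taxid):
            weights[anc] += n
    if total == 0:
        return UNCLASSIFIED
    node = tree.root
    while True:
        need = f * weights[node] - 1e-9
        for child in tree.children(node):
            if weights.get(child, 0) >= need:
                node = child
                break
        else:
            return node


@dataclass
class ReadAssignment:
    """The consensus outcome for one read.

    ``taxid`` is None for unclassified reads; ``n_hits`` of ``n_windows``
    queryable 9-mer windows (pooled over all six frames) hit the index.
    """

    read_id: str
    taxid: int | None
    n_hits: int
    n_windows: int

    @property
    def assigned(self) -> bool:
        return self.taxid is not None


def classify_read(
    read_id: str,
    dna: str,
    index: KmerIndex,
    tree: TaxonomyTree,
    f: float = 0.8,
) -> ReadAssignment:
    """Six-frame translate one read, pool k-mer hits over frames, aggregate."""
    hits: Counter[int] = Counter()
    n_hits = 0
    n_windows = 0
    for peptide in six_frame_translate(dna):
        n_windows += index.n_windows(peptide)
        for _, taxid in index.query_kmers(peptide):
            hits[taxid] += 1
            n_hits += 1
    taxid = consensus_taxon(hits, tree, f=f) if hits else UNCLASSIFIED
    return ReadAssignment(read_id=read_id, taxid=taxid, n_hits=n_hits, n_windows=n_windows)


def classify_sample(
    reads: Iterable[tuple[str, str]],
    index: KmerIndex,
    tree: TaxonomyTree,
    f: float = 0.8,
) -> tuple[list[ReadAssignment], float]:
    """Classify a stream of ``(read_id, sequence)`` pairs.

    Unreadable records (invalid characters) are skipped with a logged
    warning but still counted in the total.  ``fraction_assigned`` is
    assigned/total, with the 0/0 case defined as 0.
    """
    assignments: list[ReadAssignment] = []
    total = 0
    assigned = 0
    for read_id, dna in reads:
        total += 1
        try:
            a = classify_read(read_id, dna, index, tree, f=f)
        except ValueError as exc:
            logger.warning("skipping unreadable read %s: %s", read_id, exc)
            continue
        assignments.append(a)
        if a.assigned:
            assigned += 1
    fraction = assigned / total if total else 0.0
    return assignments, fraction


def iter_reads(path) -> Iterator[tuple[str, str]]:
    """Stream (read_id, sequence) from FASTA/FASTQ, gzip-transparent."""
    from Bio import SeqIO

    path = Path(path)
    name = path.name.removesuffix(".gz")
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            yield rec.id, str(rec.seq)


def build_genus_table(
    assignments: Mapping[str, list[ReadAssignment]],
    tree: TaxonomyTree,
    rank: str = "genus",
) -> CountTable:
    """Roll per-sample read assignments up to ``rank``.

    Library sizes are the per-sample totals of *assigned* reads, so column
    sums can fall below the library size when assignments stop above the
    rank.
    """
    per_sample: dict[str, dict[int, int]] = {}
    lib_sizes: dict[str, int] = {}
    taxids: set[int] = set()
    for sample, alist in assignments.items():
        assigned = Counter(a.taxid for a in alist if a.assigned)
        lib_sizes[sample] = sum(assigned.values())
        counts, _ = tree.roll_up_to_rank(assigned, rank)
        per_sample[sample] = counts
        taxids.update(counts)
    rows = sorted(taxids)
    samples = list(assignments)
    counts_df = pd.DataFrame(
        [[per_sample[s].get(t, 0) for s in samples] for t in rows],
        index=rows,
        columns=samples,
        dtype=int,
    )
    return CountTable(counts=counts_df, library_sizes=pd.Series(lib_sizes))


def write_assignments_tsv(path, assignments: Iterable[ReadAssignment], tree: TaxonomyTree) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttaxid\trank\tn_hits\tn_windows\n")
        for a in assignments:
            taxid = a.taxid if a.assigned else "unclassified"
            rank = tree.rank(a.taxid) if a.assigned else "-"
            fh.write(f"{a.read_id}\t{taxid}\t{rank}\t{a.n_hits}\t{a.n_windows}\n")
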
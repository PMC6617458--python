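"""Synthetic references and two-treatment metagenome corpora with truth.

The generator emulates the statistical structure the analysis assumes: a
two-treatment (peat substrate ``PS`` vs chitin-amended ``Chitin``) design
with four replicates per group, genus-level fold changes of the magnitude
reported for chitin amendment (~0.4x to ~19x), gene-family count shifts,
and sequencing depth/read length compatible with 9-mer classification
(default 10,000 x 200 nt reads per sample).

Key idealization: genera are built with pairwise-disjoint proteome 9-mer
sets (rejection-resampled), so classification of error-free reads is
exact rather than probabilistic; an optional overlap mode shares proteins
between two species of a genus to exercise LCA/consensus behaviour below
unanimity.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import _CODON
from .gene_profile import GeneFamilyDef, MatchRecord, builtin_family_registry, registry_by_id, write_domtblout
from .peptide_index import AA_ALPHABET
from .taxonomy import TaxNode, TaxonomyTree

GROUP_PS = "PS"
GROUP_CHITIN = "Chitin"

#: Default base genus relative abundances (decreasing simplex, sums to 1).
DEFAULT_BASE_ABUNDANCES = (0.30, 0.20, 0.13, 0.10, 0.08, 0.06, 0.05, 0.03, 0.03, 0.02)

#: Single-copy marker set used by the genome-equivalents estimator
#: (synthetic marker ids with lengths in aa).
DEFAULT_MARKER_SET = (
    ("SCM01", 250), ("SCM02", 280), ("SCM03", 300), ("SCM04", 320),
    ("SCM05", 350), ("SCM06", 220), ("SCM07", 400), ("SCM08", 260),
    ("SCM09", 310), ("SCM10", 330),
)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic corpus."""

    seed: int = 0
    n_genera: int = 10
    proteins_per_taxon: int = 20
    protein_len_range: tuple[int, int] = (180, 320)
    genome_spacer_frac: float = 0.02
    n_replicates_per_group: int = 4
    depth_reads: int = 10000
    read_len_nt: int = 200
    error_rate: float = 0.0
    dirichlet_concentration: float = 200.0
    base_abundances: tuple[float, ...] | None = None
    genus_effects: dict[str, float] = field(default_factory=dict)
    family_effects: dict[str, float] = field(default_factory=dict)
    family_base_count: float = 150.0
    match_pass_fraction: float = 0.9
    share_proteins: bool = False
    k: int = 9

    def resolved_base_abundances(self) -> np.ndarray:
        if self.base_abundances is not None:
            w = np.asarray(self.base_abundances, dtype=float)
            if w.size != self.n_genera:
                raise ValueError("base_abundances length != n_genera")
        elif self.n_genera == len(DEFAULT_BASE_ABUNDANCES):
            w = np.asarray(DEFAULT_BASE_ABUNDANCES)
        else:
            w = 0.75 ** np.arange(self.n_genera)
        if (w <= 0).any():
            raise ValueError("base abundances must be positive")
        return w / w.sum()

    def genus_names(self) -> list[str]:
        return [f"Genus{i + 1:02d}" for i in range(self.n_genera)]

    def sample_ids(self) -> list[str]:
        n = self.n_replicates_per_group
        return [f"{GROUP_PS}{i + 1}" for i in range(n)] + [
            f"{GROUP_CHITIN}{i + 1}" for i in range(n)
        ]

    def groups(self) -> dict[str, str]:
        n = self.n_replicates_per_group
        out = {f"{GROUP_PS}{i + 1}": GROUP_PS for i in range(n)}
        out.update({f"{GROUP_CHITIN}{i + 1}": GROUP_CHITIN for i in range(n)})
        return out

    def group_proportions(self, group: str) -> np.ndarray:
        """Expected genus proportions in a treatment group (fold changes
        applied to the Chitin group, then renormalized)."""
        w = self.resolved_base_abundances().copy()
        if group == GROUP_CHITIN:
            for i, name in enumerate(self.genus_names()):
                fc = self.genus_effects.get(name, 1.0)
                if fc <= 0:
                    raise ValueError("fold changes must be > 0")
                w[i] *= fc
        return w / w.sum()


def default_study_config(seed: int = 0) -> SimulationConfig:
    """The default study conditions: 2 x 4 design, two genera spiked up at
    the magnitudes reported for Nitrosospira (3.4x) and Cellvibrio (7.6x),
    one down-shifted genus (0.4x), and gene-family shifts mirroring the
    reported amoA-AOB increase, nosZ decreases and GH19/GH46/GH75 increases."""
    return SimulationConfig(
        seed=seed,
        genus_effects={"Genus08": 3.4, "Genus09": 7.6, "Genus04": 0.4},
        family_effects={
            "amoA_AOB": 3.1, "nosZ": 0.74, "nosZ_atypical1": 0.73,
            "nosZ_atypical2": 0.75, "GH19": 1.9, "GH46": 1.6, "GH75": 1.4,
        },
    )


# -- reference simulation ------------------------------------------------

_SYN_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON.items():
    if _aa != "*":
        _SYN_CODONS.setdefault(_aa, []).append(_codon)
_STOP = "TAA"


@dataclass
class Reference:
    """A synthetic reference: taxonomy, labelled proteome and genomes."""

    tree: TaxonomyTree
    proteins: list[tuple[str, str, int]]  # (protein_id, peptide, taxid)
    genomes: dict[int, str]  # species taxid -> genome sequence
    genus_taxids: list[int]
    genus_names: list[str]
    species_of_genus: dict[int, int]  # genus taxid -> genome-bearing species

    def genus_of_species(self) -> dict[int, int]:
        return {s: g for g, s in self.species_of_genus.items()}

    def write(self, outdir) -> dict[str, Path]:
        """Write taxdump, proteome FASTA (taxid= headers) and genome FASTA."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "nodes": outdir / "nodes.dmp",
            "names": outdir / "names.dmp",
            "proteome": outdir / "proteome.fasta",
            "genomes": outdir / "genomes.fasta",
        }
        self.tree.to_taxdump(paths["nodes"], paths["names"])
        with open(paths["proteome"], "w") as fh:
            for pid, pep, taxid in self.proteins:
                fh.write(f">{pid} taxid={taxid}\n{pep}\n")
        with open(paths["genomes"], "w") as fh:
            for taxid in sorted(self.genomes):
                fh.write(f">genome_{taxid} taxid={taxid}\n{self.genomes[taxid]}\n")
        return paths


def simulate_reference(config: SimulationConfig) -> Reference:
    """Genera with pairwise-disjoint proteome 9-mers, genomes = CDS plus a
    small neutral spacer fraction.  Deterministic under the seed."""
    rng = np.random.default_rng([config.seed, 1])
    lo, hi = config.protein_len_range
    k = config.k
    aa = np.frombuffer(AA_ALPHABET.encode(), dtype=np.uint8)

    nodes = [TaxNode(1, 1, "root", "root"), TaxNode(2, 1, "superkingdom", "Bacteria")]
    genus_taxids, genus_names = [], []
    species_of_genus: dict[int, int] = {}
    second_species: dict[int, int] = {}
    for i in range(config.n_genera):
        name = f"Genus{i + 1:02d}"
        nodes += [
            TaxNode(100 + i, 2, "phylum", f"Phylum{i + 1:02d}"),
            TaxNode(200 + i, 100 + i, "class", f"Class{i + 1:02d}"),
            TaxNode(300 + i, 200 + i, "order", f"Order{i + 1:02d}"),
            TaxNode(400 + i, 300 + i, "family", f"Family{i + 1:02d}"),
            TaxNode(500 + i, 400 + i, "genus", name),
            TaxNode(600 + i, 500 + i, "species", f"{name} alpha"),
        ]
        genus_taxids.append(500 + i)
        genus_names.append(name)
        species_of_genus[500 + i] = 600 + i
        if config.share_proteins:
            nodes.append(TaxNode(700 + i, 500 + i, "species", f"{name} beta"))
            second_species[500 + i] = 700 + i
    tree = TaxonomyTree(nodes)

    kmer_owner: dict[str, int] = {}
    proteins: list[tuple[str, str, int]] = []
    per_genus_proteins: dict[int, list[str]] = {g: [] for g in genus_taxids}
    for i, genus in enumerate(genus_taxids):
        species = species_of_genus[genus]
        for p in range(config.proteins_per_taxon):
            while True:
                length = int(rng.integers(lo, hi + 1))
                pep = bytes(aa[rng.integers(0, len(aa), length)]).decode()
                kmers = [pep[j : j + k] for j in range(length - k + 1)]
                if all(kmer_owner.get(km, i) == i for km in kmers):
                    break
            for km in kmers:
                kmer_owner[km] = i
            pid = f"prot_{genus}_{p:03d}"
            proteins.append((pid, pep, species))
            per_genus_proteins[genus].append(pep)
            # overlap mode: every other protein also labelled on a sister
            # species, pushing its k-mers' LCA up to the genus
            if config.share_proteins and p % 2 == 1:
                proteins.append((pid + "_b", pep, second_species[genus]))

    genomes: dict[int, str] = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for genus in genus_taxids:
        cds_parts = []
        for pep in per_genus_proteins[genus]:
            codons = [
                _SYN_CODONS[c][rng.integers(0, len(_SYN_CODONS[c]))] for c in pep
            ]
            cds_parts.append("".join(codons) + _STOP)
        cds = "".join(cds_parts)
        spacer_len = int(round(config.genome_spacer_frac * len(cds)))
        half = spacer_len // 2
        s1 = bytes(bases[rng.integers(0, 4, half)]).decode()
        s2 = bytes(bases[rng.integers(0, 4, spacer_len - half)]).decode()
        genomes[species_of_genus[genus]] = s1 + cds + s2
    return Reference(
        tree=tree,
        proteins=proteins,
        genomes=genomes,
        genus_taxids=genus_taxids,
        genus_names=genus_names,
        species_of_genus=species_of_genus,
    )


# -- community reads -----------------------------------------------------


@dataclass
class SimulationTruth:
    """Ground truth of a simulated two-treatment read corpus."""

    groups: dict[str, str]
    genus_proportions: pd.DataFrame  # genus name x sample (Dirichlet draws)
    genus_read_counts: pd.DataFrame  # genus name x sample (realized)
    read_sources: dict[str, list[tuple[str, int, int, int, str]]]
    # per sample: (read_id, species_taxid, genus_taxid, position, strand)
    true_ags: pd.Series  # per-sample average genome size (bp)


@dataclass
class CommunityReads:
    """Per-sample reads plus their generating truth."""

    samples: dict[str, list[tuple[str, str]]]  # sample -> (read_id, sequence)
    truth: SimulationTruth
    read_len_nt: int

    def write_fastq(self, outdir, gz: bool = False) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample, reads in self.samples.items():
            path = outdir / (f"{sample}.fastq.gz" if gz else f"{sample}.fastq")
            opener = gzip.open if gz else open
            with opener(path, "wt") as fh:
                for rid, seq in reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            paths[sample] = path
        return paths


def simulate_community_reads(
    reference: Reference, config: SimulationConfig
) -> CommunityReads:
    """Draw per-sample genus proportions (Dirichlet around the treatment
    means), read counts (multinomial at the configured depth) and reads
    (uniform genome positions, random strand, substitution errors)."""
    rng = np.random.default_rng([config.seed, 2])
    conc = config.dirichlet_concentration
    read_len = config.read_len_nt
    comp = str.maketrans("ACGT", "TGCA")
    bases = "ACGT"

    samples: dict[str, list[tuple[str, str]]] = {}
    props_cols, count_cols = {}, {}
    read_sources: dict[str, list] = {}
    true_ags = {}
    groups = config.groups()
    for sample in config.sample_ids():
        mean_props = config.group_proportions(groups[sample])
        props = rng.dirichlet(conc * mean_props) if conc > 0 else mean_props
        counts = rng.multinomial(config.depth_reads, props)
        props_cols[sample] = props
        count_cols[sample] = counts
        reads, sources = [], []
        read_no = 0
        for gi, genus in enumerate(reference.genus_taxids):
            species = reference.species_of_genus[genus]
            genome = reference.genomes[species]
            gmax = len(genome) - read_len
            if gmax < 0:
                raise ValueError("genome shorter than read length")
            for _ in range(int(counts[gi])):
                pos = int(rng.integers(0, gmax + 1))
                frag = genome[pos : pos + read_len]
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    frag = frag.translate(comp)[::-1]
                if config.error_rate > 0:
                    frag = list(frag)
                    n_err = rng.binomial(read_len, config.error_rate)
                    for p in rng.choice(read_len, size=n_err, replace=False):
                        frag[p] = bases[
                            (bases.index(frag[p]) + int(rng.integers(1, 4))) % 4
                        ]
                    frag = "".join(frag)
                rid = f"{sample}_r{read_no:06d}"
                read_no += 1
                reads.append((rid, frag))
                sources.append((rid, species, genus, pos, strand))
        samples[sample] = reads
        read_sources[sample] = sources
        denom = sum(
            count_cols[sample][gi]
            / len(reference.genomes[reference.species_of_genus[g]])
            for gi, g in enumerate(reference.genus_taxids)
        )
        total = int(count_cols[sample].sum())
        true_ags[sample] = total / denom if denom > 0 else float("nan")
    genus_index = reference.genus_names
    truth = SimulationTruth(
        groups=groups,
        genus_proportions=pd.DataFrame(props_cols, index=genus_index),
        genus_read_counts=pd.DataFrame(count_cols, index=genus_index),
        read_sources=read_sources,
        true_ags=pd.Series(true_ags),
    )
    return CommunityReads(samples=samples, truth=truth, read_len_nt=read_len)


def simulate_genus_count_table(
    config: SimulationConfig, seed: int | None = None
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Count-level shortcut: genus x sample Dirichlet-multinomial counts
    drawn directly from the study design (no reads).  On the
    disjoint-proteome reference, classifying the corpus reproduces these
    counts exactly, so statistical power studies can iterate seeds here.
    Returns (counts, groups, per-sample true proportions)."""
    rng = np.random.default_rng([seed if seed is not None else config.seed, 4])
    conc = config.dirichlet_concentration
    groups = config.groups()
    counts, props = {}, {}
    for sample in config.sample_ids():
        mean_props = config.group_proportions(groups[sample])
        p = rng.dirichlet(conc * mean_props) if conc > 0 else mean_props
        counts[sample] = rng.multinomial(config.depth_reads, p)
        props[sample] = p
    index = config.genus_names()
    return (
        pd.DataFrame(counts, index=index),
        groups,
        pd.DataFrame(props, index=index),
    )


# -- gene-family matches -------------------------------------------------


@dataclass
class GeneMatchSimulation:
    """Simulated profile-match tables with post-filter truth counts."""

    records: dict[str, list[MatchRecord]]  # per sample, decoys included
    truth_counts: pd.DataFrame  # family x sample, counts after filtering
    families: dict[str, GeneFamilyDef]
    marker_set: tuple[tuple[str, int], ...]
    marker_hits: dict[str, dict[str, int]]  # sample -> marker -> hits
    total_reads: dict[str, int]
    total_bases: dict[str, int]
    true_ags: pd.Series
    groups: dict[str, str]

    def write_domtblout(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for sample, recs in self.records.items():
            path = outdir / f"{sample}.domtblout"
            write_domtblout(recs, path, self.families)
            paths[sample] = path
        return paths


def simulate_gene_matches(
    reference: Reference | None,
    config: SimulationConfig,
    families: Sequence[GeneFamilyDef] | None = None,
) -> GeneMatchSimulation:
    """Per-sample true family counts ~ Poisson(base x fold change), emitted
    as domtblout rows that pass the e-value/coverage filters, plus a
    complement of decoy rows that fail them (so filtering the emitted
    table recovers the truth counts exactly).  Marker hits for the
    genome-equivalents estimator are drawn from the reference genome
    sizes when a reference is given."""
    rng = np.random.default_rng([config.seed, 3])
    fams = registry_by_id(families if families is not None else builtin_family_registry())
    groups = config.groups()
    pass_frac = config.match_pass_fraction
    if not (0 < pass_frac <= 1):
        raise ValueError("match_pass_fraction must be in (0, 1]")
    # per-family base rate: lognormal spread around the configured mean
    base = {
        fid: config.family_base_count * float(np.exp(rng.normal(0.0, 0.5)))
        for fid in fams
    }
    records: dict[str, list[MatchRecord]] = {}
    truth = {}
    marker_hits: dict[str, dict[str, int]] = {}
    total_reads, total_bases, true_ags = {}, {}, {}
    for sample in config.sample_ids():
        recs: list[MatchRecord] = []
        col = {}
        for fid, fam in fams.items():
            fc = config.family_effects.get(fid, 1.0) if groups[sample] == GROUP_CHITIN else 1.0
            lam = base[fid] * fc
            n_true = int(rng.poisson(lam)) if lam > 0 else 0
            col[fid] = n_true
            L = fam.model_length_aa
            min_span = math.ceil(0.6 * L)
            for j in range(n_true):
                e_value = 10.0 ** (-rng.uniform(10.0, 40.0))
                span_len = int(rng.integers(min_span, L + 1))
                start = int(rng.integers(1, L - span_len + 2))
                recs.append(
                    MatchRecord(
                        read_id=f"{sample}_{fid}_m{j:05d}",
                        family_id=fid,
                        e_value=e_value,
                        hmm_span=(start, start + span_len - 1),
                        bitscore=float(rng.uniform(40, 300)),
                    )
                )
            n_decoy = int(round(n_true * (1 - pass_frac) / pass_frac))
            for j in range(n_decoy):
                if rng.random() < 0.5:  # fail on e-value
                    e_value = 10.0 ** (-rng.uniform(2.0, 9.0))
                    span_len = int(rng.integers(min_span, L + 1))
                else:  # fail on model coverage
                    e_value = 10.0 ** (-rng.uniform(10.0, 40.0))
                    span_len = max(1, int(0.58 * L * rng.uniform(0.1, 1.0)))
                start = int(rng.integers(1, L - span_len + 2))
                recs.append(
                    MatchRecord(
                        read_id=f"{sample}_{fid}_d{j:05d}",
                        family_id=fid,
                        e_value=e_value,
                        hmm_span=(start, start + span_len - 1),
                        bitscore=float(rng.uniform(5, 40)),
                    )
                )
        records[sample] = recs
        truth[sample] = col
        total_reads[sample] = config.depth_reads
        total_bases[sample] = config.depth_reads * config.read_len_nt
        hits: dict[str, int] = {}
        if reference is not None:
            props = config.group_proportions(groups[sample])
            genus_counts = rng.multinomial(config.depth_reads, props)
            sizes = [
                len(reference.genomes[reference.species_of_genus[g]])
                for g in reference.genus_taxids
            ]
            for marker_id, length_aa in DEFAULT_MARKER_SET:
                h = 0
                for c, G in zip(genus_counts, sizes):
                    h += int(rng.binomial(int(c), min(1.0, 3.0 * length_aa / G)))
                hits[marker_id] = h
            denom = sum(c / G for c, G in zip(genus_counts, sizes))
            true_ags[sample] = config.depth_reads / denom if denom > 0 else float("nan")
        else:
            true_ags[sample] = float("nan")
        marker_hits[sample] = hits
    fam_index = list(fams)
    truth_df = pd.DataFrame(
        {s: [truth[s][f] for f in fam_index] for s in config.sample_ids()},
        index=fam_index,
    )
    return GeneMatchSimulation(
        records=records,
        truth_counts=truth_df,
        families=fams,
        marker_set=DEFAULT_MARKER_SET,
        marker_hits=marker_hits,
        total_reads=total_reads,
        total_bases=total_bases,
        true_ags=pd.Series(true_ags),
        groups=groups,
    )
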
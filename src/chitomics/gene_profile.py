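"""Functional gene profiling: ORFs, profile-match filtering, RPKG.

Reads (or their ORFs) are matched against profile models of chitin-cycle
glycoside-hydrolase families and nitrogen-cycle genes.  Matches are
ingested in the HMMER3 per-domain tabular dialect (domtblout), filtered on
e-value and model coverage, deduplicated to one count per read and family,
and normalized as RPKG: matched reads per kilobase of model per genome
equivalent.  Genome equivalents come from a transparent single-copy-marker
average-genome-size estimator honoring the contract
``genome_equivalents = total_bases / average_genome_size``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import six_frame_translate

CHITIN_CATEGORIES = {
    "GH18": "chitinase_GH18",
    "GH19": "chitinase_GH19",
    "GH20": "nacetylglucosaminidase_GH20",
    "CE4": "deacetylase_CE4",
    "GH5": "deacetylase_GH5",
    "GH7": "deacetylase_GH7",
    "GH8": "deacetylase_GH8",
    "GH46": "chitosanase_GH46",
    "GH75": "chitosanase_GH75",
    "GH80": "chitosanase_GH80",
}

# Model lengths (aa) are artifact defaults: the profile databases publish
# per-model lengths, which users should supply for real runs.
_CHITIN_LENGTHS = {
    "GH18": 330, "GH19": 215, "GH20": 480, "CE4": 150, "GH5": 280,
    "GH7": 430, "GH8": 320, "GH46": 230, "GH75": 220, "GH80": 240,
}
_NCYCLE_LENGTHS = {
    "amoA_AOA": 200, "amoA_AOB": 250, "amoB": 420, "napA": 830,
    "nrfA": 480, "narG": 1250, "nirS": 560, "nirK": 340, "norB": 460,
    "nosZ": 610, "nosZ_atypical1": 600, "nosZ_atypical2": 620,
    "nifH": 290, "ureC": 570,
}


class UnknownFamilyError(KeyError):
    """A match record names a family absent from the registry."""


class DomtbloutParseError(ValueError):
    """A domtblout line could not be parsed (message names the line number)."""


@dataclass(frozen=True)
class GeneFamilyDef:
    """One profile family: a chitin-cycle CAZy family or an N-cycle gene model."""

    family_id: str
    category: str
    model_length_aa: int
    gene_symbol: str | None = None

    def __post_init__(self):
        if self.model_length_aa <= 0:
            raise ValueError("model_length_aa must be positive")


@dataclass(frozen=True)
class MatchRecord:
    """One profile-model domain match of a read/ORF."""

    read_id: str
    family_id: str
    e_value: float
    hmm_span: tuple[int, int]  # 1-based inclusive model coordinates
    bitscore: float = 0.0

    def __post_init__(self):
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.hmm_span[0] > self.hmm_span[1]:
            raise ValueError("hmm_span from > to")


@dataclass(frozen=True)
class SampleStats:
    """Per-sample sequencing depth and genome-equivalents summary."""

    sample_id: str
    total_reads: int
    total_bases: int
    average_genome_size_bp: float
    genome_equivalents: float

    def __post_init__(self):
        if self.average_genome_size_bp <= 0 or self.genome_equivalents <= 0:
            raise ValueError("AGS and genome equivalents must be positive")
        expected = self.total_bases / self.average_genome_size_bp
        if abs(expected - self.genome_equivalents) > 1e-9 * max(expected, 1.0):
            raise ValueError("genome_equivalents != total_bases / AGS")


def builtin_family_registry() -> list[GeneFamilyDef]:
    """The study's gene-family registry.

    Ten chitin-cycle CAZy families (GH18/GH19 chitinases, GH20
    N-acetylglucosaminidases, CE4/GH5/GH7/GH8 deacetylases, GH46/GH75/GH80
    chitosanases) plus fourteen N-cycle gene models (amoA split into
    archaeal AOA and bacterial AOB, amoB, napA, nrfA, narG, nirS, nirK,
    norB, nosZ with two atypical clades, nifH, ureC).  hao, nor, nasA and
    nir have no public profile models and are deliberately absent.
    """
    families = [
        GeneFamilyDef(fid, CHITIN_CATEGORIES[fid], _CHITIN_LENGTHS[fid])
        for fid in CHITIN_CATEGORIES
    ]
    families += [
        GeneFamilyDef(fid, "ncycle", length, gene_symbol=fid)
        for fid, length in _NCYCLE_LENGTHS.items()
    ]
    return families


def registry_by_id(families: Iterable[GeneFamilyDef]) -> dict[str, GeneFamilyDef]:
    out: dict[str, GeneFamilyDef] = {}
    for fam in families:
        if fam.family_id in out:
            raise ValueError(f"duplicate family_id {fam.family_id}")
        out[fam.family_id] = fam
    return out


def save_registry_yaml(families: Iterable[GeneFamilyDef], path) -> None:
    import yaml

    data = [
        {
            "family_id": f.family_id,
            "category": f.category,
            "model_length_aa": f.model_length_aa,
            "gene_symbol": f.gene_symbol,
        }
        for f in families
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_registry_yaml(path) -> list[GeneFamilyDef]:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    return [
        GeneFamilyDef(
            d["family_id"], d["category"], d["model_length_aa"], d.get("gene_symbol")
        )
        for d in data
    ]


# -- ORF extraction ------------------------------------------------------


def find_orfs(dna: str, min_len_aa: int = 30) -> list[str]:
    """All maximal stop-free translated stretches >= ``min_len_aa`` across
    the six reading frames (a transparent stand-in for a gene caller)."""
    orfs = []
    for peptide in six_frame_translate(dna):
        for stretch in peptide.split("*"):
            if len(stretch) >= min_len_aa:
                orfs.append(stretch)
    return orfs


# -- domtblout IO --------------------------------------------------------

_N_DOMTBL_FIELDS = 22  # before the free-text description


def read_domtblout(source) -> list[MatchRecord]:
    """Parse HMMER3 per-domain tabular output.

    Whitespace-delimited; ``#`` comment lines skipped.  Field mapping:
    target name -> read id, query name -> family id, i-Evalue -> e_value,
    hmm from/to -> model-coordinate span, this-domain score -> bitscore.
    """
    if isinstance(source, (str, Path)):
        fh = open(source)
        close = True
    else:
        fh, close = source, False
    records = []
    try:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _N_DOMTBL_FIELDS:
                raise DomtbloutParseError(
                    f"line {lineno}: expected >= {_N_DOMTBL_FIELDS} fields, "
                    f"got {len(fields)}"
                )
            try:
                rec = MatchRecord(
                    read_id=fields[0],
                    family_id=fields[3],
                    e_value=float(fields[12]),
                    hmm_span=(int(fields[15]), int(fields[16])),
                    bitscore=float(fields[13]),
                )
            except ValueError as exc:
                raise DomtbloutParseError(f"line {lineno}: {exc}") from None
            records.append(rec)
    finally:
        if close:
            fh.close()
    return records


def write_domtblout(records: Iterable[MatchRecord], path, families: Mapping[str, GeneFamilyDef] | None = None) -> None:
    """Emit records in the domtblout dialect (round-trips with the reader)."""
    with open(path, "w") as fh:
        fh.write("# target name  tacc tlen query name  qacc qlen  E-value score bias "
                 "#  of  c-Evalue  i-Evalue  score  bias  hmm_from hmm_to "
                 "ali_from ali_to env_from env_to acc description\n")
        for r in records:
            qlen = families[r.family_id].model_length_aa if families else 0
            fh.write(
                f"{r.read_id} - 0 {r.family_id} - {qlen} "
                f"{r.e_value:.3g} {r.bitscore:.1f} 0.0 1 1 "
                f"{r.e_value:.3g} {r.e_value:.3g} {r.bitscore:.1f} 0.0 "
                f"{r.hmm_span[0]} {r.hmm_span[1]} 1 1 1 1 0.90 -\n"
            )


# -- filtering, counting, normalization ----------------------------------


def filter_matches(
    records: Iterable[MatchRecord],
    families: Mapping[str, GeneFamilyDef],
    e_max: float = 1e-10,
    cov_min: float = 0.60,
) -> list[MatchRecord]:
    """Keep matches with e-value <= ``e_max`` and model coverage >= ``cov_min``.

    Coverage is measured on the profile model:
    ``(hmm_to - hmm_from + 1) / model_length_aa``; both thresholds are
    inclusive.  Idempotent.
    """
    kept = []
    for r in records:
        fam = families.get(r.family_id)
        if fam is None:
            raise UnknownFamilyError(r.family_id)
        span = r.hmm_span[1] - r.hmm_span[0] + 1
        if r.e_value <= e_max and span / fam.model_length_aa >= cov_min:
            kept.append(r)
    return kept


def count_matches(
    records: Iterable[MatchRecord],
    families: Mapping[str, GeneFamilyDef],
) -> dict[str, int]:
    """Per-family matched-read counts.

    A read contributes at most once to a given family (duplicate domains
    collapse); one read may count toward several families.  Every registry
    family appears in the output, zero when unmatched.
    """
    seen: set[tuple[str, str]] = set()
    counts = {fid: 0 for fid in families}
    for r in records:
        if r.family_id not in families:
            raise UnknownFamilyError(r.family_id)
        key = (r.read_id, r.family_id)
        if key not in seen:
            seen.add(key)
            counts[r.family_id] += 1
    return counts


def estimate_genome_equivalents(
    sample_id: str,
    total_reads: int,
    total_bases: int,
    marker_set: Sequence[tuple[str, int]] | None = None,
    marker_hits: Mapping[str, int] | None = None,
    average_genome_size_bp: float | None = None,
) -> SampleStats:
    """Estimate average genome size (AGS) and genome equivalents.

    Each single-copy marker of length L aa occupies 3L bp per genome, so
    the fraction of reads hitting it estimates 3L / AGS:
    ``AGS_j = 3 L_j * total_reads / hits_j``.  The sample AGS is the
    geometric mean over markers with hits; genome equivalents are
    ``total_bases / AGS``.  Supplying ``average_genome_size_bp`` bypasses
    the marker estimator.
    """
    if average_genome_size_bp is None:
        if not marker_set or marker_hits is None:
            raise ValueError("need marker_set and marker_hits, or an explicit AGS")
        logs = []
        for marker_id, length_aa in marker_set:
            hits = marker_hits.get(marker_id, 0)
            if hits > 0:
                logs.append(math.log(3.0 * length_aa * total_reads / hits))
        if not logs:
            raise ValueError("no marker has hits; cannot estimate genome size")
        average_genome_size_bp = math.exp(sum(logs) / len(logs))
    ge = total_bases / average_genome_size_bp
    return SampleStats(
        sample_id=sample_id,
        total_reads=total_reads,
        total_bases=total_bases,
        average_genome_size_bp=average_genome_size_bp,
        genome_equivalents=ge,
    )


def rpkg(
    count: int,
    model_length_aa: int,
    genome_equivalents: float,
    length_unit: str = "nt",
) -> float:
    """Reads per kilobase of model per genome equivalent.

    With the default nucleotide unit the model length is converted
    aa -> kb as ``model_length_aa * 3 / 1000`` (reads are nucleotide);
    ``length_unit="aa"`` divides by ``model_length_aa / 1000`` instead.
    Invariant under uniform depth scaling (count and GE scale together).
    """
    if genome_equivalents <= 0:
        raise ValueError("genome_equivalents must be positive")
    if length_unit == "nt":
        length_kb = model_length_aa * 3 / 1000.0
    elif length_unit == "aa":
        length_kb = model_length_aa / 1000.0
    else:
        raise ValueError(f"unknown length_unit {length_unit!r}")
    return count / length_kb / genome_equivalents


def rpkg_table(
    counts: pd.DataFrame,
    families: Mapping[str, GeneFamilyDef],
    sample_stats: Mapping[str, SampleStats],
    length_unit: str = "nt",
) -> pd.DataFrame:
    """RPKG-normalize a family x sample count matrix."""
    values = np.zeros(counts.shape, dtype=float)
    for j, sample in enumerate(counts.columns):
        ge = sample_stats[sample].genome_equivalents
        for i, fid in enumerate(counts.index):
            values[i, j] = rpkg(
                int(counts.iloc[i, j]), families[fid].model_length_aa, ge,
                length_unit=length_unit,
            )
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)
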
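"""End-to-end orchestration of the taxonomic and functional analyses.

A strict YAML config names the per-sample inputs (reads, profile-match
tables), the reference (taxdump + labelled proteome or a prebuilt k-mer
index), the treatment groups, and every analysis threshold.  Reruns with
the same config and seed produce identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as _classify
from . import diffstats, gene_profile
from .peptide_index import KmerIndex, build_index, read_protein_fasta
from .tables import CountTable
from .taxonomy import TaxonomyTree

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The pipeline config is malformed (unknown key, missing input, ...)."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown YAML keys are rejected."""

    output_dir: str = "chitomics_out"
    reads: dict[str, str] = field(default_factory=dict)  # sample -> FASTA/FASTQ
    domtblout: dict[str, str] = field(default_factory=dict)  # sample -> matches
    groups: dict[str, str] = field(default_factory=dict)  # sample -> treatment
    nodes_dmp: str | None = None
    names_dmp: str | None = None
    proteome_fasta: str | None = None
    index_path: str | None = None
    registry_yaml: str | None = None
    sample_stats: dict[str, dict] = field(default_factory=dict)
    # classification parameters
    k: int = 9
    consensus_fraction: float = 0.8
    # profile-match filter
    e_max: float = 1e-10
    cov_min: float = 0.60
    length_unit: str = "nt"
    # statistics
    min_cpm: float = 4.0
    min_samples: int = 4
    tagwise: bool = False
    prior_df: float = 10.0
    n_perm: int = 9999
    seed: int = 0
    alpha: float = 0.05
    # upstream QC settings recorded for provenance only (reads arrive merged)
    provenance: dict = field(
        default_factory=lambda: {
            "merge_min_length_bp": 100,
            "merge_max_length_bp": 500,
            "merge_min_overlap_bp": 100,
            "merge_quality_threshold": 30,
        }
    )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config must be a YAML mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def validate_taxonomic(self) -> None:
        if not self.reads:
            raise ConfigError("no read files configured (reads:)")
        self._validate_groups(self.reads)
        if self.index_path is None and (
            self.proteome_fasta is None or self.nodes_dmp is None
        ):
            raise ConfigError("need index_path or proteome_fasta + nodes_dmp")

    def validate_functional(self) -> None:
        if not self.domtblout:
            raise ConfigError("no match tables configured (domtblout:)")
        self._validate_groups(self.domtblout)
        for sample in self.domtblout:
            if sample not in self.sample_stats:
                raise ConfigError(f"sample_stats missing for sample {sample!r}")

    def _validate_groups(self, samples) -> None:
        missing = [s for s in samples if s not in self.groups]
        if missing:
            raise ConfigError(f"samples without a group: {missing}")


def _load_reference(config: PipelineConfig) -> tuple[TaxonomyTree, KmerIndex]:
    tree = TaxonomyTree.from_taxdump(config.nodes_dmp, config.names_dmp)
    if config.index_path and Path(config.index_path).exists():
        index = KmerIndex.load(config.index_path)
    else:
        proteins = read_protein_fasta(config.proteome_fasta)
        index = build_index(proteins, tree, k=config.k)
        if config.index_path:
            index.save(config.index_path)
    return tree, index


def run_taxonomic_analysis(config: PipelineConfig) -> dict:
    """Classify all samples, build the genus table, and run the count
    statistics (CPM filter, TMM, qCML, NB exact test, BH) plus PERMANOVA
    and the dispersion-homogeneity check on Bray-Curtis distances."""
    config.validate_taxonomic()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, index = _load_reference(config)
    logger.info("reference loaded: %d taxa, %d k-mers", len(tree), len(index))

    assignments = {}
    fractions = {}
    for sample, path in config.reads.items():
        alist, frac = _classify.classify_sample(
            _classify.iter_reads(path), index, tree, f=config.consensus_fraction
        )
        assignments[sample] = alist
        fractions[sample] = frac
        logger.info(
            "sample %s: %d reads, fraction assigned %.3f", sample, len(alist), frac
        )
        _classify.write_assignments_tsv(
            outdir / f"{sample}.assignments.tsv", alist, tree
        )

    table = _classify.build_genus_table(assignments, tree)
    named = table.counts.rename(
        index=lambda t: tree.name(t) or str(t)
    )
    CountTable(named, table.library_sizes).to_tsv(outdir / "genus_table.tsv")

    results = diffstats.differential_abundance(
        named,
        config.groups,
        library_sizes=table.library_sizes,
        min_cpm=config.min_cpm,
        min_samples=config.min_samples,
        tagwise=config.tagwise,
        prior_df=config.prior_df,
        alpha=config.alpha,
    )
    results.to_csv(outdir / "genus_diff.tsv", sep="\t", index_label="genus")

    dist = diffstats.bray_curtis(named)
    dist.to_csv(outdir / "bray_curtis.tsv", sep="\t")
    labels = [config.groups[s] for s in named.columns]
    perm = diffstats.permanova(
        dist, labels, n_perm=config.n_perm, seed=config.seed
    )
    disp = diffstats.dispersion_homogeneity(
        dist, labels, n_perm=min(config.n_perm, 999), seed=config.seed
    )
    summary = {
        "stage": "taxonomic",
        "n_samples": len(assignments),
        "fraction_assigned": fractions,
        "mean_fraction_assigned": float(np.mean(list(fractions.values()))),
        "n_genera": int(named.shape[0]),
        "n_tested": int(results.shape[0]),
        "n_significant": int(results["significant"].sum()) if len(results) else 0,
        "permanova_pseudo_f": _json_num(perm.pseudo_f),
        "permanova_p": perm.p_value,
        "permanova_exhaustive": perm.exhaustive,
        "betadisper_p": disp.p_value,
    }
    with open(outdir / "taxonomic_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {
        "genus_table": table,
        "results": results,
        "permanova": perm,
        "betadisper": disp,
        "summary": summary,
    }


def run_functional_analysis(config: PipelineConfig) -> dict:
    """Filter and count profile matches per sample, estimate genome
    equivalents, RPKG-normalize, and run the quasi-Poisson treatment test
    with BH adjustment."""
    config.validate_functional()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.registry_yaml:
        families = gene_profile.registry_by_id(
            gene_profile.load_registry_yaml(config.registry_yaml)
        )
    else:
        families = gene_profile.registry_by_id(gene_profile.builtin_family_registry())

    count_cols = {}
    stats = {}
    for sample, path in config.domtblout.items():
        records = gene_profile.read_domtblout(path)
        kept = gene_profile.filter_matches(
            records, families, e_max=config.e_max, cov_min=config.cov_min
        )
        logger.info("sample %s: %d matches, %d pass filters", sample, len(records), len(kept))
        count_cols[sample] = gene_profile.count_matches(kept, families)
        ss = config.sample_stats[sample]
        stats[sample] = gene_profile.estimate_genome_equivalents(
            sample,
            total_reads=int(ss["total_reads"]),
            total_bases=int(ss["total_bases"]),
            marker_set=[tuple(m) for m in ss.get("marker_set", [])] or None,
            marker_hits=ss.get("marker_hits"),
            average_genome_size_bp=ss.get("average_genome_size_bp"),
        )

    fam_index = list(families)
    counts = pd.DataFrame(
        {s: [count_cols[s][f] for f in fam_index] for s in config.domtblout},
        index=fam_index,
    )
    counts.to_csv(outdir / "family_counts.tsv", sep="\t", index_label="family")
    rpkg = gene_profile.rpkg_table(
        counts, families, stats, length_unit=config.length_unit
    )
    rpkg.to_csv(outdir / "family_rpkg.tsv", sep="\t", index_label="family")

    # per-sample log exposure: log(genome equivalents); the per-family
    # model-length term is constant across samples and cancels in the
    # treatment contrast
    offsets = pd.Series(
        {s: math.log(stats[s].genome_equivalents) for s in counts.columns}
    )
    results = diffstats.quasi_poisson_test(counts, config.groups, offsets=offsets)
    results["fdr"] = diffstats.bh_adjust(results["p_value"].fillna(1.0))
    results["significant"] = results["fdr"] < config.alpha
    results.to_csv(outdir / "family_diff.tsv", sep="\t", index_label="family")
    summary = {
        "stage": "functional",
        "n_samples": int(counts.shape[1]),
        "n_families": int(counts.shape[0]),
        "n_significant": int(results["significant"].sum()),
        "genome_equivalents": {s: stats[s].genome_equivalents for s in stats},
    }
    with open(outdir / "functional_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return {"counts": counts, "rpkg": rpkg, "results": results, "summary": summary}


def _json_num(x: float):
    return x if math.isfinite(x) else str(x)
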
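"""Feature x sample count tables shared by the taxonomic and functional stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class CountTable:
    """An integer count matrix (features as rows, samples as columns) with
    per-sample library sizes.

    For taxon tables the library size is the number of assigned reads in
    the sample (which may exceed the column sum when some assignments fall
    above the table's rank); for gene tables it defaults to the column sum.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def sample_ids(self) -> list:
        return list(self.counts.columns)

    @property
    def feature_ids(self) -> list:
        return list(self.counts.index)

    def relative_abundance(self) -> pd.DataFrame:
        """Counts divided by library size, per sample."""
        lib = self.library_sizes.replace(0, pd.NA)
        return self.counts.div(lib, axis=1).fillna(0.0).astype(float)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.loc["__library_size__"] = self.library_sizes
        out.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="feature")
        lib = None
        if "__library_size__" in df.index:
            lib = df.loc["__library_size__"]
            df = df.drop(index="__library_size__")
        return cls(counts=df, library_sizes=lib)
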
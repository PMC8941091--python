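"""Core tabular containers for paired DNA/RNA OTU data.

The pipeline's universal currency is the :class:`CountTable`: an OTU x sample
matrix of non-negative integer read counts together with per-sample metadata
(habitat, season, nucleic-acid type and the identifier that links each RNA
sample to its DNA partner).  After normalization the matrix becomes a
:class:`NormalizedTable` holding real-valued "CSS reads".
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

DNA = "DNA"
RNA = "RNA"

#: metadata columns every table must carry
METADATA_COLUMNS = ("habitat", "season", "nucleic_acid", "pair_id")


def _check_metadata(counts: pd.DataFrame, metadata: pd.DataFrame) -> None:
    if not counts.columns.is_unique:
        raise ValueError("sample ids must be unique")
    if not counts.index.is_unique:
        raise ValueError("OTU ids must be unique")
    missing = set(counts.columns) - set(metadata.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
    for col in METADATA_COLUMNS:
        if col not in metadata.columns:
            raise ValueError(f"metadata lacks required column {col!r}")
    bad = set(metadata["nucleic_acid"]) - {DNA, RNA}
    if bad:
        raise ValueError(f"nucleic_acid must be DNA or RNA, got {sorted(bad)}")


@dataclasses.dataclass
class CountTable:
    """OTU x sample read counts with aligned sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id with one column per sample; entries are
        non-negative integers.
    metadata
        DataFrame indexed by sample id with at least the columns
        ``habitat``, ``season``, ``nucleic_acid`` (``"DNA"`` | ``"RNA"``) and
        ``pair_id`` (empty string for unpaired samples).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        _check_metadata(self.counts, self.metadata)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts are not allowed")
        # align metadata rows to column order
        self.metadata = self.metadata.loc[list(self.counts.columns)]

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def select_samples(self, sample_ids) -> "CountTable":
        ids = list(sample_ids)
        return CountTable(self.counts[ids].copy(), self.metadata.loc[ids].copy())

    def dna(self) -> "CountTable":
        return self.select_samples(self.metadata.index[self.metadata["nucleic_acid"] == DNA])

    def rna(self) -> "CountTable":
        return self.select_samples(self.metadata.index[self.metadata["nucleic_acid"] == RNA])

    def pairs(self) -> list[tuple[str, str, str]]:
        """Return ``(dna_sample, rna_sample, pair_id)`` for every matched pair.

        A pair id must map to exactly one DNA and one RNA sample; ids present
        on only one side are ignored (unpaired samples are legitimate — the
        source study had far more DNA than RNA samples).
        """
        meta = self.metadata
        out = []
        for pid, grp in meta[meta["pair_id"] != ""].groupby("pair_id", sort=True):
            d = grp.index[grp["nucleic_acid"] == DNA]
            r = grp.index[grp["nucleic_acid"] == RNA]
            if len(d) > 1 or len(r) > 1:
                raise ValueError(f"pair_id {pid!r} maps to multiple samples of one type")
            if len(d) == 1 and len(r) == 1:
                out.append((d[0], r[0], pid))
        return out

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.metadata.copy())

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, counts_path, metadata_path) -> None:
        self.counts.rename_axis("otu_id").to_csv(counts_path, sep="\t")
        self.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, metadata_path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", index_col=0, keep_default_na=False)
        return cls(counts, meta)

    def to_biom(self, path) -> None:
        """Write the table as BIOM v2.1 (HDF5)."""
        import biom
        import biom.util

        t = biom.Table(
            self.counts.to_numpy(),
            observation_ids=self.otu_ids,
            sample_ids=self.sample_ids,
            sample_metadata=self.metadata.to_dict(orient="records"),
        )
        with biom.util.biom_open(str(path), "w") as fh:
            t.to_hdf5(fh, "reactscape")

    @classmethod
    def from_biom(cls, path) -> "CountTable":
        import biom

        t = biom.load_table(str(path))
        counts = pd.DataFrame(
            t.matrix_data.toarray(),
            index=t.ids("observation"),
            columns=t.ids("sample"),
        ).astype(int)
        meta = pd.DataFrame(
            [dict(t.metadata(s, "sample") or {}) for s in t.ids("sample")],
            index=t.ids("sample"),
        )
        return cls(counts, meta)


@dataclasses.dataclass
class NormalizedTable:
    """Real-valued OTU x sample matrix after library-size normalization."""

    values: pd.DataFrame
    metadata: pd.DataFrame
    scaling_factors: pd.Series
    method: str = "css"

    def __post_init__(self) -> None:
        _check_metadata(self.values, self.metadata)
        if (self.scaling_factors <= 0).any():
            raise ValueError("scaling factors must be strictly positive")
        self.metadata = self.metadata.loc[list(self.values.columns)]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.index)

    def select_samples(self, sample_ids) -> "NormalizedTable":
        ids = list(sample_ids)
        return NormalizedTable(
            self.values[ids].copy(),
            self.metadata.loc[ids].copy(),
            self.scaling_factors.loc[ids].copy(),
            self.method,
        )

    def pairs(self) -> list[tuple[str, str, str]]:
        return CountTable.pairs(self)  # same metadata contract

    def to_tsv(self, values_path, metadata_path=None) -> None:
        self.values.rename_axis("otu_id").to_csv(values_path, sep="\t")
        if metadata_path is not None:
            self.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def strata(metadata: pd.DataFrame, by=("habitat", "season")) -> list[tuple]:
    """Distinct habitat x season (by default) combinations, in sorted order."""
    cols = list(by)
    uniq = metadata[cols].drop_duplicates().sort_values(cols)
    return [tuple(r) for r in uniq.itertuples(index=False)]


def make_metadata(sample_ids, habitat, season, nucleic_acid, pair_id) -> pd.DataFrame:
    """Assemble a metadata frame from per-sample sequences (scalars broadcast)."""
    n = len(sample_ids)

    def _col(v):
        return [v] * n if np.isscalar(v) or isinstance(v, str) else list(v)

    return pd.DataFrame(
        {
            "habitat": _col(habitat),
            "season": _col(season),
            "nucleic_acid": _col(nucleic_acid),
            "pair_id": _col(pair_id),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
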
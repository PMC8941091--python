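"""Table-level corrections and normalization.

Order of application mirrors the analysis workflow: phantom-taxon correction
(RNA observed where DNA is absent → DNA set to 1), stratum-wise singleton
filtering (an OTU observation appearing in a single sample of a habitat x
season x nucleic-acid stratum with fewer than 10 reads is unreliable),
cumulative sum scaling (CSS), and optional rarefaction for sensitivity
analysis.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .tables import CountTable, NormalizedTable


def correct_phantoms(table: CountTable) -> CountTable:
    """Set DNA counts of phantom taxa (RNA > 0, DNA = 0) to 1.

    Operates pairwise: for every matched DNA/RNA sample pair, any OTU with a
    positive RNA count but a zero DNA count gets DNA = 1.  No DNA count is
    ever decreased and nothing other than 0 → 1 promotions happens.
    """
    out = table.copy()
    for dna_s, rna_s, _ in table.pairs():
        mask = (out.counts[dna_s] == 0) & (out.counts[rna_s] > 0)
        out.counts.loc[mask, dna_s] = 1
    return out


@dataclasses.dataclass
class SingletonReport:
    removed: pd.DataFrame  # columns: otu_id, sample_id, habitat, season, nucleic_acid, count

    def __len__(self) -> int:
        return len(self.removed)


def filter_combination_singletons(
    table: CountTable, min_reads: int = 10
) -> tuple[CountTable, SingletonReport]:
    """Zero out unreliable within-stratum singleton observations.

    Within each habitat x season x nucleic-acid stratum, an OTU present in
    exactly one sample of that stratum with fewer than ``min_reads`` reads is
    set to 0.  Observations with ``count >= min_reads`` are kept even when
    they are singletons.  The operation is idempotent.
    """
    out = table.copy()
    rows = []
    for (hab, season, nat), grp in table.metadata.groupby(
        ["habitat", "season", "nucleic_acid"], sort=True
    ):
        sub = out.counts[list(grp.index)]
        presence = (sub > 0).sum(axis=1)
        singleton_otus = presence.index[presence == 1]
        if len(singleton_otus) == 0:
            continue
        block = sub.loc[singleton_otus]
        # position of the single positive observation per OTU
        for otu, row in block.iterrows():
            s = row.idxmax()
            c = row[s]
            if 0 < c < min_reads:
                out.counts.loc[otu, s] = 0
                rows.append((otu, s, hab, season, nat, int(c)))
    report = SingletonReport(
        pd.DataFrame(
            rows, columns=["otu_id", "sample_id", "habitat", "season", "nucleic_acid", "count"]
        )
    )
    return out, report


def css_normalize(
    table: CountTable, quantile: float = 0.5, scale_constant: float = 1000.0
) -> NormalizedTable:
    """Cumulative sum scaling of read counts.

    For sample j, the scaling factor s_j is the sum of counts less than or
    equal to q_j, the ``quantile`` of the sample's *nonzero* counts; values
    are counts / s_j * ``scale_constant``.  Zeros stay zero and relative
    patterns within a sample are untouched — only the per-sample scale
    changes.

    With ``quantile=None`` the quantile is chosen adaptively: the smallest
    candidate quantile (on a 0.05 grid from 0.5) at which the median
    scaling factor across samples stabilises (relative change between
    successive candidates below 10%).
    """
    counts = table.counts.to_numpy(dtype=float)
    if (counts.sum(axis=0) == 0).any():
        bad = [s for s, tot in zip(table.sample_ids, counts.sum(axis=0)) if tot == 0]
        raise ValueError(f"all-zero samples cannot be normalized: {bad[:5]}")
    if quantile is None:
        quantile = _adaptive_quantile(counts)
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    factors = _css_factors(counts, quantile)
    values = counts / factors * scale_constant
    return NormalizedTable(
        values=pd.DataFrame(values, index=table.counts.index, columns=table.counts.columns),
        metadata=table.metadata.copy(),
        scaling_factors=pd.Series(factors, index=table.counts.columns, name="css_factor"),
        method=f"css(q={quantile:g})",
    )


def _css_factors(counts: np.ndarray, quantile: float) -> np.ndarray:
    factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        col = counts[:, j]
        nz = col[col > 0]
        q = np.quantile(nz, quantile)
        factors[j] = col[col <= q].sum()
    return factors


def _adaptive_quantile(counts: np.ndarray, grid_step: float = 0.05, rel_tol: float = 0.1) -> float:
    qs = np.arange(0.5, 1.0, grid_step)
    med = np.array([np.median(_css_factors(counts, q)) for q in qs])
    for i in range(1, len(qs)):
        if abs(med[i] - med[i - 1]) / max(med[i - 1], 1e-12) < rel_tol:
            return float(qs[i - 1])
    return float(qs[-1])


def rarefy(table: CountTable, depth: int, seed: int = 0) -> tuple[CountTable, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with library size below ``depth`` are dropped and reported.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.counts.sum(axis=0)
    dropped = [s for s in table.sample_ids if totals[s] < depth]
    kept = [s for s in table.sample_ids if totals[s] >= depth]
    if not kept:
        raise ValueError(f"rarefaction depth {depth} exceeds every library size")
    rng = np.random.default_rng(seed)
    cols = {}
    for s in kept:
        col = table.counts[s].to_numpy()
        if col.sum() == depth:
            cols[s] = col
        else:
            cols[s] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(cols, index=table.counts.index)
    return CountTable(counts, table.metadata.loc[kept].copy()), dropped
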
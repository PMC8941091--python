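"""Continuum origin classification and reactive/unreactive partitioning.

Each OTU's *potential origin* is the first habitat — in the fixed
terrestrial→aquatic order — in which it was ever detected in DNA, pooling
seasons and years.  Within each local pool (habitat x season), an OTU's
percent contribution to the DNA and RNA read totals is computed; the median
of all nonzero %RNA contributions pooled across strata is the potential
reactivity threshold (PRT).  Taxa whose local %RNA exceeds the PRT are
*reactive*; taxa at or below it, or with no RNA at all, are *unreactive* in
that stratum.  An OTU may switch classes between strata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic import DEFAULT_HABITAT_ORDER
from .tables import CountTable, strata

REACTIVE = "reactive"
UNREACTIVE_BELOW_PRT = "unreactive_below_prt"
UNREACTIVE_NO_RNA = "unreactive_no_rna"


def classify_origin(
    dna: CountTable, habitat_order=DEFAULT_HABITAT_ORDER, other_label: str = "other"
) -> pd.Series:
    """First habitat (in continuum order) where each OTU is detected in DNA.

    OTUs found only in habitats outside ``habitat_order`` (tributaries,
    lakes, groundwater, ...) are labelled ``other``; OTUs never detected
    raise.
    """
    habitat_order = list(habitat_order)
    if len(set(habitat_order)) != len(habitat_order):
        raise ValueError("habitat_order contains duplicates")
    meta = dna.metadata
    if (meta["nucleic_acid"] != "DNA").any():
        dna = dna.dna()
        meta = dna.metadata
    detected_any = dna.counts.sum(axis=1) > 0
    if (~detected_any).any():
        missing = list(dna.counts.index[~detected_any])
        raise ValueError(f"OTUs with zero counts everywhere: {missing[:5]}")
    origin = pd.Series(other_label, index=dna.counts.index, name="origin")
    # walk the continuum from the estuary back so earlier habitats overwrite
    for hab in reversed(habitat_order):
        cols = meta.index[meta["habitat"] == hab]
        if len(cols) == 0:
            continue
        present = dna.counts[list(cols)].sum(axis=1) > 0
        origin[present] = hab
    return origin


def local_contributions(table: CountTable) -> pd.DataFrame:
    """Percent read contribution of each OTU to each local pool.

    Returns a long frame with columns ``otu_id, habitat, season, percent_dna,
    percent_rna``; within a stratum each percent column sums to 100 (RNA only
    when the stratum has RNA reads).
    """
    rows = []
    for hab, season in strata(table.metadata):
        sel = (table.metadata["habitat"] == hab) & (table.metadata["season"] == season)
        sub = table.metadata[sel]
        frame = {"otu_id": table.counts.index, "habitat": hab, "season": season}
        for nat, col in (("DNA", "percent_dna"), ("RNA", "percent_rna")):
            ids = sub.index[sub["nucleic_acid"] == nat]
            if len(ids) == 0:
                frame[col] = np.nan
                continue
            reads = table.counts[list(ids)].sum(axis=1).to_numpy(dtype=float)
            total = reads.sum()
            if total == 0:
                raise ValueError(f"stratum {hab}/{season} has zero {nat} reads")
            frame[col] = 100.0 * reads / total
        rows.append(pd.DataFrame(frame))
    return pd.concat(rows, ignore_index=True)


def compute_prt(contributions: pd.DataFrame) -> float:
    """Median of all nonzero %RNA contributions pooled across strata."""
    vals = contributions["percent_rna"].to_numpy(dtype=float)
    vals = vals[np.isfinite(vals) & (vals > 0)]
    if vals.size == 0:
        raise ValueError("no RNA contributions anywhere; PRT undefined")
    return float(np.median(vals))


def classify_reactivity(contributions: pd.DataFrame, prt: float) -> pd.DataFrame:
    """Attach per-stratum reactivity labels given the (global) PRT.

    %RNA > PRT → reactive; 0 < %RNA <= PRT → unreactive_below_prt;
    %RNA = 0 (or the stratum has no RNA samples) → unreactive_no_rna.
    """
    if prt < 0:
        raise ValueError("PRT must be non-negative")
    out = contributions.copy()
    rna = out["percent_rna"].fillna(0.0)
    out["reactivity"] = np.where(
        rna > prt, REACTIVE, np.where(rna > 0, UNREACTIVE_BELOW_PRT, UNREACTIVE_NO_RNA)
    )
    return out


def loglog_slope(percent_dna, percent_rna) -> float:
    """OLS slope of log10(%RNA) on log10(%DNA) over strictly positive pairs."""
    x = np.asarray(percent_dna, dtype=float)
    y = np.asarray(percent_rna, dtype=float)
    ok = (x > 0) & (y > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 OTUs with positive %DNA and %RNA")
    slope, _ = np.polyfit(np.log10(x[ok]), np.log10(y[ok]), 1)
    return float(slope)


def classify(
    table: CountTable,
    habitat_order=DEFAULT_HABITAT_ORDER,
    groups: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, float]:
    """Full classification: origin + contributions + PRT + reactivity.

    ``groups`` may supply per-(otu, habitat, season) abundance-group labels
    to merge in.  OTUs never observed in any sample are dropped.  Returns
    the long classification frame and the PRT.
    """
    observed = table.counts.sum(axis=1) > 0
    if not observed.all():
        table = CountTable(table.counts.loc[observed], table.metadata)
    origin = classify_origin(table, habitat_order)
    contrib = local_contributions(table)
    prt = compute_prt(contrib)
    cls = classify_reactivity(contrib, prt)
    cls = cls.merge(origin.rename("origin"), left_on="otu_id", right_index=True)
    if groups is not None:
        cls = cls.merge(groups, on=["otu_id", "habitat", "season"], how="left")
    return cls, prt


def summarize_origin_reactivity(classification: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum fractions of DNA reads and of OTUs by origin x reactivity.

    Only OTUs present in the stratum's DNA (percent_dna > 0) are counted.
    ``frac_dna_reads`` within a stratum sums to 1; so does ``frac_otus``.
    """
    present = classification[classification["percent_dna"] > 0].copy()
    g = present.groupby(["habitat", "season", "origin", "reactivity"], sort=True)
    agg = g.agg(dna_percent=("percent_dna", "sum"), n_otus=("otu_id", "size")).reset_index()
    totals = agg.groupby(["habitat", "season"])[["dna_percent", "n_otus"]].transform("sum")
    agg["frac_dna_reads"] = agg["dna_percent"] / totals["dna_percent"]
    agg["frac_otus"] = agg["n_otus"] / totals["n_otus"]
    return agg.drop(columns="dna_percent")
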
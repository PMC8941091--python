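"""End-to-end pipeline orchestration.

A :class:`PipelineConfig` points at either input TSV tables or a simulation
scenario; :func:`run_pipeline` then executes the fixed stage order

    simulate/load → phantom correction → singleton filter → CSS →
    ordination + pair distances → abundance groups → origin/reactivity

writing every stage's output as TSV/JSON plus a run manifest (parameters,
seeds, package version, SHA-256 of every written file) so a rerun with the
same config is byte-identical and verifiable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance_groups import (
    acceleration_thresholds,
    assign_abundance_groups,
    rank_abundance_curve,
)
from .origin_reactivity import classify, summarize_origin_reactivity
from .pair_distance import records_to_frame, run_pair_analysis, stratum_summary
from .preprocess import correct_phantoms, css_normalize, filter_combination_singletons
from .synthetic import (
    ContinuumScenario,
    default_mock_grid,
    simulate_continuum,
    simulate_mock_experiment,
)
from .tables import CountTable


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str
    counts_path: str | None = None
    metadata_path: str | None = None
    scenario: str | None = None  # "mock" | "continuum"
    seed: int = 0
    phantom_correction: bool = True
    singleton_min_reads: int = 10
    css_quantile: float | None = None  # adaptive, as the source normalization tool does
    threshold: float = 0.75
    habitat_order: tuple | None = None
    smooth_window: int = 5
    scenario_kwargs: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        have_files = self.counts_path is not None and self.metadata_path is not None
        if have_files == (self.scenario is not None):
            raise ValueError("set exactly one of input tables or a simulation scenario")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, index=False):
        p = out / name
        df.to_csv(p, sep="\t", index=index)
        written.append(p)

    # -- stage: load or simulate ------------------------------------------
    truth = None
    if config.scenario == "mock":
        table = simulate_mock_experiment(
            default_mock_grid(seed=config.seed, **config.scenario_kwargs), seed=config.seed
        )
    elif config.scenario == "continuum":
        table, truth = simulate_continuum(
            ContinuumScenario(seed=config.seed, **config.scenario_kwargs)
        )
    elif config.scenario is None:
        table = CountTable.from_tsv(config.counts_path, config.metadata_path)
    else:
        raise ValueError(f"unknown scenario {config.scenario!r}")
    table.to_tsv(out / "counts.tsv", out / "metadata.tsv")
    written += [out / "counts.tsv", out / "metadata.tsv"]
    if truth is not None:
        save_df(truth.origin.reset_index(), "truth_origin.tsv")
        save_df(truth.reactivity, "truth_reactivity.tsv")

    # -- stage: preprocess -------------------------------------------------
    if config.phantom_correction:
        table = correct_phantoms(table)
    table, report = filter_combination_singletons(table, config.singleton_min_reads)
    save_df(report.removed, "singleton_removals.tsv")
    norm = css_normalize(table, quantile=config.css_quantile)
    norm.to_tsv(out / "css_values.tsv")
    written.append(out / "css_values.tsv")

    # -- stage: ordination + pair distances --------------------------------
    records = run_pair_analysis(norm, threshold=config.threshold)
    save_df(records_to_frame(records), "pair_distances.tsv")
    save_df(stratum_summary(records), "pair_distance_summary.tsv")

    # -- stage: abundance groups (pooled curve) ----------------------------
    groups_long = []
    thresholds_out = {}
    for hab in sorted(norm.metadata["habitat"].unique()):
        ids = norm.metadata.index[
            (norm.metadata["habitat"] == hab) & (norm.metadata["nucleic_acid"] == "DNA")
        ]
        try:
            curve = rank_abundance_curve(norm, ids)
            thr = acceleration_thresholds(curve, config.smooth_window, habitat=hab)
        except ValueError:
            continue
        thresholds_out[hab] = dataclasses.asdict(thr)
        for season in sorted(norm.metadata.loc[ids, "season"].unique()):
            sel = ids[norm.metadata.loc[ids, "season"] == season]
            labels = assign_abundance_groups(norm, thr, sel)
            groups_long.append(
                pd.DataFrame(
                    {
                        "otu_id": labels.index,
                        "habitat": hab,
                        "season": season,
                        "group": labels.to_numpy(),
                    }
                )
            )
    (out / "abundance_thresholds.json").write_text(json.dumps(thresholds_out, indent=2))
    written.append(out / "abundance_thresholds.json")
    groups = pd.concat(groups_long, ignore_index=True) if groups_long else None
    if groups is not None:
        save_df(groups, "abundance_groups.tsv")

    # -- stage: origin & reactivity ----------------------------------------
    habitat_order = config.habitat_order
    if habitat_order is None:
        habitat_order = tuple(sorted(table.metadata["habitat"].unique()))
        if config.scenario == "continuum":
            from .synthetic import DEFAULT_HABITAT_ORDER

            habitat_order = DEFAULT_HABITAT_ORDER
    cls, prt = classify(table, habitat_order, groups=groups)
    save_df(cls, "classification.tsv")
    save_df(summarize_origin_reactivity(cls), "origin_reactivity_summary.tsv")

    # -- manifest ----------------------------------------------------------
    manifest = {
        "reactscape_version": __version__,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "prt_percent": prt,
        "files": {p.name: _sha256(p) for p in sorted(set(written))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
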
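"""Synthetic paired DNA/RNA community generators.

Two study designs are emulated so that every downstream stage of the pipeline
can be exercised with known ground truth:

* a *mock experiment*: species abundance distributions (SADs) of varying
  evenness are sampled multinomially to produce DNA assemblages, and RNA
  assemblages are derived from each DNA assemblage by zeroing a chosen number
  of OTUs — a direct dial on the strength of mass effects (taxa present in
  DNA but silent in RNA);

* a *watershed continuum*: an ordered chain of habitats
  (soil → soilwater → stream → upriver → reservoirs → downriver → estuary)
  in which each habitat recruits new taxa, upstream taxa are carried
  downstream, and a season-specific fraction of the carried-over taxa is
  unreactive (no or floor-level RNA).  The generator returns the true origin
  habitat and per-stratum reactivity of every OTU for recovery testing.

All randomness flows through :class:`numpy.random.SeedSequence` spawned from
a single user seed, so identical scenarios reproduce bit-identical tables.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable, make_metadata

DEFAULT_HABITAT_ORDER = (
    "soil",
    "soilwater",
    "stream",
    "upriver",
    "reservoirs",
    "downriver",
    "estuary",
)

SAD_FAMILIES = ("geometric", "lognormal", "broken_stick", "near_uniform")


# ---------------------------------------------------------------------------
# species abundance distributions
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SadSpec:
    """A species abundance distribution of a given family and evenness.

    ``evenness_param`` is family-specific but always oriented so that larger
    values give a more even community (higher Pielou J'):

    * ``geometric`` — common ratio r in (0, 1]; p_i ∝ r**i.
    * ``lognormal`` — 1/sigma of the underlying normal; abundances are taken
      at equally spaced quantiles of a lognormal.
    * ``broken_stick`` — mixing weight w in [0, 1] blending the MacArthur
      broken-stick expectation (w=0) with the uniform distribution (w=1).
    * ``near_uniform`` — symmetric Dirichlet concentration alpha; ``inf``
      yields the exactly uniform limit.
    """

    kind: str
    richness: int
    evenness_param: float
    seed: int = 0

    def __post_init__(self):
        if self.kind not in SAD_FAMILIES:
            raise ValueError(f"unknown SAD family {self.kind!r}; choose from {SAD_FAMILIES}")
        if self.richness < 2:
            raise ValueError("richness must be at least 2")


def generate_sad(spec: SadSpec) -> np.ndarray:
    """Relative abundances for ``spec``: positive, summing to 1, sorted descending."""
    s = spec.richness
    kind, par = spec.kind, spec.evenness_param
    if kind == "geometric":
        if not 0 < par <= 1:
            raise ValueError("geometric ratio must be in (0, 1]")
        p = par ** np.arange(s, dtype=float)
    elif kind == "lognormal":
        if par <= 0:
            raise ValueError("lognormal evenness parameter must be positive")
        sigma = 1.0 / par
        q = (np.arange(s) + 0.5) / s
        p = np.exp(sigma * stats.norm.ppf(q))
    elif kind == "broken_stick":
        if not 0 <= par <= 1:
            raise ValueError("broken-stick mixing weight must be in [0, 1]")
        bs = np.cumsum(1.0 / np.arange(s, 0, -1))[::-1] / s
        p = (1 - par) * bs + par * np.full(s, 1.0 / s)
    elif kind == "near_uniform":
        if par <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if math.isinf(par):
            p = np.full(s, 1.0 / s)
        else:
            rng = np.random.default_rng(spec.seed)
            p = rng.dirichlet(np.full(s, par))
            p = np.clip(p, 1e-300, None)
    p = np.sort(p)[::-1]
    return p / p.sum()


def pielou_evenness(p: np.ndarray) -> float:
    """Pielou's J' = H' / ln(S) of a relative-abundance vector."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    if len(p) < 2:
        return 0.0
    return float(-(p * np.log(p)).sum() / np.log(len(p)))


# ---------------------------------------------------------------------------
# sampling and RNA derivation
# ---------------------------------------------------------------------------

def sample_assemblage(probs: np.ndarray, depth: int, seed) -> np.ndarray:
    """Multinomial read counts at ``depth`` from a relative-abundance vector."""
    probs = np.asarray(probs, dtype=float)
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if abs(probs.sum() - 1.0) > 1e-8:
        raise ValueError("probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(depth, probs / probs.sum())


def derive_rna(dna_counts: np.ndarray, n_remove: int, seed) -> np.ndarray:
    """Copy of ``dna_counts`` with ``n_remove`` random nonzero OTUs zeroed."""
    dna_counts = np.asarray(dna_counts)
    nonzero = np.flatnonzero(dna_counts)
    if n_remove > len(nonzero):
        raise ValueError(
            f"cannot remove {n_remove} OTUs from an assemblage with {len(nonzero)} nonzero OTUs"
        )
    rna = dna_counts.copy()
    if n_remove > 0:
        rng = np.random.default_rng(seed)
        drop = rng.choice(nonzero, size=n_remove, replace=False)
        rna[drop] = 0
    return rna


# ---------------------------------------------------------------------------
# mock experiment
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MockScenario:
    sad: SadSpec
    n_sites: int = 5
    depth: int = 1000
    n_remove: int = 0
    seed: int = 0
    label: str = ""

    def __post_init__(self):
        if self.n_remove >= self.sad.richness:
            raise ValueError("n_remove must be smaller than SAD richness")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


def default_mock_grid(
    families=SAD_FAMILIES,
    removal_levels=(0, 5, 10, 15),
    n_sites: int = 5,
    richness: int = 60,
    depth: int = 5000,
    seed: int = 0,
) -> list[MockScenario]:
    """The mock grid: each SAD family crossed with a gradient of OTU removal.

    Evenness parameters are fixed per family at mid-range values spanning an
    evenness gradient from strongly dominated (geometric r=0.8) to near
    uniform (Dirichlet alpha=50).  The depth and removal levels are chosen so
    that even the least even family observes comfortably more OTUs per
    assemblage than the largest removal level.
    """
    params = {
        "geometric": 0.8,
        "lognormal": 0.8,
        "broken_stick": 0.3,
        "near_uniform": 50.0,
    }
    out = []
    for fam in families:
        for n_rm in removal_levels:
            out.append(
                MockScenario(
                    sad=SadSpec(fam, richness, params[fam], seed=seed),
                    n_sites=n_sites,
                    depth=depth,
                    n_remove=n_rm,
                    seed=seed,
                    label=f"{fam}_rm{n_rm}",
                )
            )
    return out


def simulate_mock_experiment(scenarios: list[MockScenario], seed: int = 0) -> CountTable:
    """Simulate all scenarios into one table of paired DNA/RNA samples.

    Sample metadata records the scenario label as ``habitat`` and a constant
    ``season`` so that downstream stratum machinery applies unchanged; the
    per-pair removal level is recoverable from the scenario label.
    """
    if not scenarios:
        raise ValueError("need at least one scenario")
    richness = {sc.sad.richness for sc in scenarios}
    if len(richness) != 1:
        raise ValueError("all scenarios must share one OTU universe (equal richness)")
    n_otu = richness.pop()
    otu_ids = [f"otu{i:04d}" for i in range(n_otu)]

    root = np.random.SeedSequence(seed)
    cols, metas = {}, []
    for i, sc in enumerate(scenarios):
        label = sc.label or f"scenario{i}"
        probs = generate_sad(sc.sad)
        ss = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i, sc.seed))
        site_seeds = ss.spawn(2 * sc.n_sites)
        for site in range(sc.n_sites):
            dna = sample_assemblage(probs, sc.depth, site_seeds[2 * site])
            rna = derive_rna(dna, sc.n_remove, site_seeds[2 * site + 1])
            pid = f"{label}_site{site}"
            for nat, vec in ((("DNA"), dna), (("RNA"), rna)):
                sid = f"{pid}_{nat}"
                cols[sid] = vec
                metas.append((sid, label, "mock", nat, pid, sc.n_remove))
    counts = pd.DataFrame(cols, index=pd.Index(otu_ids, name="otu_id"))
    meta = make_metadata(
        [m[0] for m in metas],
        [m[1] for m in metas],
        [m[2] for m in metas],
        [m[3] for m in metas],
        [m[4] for m in metas],
    )
    meta["n_remove"] = [m[5] for m in metas]
    return CountTable(counts, meta)


# ---------------------------------------------------------------------------
# watershed continuum
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class ContinuumScenario:
    """A terrestrial→estuary continuum with seasonal unreactive carry-over.

    Each habitat recruits ``round(recruitment_rate * source_pool_size)`` new
    OTUs (the first habitat recruits the full source pool) with lognormal
    abundance scores; terrestrial pools (first two habitats) get a dominance
    factor so the terrestrial source pool dominates reads downstream.

    Within a stratum (habitat x season), the unreactive taxa are the bottom
    ``carryover_unreactive_frac[season]`` fraction of carried-over OTUs (and
    ``local_unreactive_frac`` of locally recruited ones) ranked by DNA
    abundance with per-stratum lognormal jitter: passive influx is
    concentrated among numerically rare taxa — washed-in cells are dilute —
    while dominant taxa are growing locally, hence reactive.  The carry-over
    fraction ramps up along the continuum from
    ``carryover_gradient_start x carryover_unreactive_frac`` at the source to
    the full seasonal value at the terminal habitat — passively transported
    taxa accumulate downstream — which gives each season a real spatial
    ∆-distance gradient rather than near-tied strata.  Because the
    abundance distribution is steep (``abundance_sigma``), a high unreactive
    *taxon* fraction still carries little *read* mass, so seasons differ
    mainly in incidence (m_S), as a mass-effects gradient should.
    Reactive taxa get RNA proportional to their DNA relative abundance;
    unreactive taxa sit at the fixed RNA floor ``rna_floor`` — whether they
    register as "no RNA" is then purely a matter of sequencing depth, as in
    real libraries.
    """

    habitat_order: tuple = DEFAULT_HABITAT_ORDER
    seasons: tuple = ("spring", "summer")
    source_pool_size: int = 200
    recruitment_rate: float = 0.1
    carryover_unreactive_frac: tuple = (0.7, 0.3)  # aligned with seasons
    carryover_gradient_start: float = 0.4  # upstream attenuation of carry-over
    local_unreactive_frac: float = 0.5
    depth: int = 20000
    n_samples_per_stratum: int = 4
    seed: int = 0
    terrestrial_factor: float = 10.0
    rna_floor: float = 2.5e-5  # relative RNA abundance of unreactive taxa
    abundance_sigma: float = 1.5  # lognormal spread of per-OTU base scores
    reactivity_jitter: float = 0.3  # per-stratum noise on the abundance ranking

    def __post_init__(self):
        if len(set(self.habitat_order)) != len(self.habitat_order):
            raise ValueError("habitat_order contains duplicates")
        if len(self.habitat_order) < 2:
            raise ValueError("need at least 2 habitats")
        if len(self.carryover_unreactive_frac) != len(self.seasons):
            raise ValueError("one carryover_unreactive_frac per season")
        for f in self.carryover_unreactive_frac + (
            self.local_unreactive_frac,
            self.recruitment_rate,
        ):
            if not 0 <= f <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclasses.dataclass
class ContinuumTruth:
    """Ground truth accompanying a simulated continuum dataset."""

    origin: pd.Series  # otu_id -> habitat of first recruitment
    reactivity: pd.DataFrame  # columns: otu_id, habitat, season, reactive (bool)


def simulate_continuum(scenario: ContinuumScenario) -> tuple[CountTable, ContinuumTruth]:
    sc = scenario
    habitats = list(sc.habitat_order)
    root = np.random.SeedSequence(sc.seed)
    rng_pool, rng_react, rng_samp = (np.random.default_rng(s) for s in root.spawn(3))

    # recruit OTU pools per habitat
    n_new = [sc.source_pool_size] + [
        round(sc.recruitment_rate * sc.source_pool_size) for _ in habitats[1:]
    ]
    otu_ids, origin_idx, base_score = [], [], []
    for h_i, (hab, n) in enumerate(zip(habitats, n_new)):
        scores = rng_pool.lognormal(mean=0.0, sigma=sc.abundance_sigma, size=n)
        if h_i <= 1:  # soil and soilwater dominate
            scores = scores * sc.terrestrial_factor
        for j in range(n):
            otu_ids.append(f"{hab[:4]}_{h_i}_{j:04d}")
        origin_idx.extend([h_i] * n)
        base_score.extend(scores)
    origin_idx = np.asarray(origin_idx)
    base_score = np.asarray(base_score)
    n_otu = len(otu_ids)
    origin = pd.Series(
        [habitats[i] for i in origin_idx], index=pd.Index(otu_ids, name="otu_id"), name="origin"
    )

    def _draw_unreactive(pool: np.ndarray, frac: float, rel: np.ndarray) -> np.ndarray:
        """Bottom ~frac of ``pool`` (indices) by jittered DNA abundance."""
        k = int(round(frac * len(pool)))
        if k == 0 or len(pool) == 0:
            return np.empty(0, dtype=int)
        score = rel[pool] * rng_react.lognormal(0.0, sc.reactivity_jitter, size=len(pool))
        return pool[np.argsort(score)[:k]]

    cols, metas, react_rows = {}, [], []
    for s_i, season in enumerate(sc.seasons):
        carry = sc.carryover_unreactive_frac[s_i]
        for h_i, hab in enumerate(habitats):
            avail = origin_idx <= h_i
            local = origin_idx == h_i

            dna_rel = np.where(avail, base_score, 0.0)
            dna_rel = dna_rel / dna_rel.sum()

            g0 = sc.carryover_gradient_start
            carry_eff = carry * (g0 + (1 - g0) * h_i / (len(habitats) - 1))
            unreactive = np.zeros(n_otu, dtype=bool)
            unreactive[_draw_unreactive(np.flatnonzero(avail & ~local), carry_eff, dna_rel)] = True
            unreactive[
                _draw_unreactive(np.flatnonzero(local), sc.local_unreactive_frac, dna_rel)
            ] = True
            reactive = avail & ~unreactive

            rna_rel = np.zeros(n_otu)
            noise = rng_react.lognormal(0.0, 0.3, size=n_otu)
            rna_rel[reactive] = dna_rel[reactive] * noise[reactive]
            rna_rel[unreactive] = sc.rna_floor * noise[unreactive]
            rna_rel = rna_rel / rna_rel.sum()

            for otu_i in np.flatnonzero(avail):
                react_rows.append((otu_ids[otu_i], hab, season, bool(reactive[otu_i])))

            for rep in range(sc.n_samples_per_stratum):
                pid = f"{hab}_{season}_{rep}"
                dna = rng_samp.multinomial(sc.depth, dna_rel)
                rna = rng_samp.multinomial(sc.depth, rna_rel)
                for nat, vec in (("DNA", dna), ("RNA", rna)):
                    sid = f"{pid}_{nat}"
                    cols[sid] = vec
                    metas.append((sid, hab, season, nat, pid))

    counts = pd.DataFrame(cols, index=pd.Index(otu_ids, name="otu_id"))
    meta = make_metadata(
        [m[0] for m in metas],
        [m[1] for m in metas],
        [m[2] for m in metas],
        [m[3] for m in metas],
        [m[4] for m in metas],
    )
    truth = ContinuumTruth(
        origin=origin,
        reactivity=pd.DataFrame(
            react_rows, columns=["otu_id", "habitat", "season", "reactive"]
        ),
    )
    return CountTable(counts, meta), truth
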
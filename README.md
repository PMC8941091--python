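# reactscape

Community-assembly inference from paired DNA/RNA 16S rRNA OTU tables.

## The problem

Along a hydrological continuum (soils → soilwater → streams → river →
reservoirs → estuary), bacterial communities are continuously re-assembled
by two competing processes: **mass effects** (passive influx of cells that
are not growing locally) and **species selection** (local environmental
filtering of taxa that do grow). DNA-based 16S profiles see the *total*
assemblage, including dormant and dead cells in transit; rRNA (cDNA)
profiles enrich for the *reactive* fraction. `reactscape` turns the
divergence between paired DNA- and RNA-based assemblage structures into an
index of which process dominates, and classifies each OTU by its likely
origin along the continuum and its local reactivity.

## The statistic

For every DNA–RNA sample pair, two joint PCoA ordinations are built over all
samples — one from Bray–Curtis dissimilarities (abundance-sensitive), one
from Sørensen dissimilarities (incidence only). Within each ordination the
pair distance

m(p, q) = √( (p₁−q₁)² + … + (p_n−q_n)² )

is taken over the first n axes that cumulatively explain 75 % of the
variance (n₇₅%), giving m_BC and m_S. Their difference

**∆ = m_BC − m_S ∈ [−1, 1]**

is the assembly index: low or negative ∆ means the pair diverges mostly in
*which* taxa are present (influx of unreactive taxa → mass effects); high ∆
means shared taxa diverge in *abundance* (selection). Around this core the
package provides:

- the table-level corrections used upstream: phantom-taxon correction
  (RNA > 0, DNA = 0 → DNA = 1), within-stratum singleton filtering
  (singleton observations with < 10 reads), cumulative sum scaling (CSS)
  and rarefaction;
- empirical abundance-group thresholds (abundant / moderate / rare) from
  the points of maximum acceleration along the rank abundance curve;
- continuum-origin labels (first habitat of DNA detection) and a
  reactive/unreactive partition of taxa per habitat × season via the
  potential reactivity threshold (PRT), the median nonzero %RNA
  contribution;
- a synthetic-data module that simulates both a mock experiment (SADs of
  varying evenness, RNA derived from DNA by OTU removal) and a full
  watershed continuum with known origin/reactivity ground truth.

## Worked example

```python
import reactscape as rs
from reactscape.pair_distance import records_to_frame

# simulate a two-season continuum (spring: strong unreactive carry-over)
table, truth = rs.simulate_continuum(rs.ContinuumScenario(seed=1))

# preprocessing: phantom correction, stratum singleton filter
table = rs.correct_phantoms(table)
table, report = rs.filter_combination_singletons(table)

# DNA-RNA pair distances in truncated PCoA space
records = rs.run_pair_analysis(table)
print(records_to_frame(records).groupby("season")["delta"].mean())

# origin + reactivity classification
cls, prt = rs.classify(table)
print(f"PRT = {prt:.4f}% RNA contribution")
```

prints

```
season
spring   -0.067321
summer    0.031704
Name: delta, dtype: float64
PRT = 0.1138% RNA contribution
```

Spring — the high-carry-over season — has the lower mean ∆: divergence is
incidence-driven (mass effects), while in summer shared taxa differ mainly
in abundance (selection). The PRT is the median nonzero per-stratum %RNA
contribution; taxa above it track their DNA abundance (reactive), taxa at
or below it sit at a decoupled floor.

The same pipeline is scriptable:

```sh
reactscape simulate continuum --seed 1 --out sim/
reactscape pairdist --table sim/counts.tsv --metadata sim/metadata.tsv --out out/
reactscape run --config pipeline.yaml
```

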
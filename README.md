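# cnmod

Co-expression module detection and occurrence-probability scoring for
carbon/nitrogen-metabolism (CNM) qPCR panels.

## The problem

Plants exposed to a nitrogenous pollutant such as thiocyanate (SCN⁻)
reorganize their carbon and nitrogen metabolism; exogenous
2-oxoglutarate (2-OG), the TCA-cycle acid that couples the two,
can mitigate the stress. Given a 40-gene panel spanning C metabolism,
N metabolism and 2-OG biosynthesis, assayed by RT-qPCR in roots and
shoots across an SCN⁻ dose series with and without 2-OG pretreatment,
the question is: *which co-expression module of the panel carries the
response?*

`cnmod` answers it with a fully reproducible pipeline aimed at anyone
analyzing small targeted expression panels against a protein–protein
interaction network:

1. **qPCR quantification.** Relative expression by the Livak method,
   RE = 2^−ΔΔCt, where ΔCt = Ct_target − Ct_GAPDH per biological
   replicate and ΔΔCt subtracts the calibrator condition's mean ΔCt.
   Replicates aggregate to mean ± sample SD.
2. **Network modules.** A STRING-style weighted edge list is filtered
   at combined score > 0.4 and partitioned by Louvain maximization of
   resolution-parameterized modularity
   Q_γ = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j) at γ = 0.8
   (best of 20 seeded restarts).
3. **Occurrence probability.** Within each (tissue, condition) stratum
   the 40 gene means are transformed toward normality (√x or ln x,
   whichever minimizes |sample skewness|) and each gene is scored by
   p = Φ((x̃ − μ̂)/σ̂) against the stratum's empirical distribution.
   The **key module** is the one whose gene–condition pairs most often
   exceed p > 0.75 (ties broken by mean p, then module id).
4. **Growth.** Relative growth rate RGR = 100 · (W_F − W_I)/W_I and
   per-condition C%/N% summaries.

A seeded synthetic-data generator plants a 4-block partition
(sizes 11/10/10/9) and a log2 fold-change in a designated key module,
so every stage — and the whole pipeline — can be verified end to end
without external data.

## Worked example

```python
from cnmod import PipelineConfig, SimConfig, run_pipeline

res = run_pipeline(PipelineConfig(outdir="demo_run", sim=SimConfig(seed=11), seed=11))
print((res.outdir / "summary.txt").read_text())
```

prints

```
cnmod 0.1.0 run summary
genes: 40; modules: 4 (Q_r=0.744334 at resolution 0.8)
module sizes: module 1: 11 genes (27.5%), module 2: 10 genes (25.0%), module 3: 10 genes (25.0%), module 4: 9 genes (22.5%)
occurrence threshold: p > 0.75 (tissue=shoot)
key module: module 2 (decided by frac_exceed)
```

The simulated 40-gene panel splits into four modules whose node shares
(27.5/25.0/25.0/22.5%) reflect the planted sizes. Module 2 — the
detected module covering the planted key block, whose genes carry a
log2 fold-change of 2 under the 2-OG conditions — wins the key-module
call outright: 48 of its 70 gene–condition probabilities exceed 0.75
(frac_exceed 0.69, mean p 0.77), versus frac_exceed ≤ 0.17 elsewhere
(see `demo_run/module_report.json`). The run directory also holds the
replicate-level and aggregated expression tables, the partition and
module summary, per-gene occurrence probabilities, the growth summary,
and a manifest with parameters, seed and input checksums from which the
run is byte-reproducible.

The same stages are available from the shell and compose exactly like
`run`:

```bash
cnmod simulate --seed 11 --out sim/
cnmod qpcr --ct sim/ct.tsv --housekeeping GAPDH --calibrator scn0 --out expr/
cnmod network --edges sim/edges.tsv --catalog sim/catalog.tsv \
      --threshold 0.4 --resolution 0.8 --restarts 20 --seed 11 --out net/
cnmod occurrence --expr expr/expression_aggregated.tsv \
      --partition net/partition.tsv --tissue shoot --threshold 0.75 --out occ/
```

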
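# Methods

This note documents the models and conventions behind `cnmod`, the
defaults and why they were chosen, and what the synthetic benchmark
does and does not establish about real data.

## Relative quantification (qpcr)

The Livak 2^−ΔΔCt method with a fixed amplification efficiency of 2.
Per biological replicate *r*:

    ΔCt_r  = Ct_target,r − Ct_housekeeping,r
    ΔΔCt_r = ΔCt_r − mean_{calibrator replicates}(ΔCt)
    RE_r   = 2^(−ΔΔCt_r)

Biological replicates are independent units, so ΔΔCt is taken against
the calibrator condition's *mean* ΔCt rather than replicate-paired;
replicate pairing is undefined for unpaired designs. A consequence is
that the calibrator's mean ΔΔCt is exactly 0, i.e. the *geometric* mean
of its replicate REs is exactly 1 (the arithmetic mean exceeds 1 by
Jensen's inequality — expected, not a bug). The default calibrator is
the untreated, non-pretreated control (`scn0`); the default reference
gene is GAPDH. Both are configurable. Replicates missing a housekeeping
Ct are dropped with a warning; genes left with fewer than two
replicates in any condition are flagged and excluded from scoring.
Primer-efficiency correction and multi-reference normalization are out
of scope.

Aggregation everywhere is mean ± sample SD (n−1 denominator): the
replicates are a sample, and a single replicate reports SD as NA, not 0.

## Growth (growth)

RGR (%) = 100 · (W_final − W_initial)/W_initial on fresh weights, with
per-condition descriptive summaries of RGR and optional C%/N%. No
hypothesis testing (Tukey letters, ANOVA, EC fitting) is performed —
the module is deliberately descriptive.

## Network modules (network)

Input is a STRING-export-like weighted edge list. Edges are kept when
the combined score is *strictly* greater than the threshold
(default 0.4) — a score of exactly 0.4 is excluded; duplicate unordered
pairs collapse to their maximum score; self-loops are dropped; and
every catalog gene remains a node, so genes with no retained edges
become singleton modules rather than disappearing (the catalog is the
analysis universe).

Modules maximize resolution-parameterized modularity with the
resolution γ multiplying the null-model term (Reichardt–Bornholdt
convention, the one Gephi uses), default γ = 0.8. Optimization is
seeded Louvain (networkx) run `n_restarts` times (default 20; 50 in the
oracle tests) with distinct node sweep orders derived from the single
seed; the restart with the highest Q_γ wins, earliest restart on ties.
Modules are relabeled 1..K by descending size, ties by smallest
contained gene id, making partitions deterministic and comparable
across runs. On an exhaustive-search suite of 23 connected graphs with
≤ 8 nodes (bridged 4-cliques, triangles, paths, stars, cycles, complete
graphs, barbells, grids, weighted cycles) the restarted Louvain attains
the global optimum of Q_0.8 on every graph; this is a property of small
graphs and is not guaranteed at scale.

Module "contribution" is node share: 100 · |module| / |catalog|. A
40-gene catalog split 11/10/10/9 gives 27.5/25.0/25.0/22.5%.
Composition is the module × pathway-category cross-tabulation.

## Occurrence probability (occurrence)

The statistic scores how far a gene's expression sits in the upper tail
of its stratum. Design choices the method itself leaves open are
resolved as follows and surfaced in every report:

* **Stratum.** μ̂ and σ̂ are the sample mean and SD (n−1) of the
  *transformed* mean expressions of all catalog genes within one
  (tissue, condition). Per-condition stratification matches the way the
  statistic is presented per treatment panel.
* **Transform.** √x or ln x, chosen per stratum by the smaller
  adjusted Fisher–Pearson |sample skewness| after transform; ties go to
  √x, and ln is ineligible when any value is 0. Under multiplicative
  (lognormal) noise ln is exactly normalizing, and ln-based z-scores
  are invariant to global rescaling of a stratum; √-based scores are
  not, which is why each probability row records its transform.
* **Inputs.** Replicate-mean relative expression per gene (the
  aggregated view); shoot tissue by default.
* **Score.** p = Φ((x̃ − μ̂)/σ̂) with Φ computed via the complementary
  error function, Φ(z) = ½(1 + erf(z/√2)); agreement with scipy's
  reference CDF is ≤ 2.3e−16 over z ∈ [−8, 8].
* **Key module.** frac_exceed(m) = #{(gene, condition) in m with
  p > threshold} / (|m| · #conditions), threshold 0.75, *strict*
  inequality (p = 0.75 does not count). The key module maximizes
  frac_exceed; exact ties fall back to larger mean p, then smaller
  module id, and the report records which rule decided. A count of
  exceedances is used as the primary aggregate because the call is
  phrased as a threshold crossing; mean p is the documented tie-break,
  not the headline statistic.

A stratum whose transformed values are all identical has σ̂ = 0 and is
rejected with an error naming the stratum — this occurs by construction
in noise-free simulations for untreated conditions, where every
non-key gene has RE exactly 1; noise-free runs should score the treated
(2-OG) conditions.

## Synthetic data (simulate)

The generator emulates the study design, not the biochemistry:

* **Catalog.** 40 genes in 10 enzyme families — PEPC(5), ERS(3),
  TPS(5), SPS(5) (C metabolism); NR(3), NiR(3), GS(4) (N metabolism);
  NADP-ICDH(4), NAD-IDH(4), GDH(4) (2-OG synthesis). The PEPC family
  carries five members (Osppc2b included alongside the four enumerated
  isoforms) so the panel totals 40; the catalog writer flags this in a
  header comment. Genes are sliced in catalog order into planted
  modules of sizes 11/10/10/9; module 3 (NiR + GS + three NADP-ICDH
  genes, an N-metabolism/2-OG block) is the default key module.
* **Ct model.** Additive Gaussian on the cycle scale: each
  (gene, tissue) has a fixed baseline ~ Normal(24, 1.5) cycles, and an
  observation is baseline − log2(fold change) + Normal(0, σ_Ct),
  σ_Ct = 0.25 by default. Key-module genes carry a planted
  log2 fold-change (default 2) in the 2-OG-pretreated conditions; all
  other gene/condition pairs have fold change 1. The housekeeping gene
  baseline is constant across conditions. Gaussian cycle noise makes
  RE lognormal, which is exactly the distributional shape the ln
  transform of the scoring stage expects.
* **Design.** 2 tissues (root, shoot) × 8 conditions (SCN⁻ at
  0/24/96/300 mg/L × with/without 2-OG) × 4 biological replicates,
  condition ids `scn<dose>[_og]`.
* **Network.** Planted-partition model: each unordered pair gets an
  edge with probability p_within = 0.6 (same planted module) or
  p_between = 0.05, with combined scores uniform on (0.5, 0.99) within
  and (0.15, 0.45) between. The between-range deliberately straddles
  the 0.4 filter slightly, so a few between-module edges survive
  filtering — recovery is tested under that mild contamination. An
  optional `score_boundary` lets a configuration forbid straddling.
* **Growth.** W_final = W_initial · (1 + RGR_true/100) · lognormal
  noise (σ = 0.05), RGR_true = 50% flat across conditions by default;
  C% ~ Normal(40, 1), N% ~ Normal(3, 0.3), typical dry-mass fractions.
* **Seeding.** Everything derives from the single config seed through
  named numpy SeedSequence streams; each generator is a pure function
  of its config, and ground-truth module labels live in a
  `planted_module` column that the analysis reader drops by default.

**What passing the benchmark shows — and does not.** Recovery at 100%
of 50 seeds under the reference conditions (p_within 0.6, p_between
0.05, log2FC 2, σ_Ct 0.3) shows the pipeline is internally consistent
and has useful sensitivity at realistic qPCR noise. It does not show
that real STRING networks have planted-partition structure, that real
treatment effects are uniform within a module, or that expression noise
is exactly lognormal; on real data the key-module call should be read
together with the per-module exceedance table, not as a certainty.

## Numerical and policy details

* Problem sizes: recovery studies use 50 seeds, one tissue, default
  panel; the exhaustive modularity oracle is restricted to ≤ 8-node
  graphs (Bell(8) = 4140 partitions).
* Q_γ ties inside Louvain resolve by networkx's seeded order; across
  restarts the earliest best partition is kept (tolerance 1e−12).
* All artifacts are UTF-8 TSV with '#' comments at full double
  precision, plus JSON for the module report and manifest; runs with
  the same config are byte-identical.
* Edge-case contracts: empty catalog, unknown edge genes, nonpositive
  Ct, missing calibrator, σ̂ = 0 strata, and empty probability sets are
  errors; an edgeless graph yields all singletons with Q = 0 and a
  warning.

## Known limitations

* Louvain optimality is verified only on small graphs; at larger scale
  it is a heuristic like every modularity maximizer.
* The skewness-minimizing transform choice is a convention; with very
  few strata values skewness estimates are unstable.
* Module "contribution" is defined as node share. Under other
  definitions (e.g. edge- or interaction-weighted shares) modules of
  equal node count would differ.
* Efficiency-corrected qPCR models (Pfaffl) are not implemented.
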
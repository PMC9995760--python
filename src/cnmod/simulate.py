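"""Synthetic data generation with planted structure.

The generators emulate the study design the analysis assumes: a 40-gene
CNM panel assayed by RT-qPCR in two tissues under 8 conditions (4 SCN-
doses x with/without 2-OG pretreatment) with 4 biological replicates, a
STRING-export-like weighted edge list drawn from a planted-partition
model, and a fresh-weight growth table.  One module is designated the
"key" module: its genes receive a log2 fold-change under the 2-OG
pretreated conditions, which the downstream occurrence scoring should
recover.

Every generator is a pure function of its ``SimConfig``; the config seed
is expanded into independent per-artifact streams so that, e.g., the
edge list does not change when the number of replicates does.

Ground-truth planted module labels travel in a dedicated
``planted_module`` catalog column that the analysis modules never read;
it exists only so recovery tests can compare against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "DEFAULT_FAMILIES",
    "condition_id",
    "generate_catalog",
    "generate_ct_table",
    "generate_edge_list",
    "generate_growth_table",
]

# (family, gene count, pathway category); the canonical 10-family CNM
# panel: 4 C-metabolism families, 3 N-metabolism families, 3 families on
# the 2-OG biosynthesis routes.
DEFAULT_FAMILIES: tuple[tuple[str, int, str], ...] = (
    ("PEPC", 5, "C metabolism"),
    ("ERS", 3, "C metabolism"),
    ("TPS", 5, "C metabolism"),
    ("SPS", 5, "C metabolism"),
    ("NR", 3, "N metabolism"),
    ("NiR", 3, "N metabolism"),
    ("GS", 4, "N metabolism"),
    ("NADP-ICDH", 4, "2-OG synthesis"),
    ("NAD-IDH", 4, "2-OG synthesis"),
    ("GDH", 4, "2-OG synthesis"),
)

# Published gene names for the default panel, used whenever a family's
# configured size matches.  PEPC carries five members (Osppc2b included
# alongside the four enumerated isoforms) so the panel totals 40.
DEFAULT_GENE_NAMES: Mapping[str, tuple[str, ...]] = {
    "PEPC": ("Osppc1", "Osppc2a", "Osppc2b", "Osppc3", "Osppc4"),
    "ERS": ("OsERS1", "OsERS2", "OsERS3"),
    "TPS": ("OsTPS1", "OsTPS4", "OsTPS5", "OsTPS8", "OsTPS9"),
    "SPS": ("OsSPS1", "OsSPS2", "OsSPS4", "OsSPS5", "OsSPS6"),
    "NR": ("OsNIA1", "OsNIA2", "OsNR1"),
    "NiR": ("OsNiR1", "OsNiR2", "OsNiR3"),
    "GS": ("OsGS1;1", "OsGS1;2", "OsGS1;3", "OsGS2"),
    "NADP-ICDH": ("OsICDH1", "OsICDH2", "OsICDH3", "OsICDH4"),
    "NAD-IDH": ("OsIDHa", "OsIDHc;1", "OsIDHc;2", "OsIDH1"),
    "GDH": ("OsGDH1", "OsGDH2", "OsGDH3", "OsGDH4"),
}

DEFAULT_CONDITIONS: tuple[tuple[float, bool], ...] = tuple(
    (dose, og) for og in (False, True) for dose in (0.0, 24.0, 96.0, 300.0)
)

# sub-stream identifiers mixed with the config seed
_STREAM_CT = 1
_STREAM_EDGES = 2
_STREAM_GROWTH = 3


def condition_id(scn_dose: float, og_pretreated: bool) -> str:
    """Canonical condition label, e.g. ``scn24`` or ``scn96_og``."""
    dose = int(scn_dose) if float(scn_dose).is_integer() else scn_dose
    return f"scn{dose}_og" if og_pretreated else f"scn{dose}"


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the design the analysis targets: 40 genes in 10
    enzyme families, 2 tissues, 8 conditions (SCN- at 0/24/96/300 mg/L,
    each with and without 2-OG pretreatment), 4 biological replicates,
    and a 4-block planted partition with sizes 11/10/10/9 whose third
    block is the key module.
    """

    n_genes: int = 40
    families: Sequence[tuple[str, int, str]] = DEFAULT_FAMILIES
    n_modules: int = 4
    module_sizes: Sequence[int] = (11, 10, 10, 9)
    key_module_index: int = 3
    conditions: Sequence[tuple[float, bool]] = DEFAULT_CONDITIONS
    tissues: Sequence[str] = ("root", "shoot")
    n_replicates: int = 4
    housekeeping_id: str = "GAPDH"
    # qPCR model (cycle scale)
    ct_base_mean: float = 24.0
    ct_gene_spread: float = 1.5
    ct_noise_sd: float = 0.25
    key_effect_log2fc: float = 2.0
    # planted-partition network model
    p_within: float = 0.6
    p_between: float = 0.05
    score_within_range: tuple[float, float] = (0.5, 0.99)
    score_between_range: tuple[float, float] = (0.15, 0.45)
    score_boundary: float | None = None
    # growth model
    rgr_true: float = 50.0
    w_initial_mean: float = 1.0
    w_initial_spread: float = 0.1
    growth_noise_sd: float = 0.05
    c_pct_mean: float = 40.0
    c_pct_sd: float = 1.0
    n_pct_mean: float = 3.0
    n_pct_sd: float = 0.3
    seed: int = 0
    gene_names: Mapping[str, Sequence[str]] = field(default_factory=lambda: DEFAULT_GENE_NAMES)

    def __post_init__(self) -> None:
        fam_total = sum(count for _, count, _ in self.families)
        if fam_total != self.n_genes:
            raise ValueError(
                f"family gene counts sum to {fam_total}, expected n_genes={self.n_genes}"
            )
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) != self.n_genes:
            raise ValueError("module_sizes must sum to n_genes")
        if not 1 <= self.key_module_index <= self.n_modules:
            raise ValueError("key_module_index out of range")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")
        if not (0 <= self.p_between < self.p_within <= 1):
            raise ValueError("require 0 <= p_between < p_within <= 1")
        for name, (lo, hi) in (
            ("score_within_range", tuple(self.score_within_range)),
            ("score_between_range", tuple(self.score_between_range)),
        ):
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name} must be a sub-interval of [0, 1]")
            if self.score_boundary is not None and lo < self.score_boundary < hi:
                raise ValueError(f"{name} straddles score_boundary={self.score_boundary}")
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue names must be unique")

    @property
    def condition_ids(self) -> list[str]:
        return [condition_id(d, og) for d, og in self.conditions]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["families"] = [list(f) for f in self.families]
        d["conditions"] = [[float(x), bool(og)] for x, og in self.conditions]
        d["gene_names"] = {k: list(v) for k, v in self.gene_names.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "families" in d:
            d["families"] = [tuple(f) for f in d["families"]]
        if "conditions" in d:
            d["conditions"] = [(float(x), bool(og)) for x, og in d["conditions"]]
        if "gene_names" in d:
            d["gene_names"] = {k: tuple(v) for k, v in d["gene_names"].items()}
        return cls(**d)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), stream])


def generate_catalog(config: SimConfig) -> pd.DataFrame:
    """Build the gene catalog with planted module labels.

    Returns a frame with columns ``gene_id``, ``family``, ``category``
    and ``planted_module``.  Genes are laid out family by family in the
    configured order and sliced into the configured module sizes;
    ``planted_module`` is ground truth for recovery tests only and must
    not be consumed by analysis code.
    """
    records = []
    for family, count, category in config.families:
        names = config.gene_names.get(family, ())
        if len(names) == count:
            ids = list(names)
        else:
            ids = [f"{family}_{k + 1}" for k in range(count)]
        for gid in ids:
            records.append((gid, family, category))
    catalog = pd.DataFrame(records, columns=["gene_id", "family", "category"])
    if catalog["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in catalog")
    modules = np.repeat(
        np.arange(1, config.n_modules + 1), np.asarray(config.module_sizes, dtype=int)
    )
    catalog["planted_module"] = modules
    return catalog


def _true_log2fc(config: SimConfig, planted_module: int, og_pretreated: bool) -> float:
    if og_pretreated and planted_module == config.key_module_index:
        return float(config.key_effect_log2fc)
    return 0.0


def generate_ct_table(config: SimConfig, catalog: pd.DataFrame) -> pd.DataFrame:
    """Simulate the replicate Ct table, housekeeping gene included.

    Cycle-threshold model: each (gene, tissue) has a fixed baseline
    ``ct_base ~ Normal(ct_base_mean, ct_gene_spread)``; an observed Ct is
    ``ct_base - log2(fold change) + Normal(0, ct_noise_sd)``.  Key-module
    genes carry ``key_effect_log2fc`` under 2-OG pretreated conditions,
    all other gene/condition pairs a fold change of 1.  The housekeeping
    gene baseline is ``ct_base_mean`` in every tissue, constant in
    expectation across conditions.
    """
    rng = _rng(config, _STREAM_CT)
    genes = catalog["gene_id"].tolist()
    planted = dict(zip(catalog["gene_id"], catalog["planted_module"]))
    base = {
        (g, t): rng.normal(config.ct_base_mean, config.ct_gene_spread)
        for g in genes
        for t in config.tissues
    }
    rows = []
    for tissue in config.tissues:
        for dose, og in config.conditions:
            cid = condition_id(dose, og)
            for rep in range(1, config.n_replicates + 1):
                for g in genes:
                    mu = base[(g, tissue)] - _true_log2fc(config, planted[g], og)
                    ct = mu + (rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0)
                    rows.append((g, tissue, cid, rep, ct))
                hk = config.ct_base_mean + (
                    rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd else 0.0
                )
                rows.append((config.housekeeping_id, tissue, cid, rep, hk))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "condition_id", "replicate", "ct"])


def generate_edge_list(config: SimConfig, catalog: pd.DataFrame) -> pd.DataFrame:
    """Draw a weighted edge list from the planted-partition model.

    Each unordered gene pair receives an edge with probability
    ``p_within`` (same planted module) or ``p_between`` (different);
    combined scores are uniform on the corresponding score range.  No
    self-loops, no duplicate pairs.
    """
    rng = _rng(config, _STREAM_EDGES)
    genes = catalog["gene_id"].tolist()
    planted = catalog["planted_module"].to_numpy()
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            within = planted[i] == planted[j]
            p = config.p_within if within else config.p_between
            lo, hi = config.score_within_range if within else config.score_between_range
            if rng.random() < p:
                rows.append((genes[i], genes[j], rng.uniform(lo, hi)))
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "combined_score"])


def generate_growth_table(config: SimConfig) -> pd.DataFrame:
    """Simulate per-replicate fresh weights and C/N percentages.

    Final weight = initial x (1 + rgr_true/100) x lognormal(0,
    growth_noise_sd) noise, so the noise-free table reproduces
    ``rgr_true`` exactly under the downstream RGR computation.
    """
    rng = _rng(config, _STREAM_GROWTH)
    rows = []
    for dose, og in config.conditions:
        cid = condition_id(dose, og)
        for rep in range(1, config.n_replicates + 1):
            w0 = config.w_initial_mean * (1.0 + config.w_initial_spread * rng.uniform(-1, 1))
            noise = (
                float(np.exp(rng.normal(0.0, config.growth_noise_sd)))
                if config.growth_noise_sd
                else 1.0
            )
            wf = w0 * (1.0 + config.rgr_true / 100.0) * noise
            c_pct = float(np.clip(rng.normal(config.c_pct_mean, config.c_pct_sd), 0, 100))
            n_pct = float(np.clip(rng.normal(config.n_pct_mean, config.n_pct_sd), 0, 100))
            rows.append((cid, rep, w0, wf, c_pct, n_pct))
    return pd.DataFrame(
        rows, columns=["condition_id", "replicate", "w_initial", "w_final", "c_pct", "n_pct"]
    )
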
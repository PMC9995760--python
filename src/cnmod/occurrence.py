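"""Occurrence-probability scoring and key-module identification.

Relative-expression values are right-skewed (approximately lognormal
under multiplicative qPCR noise), so each (tissue, condition) stratum is
first transformed toward normality with either sqrt or natural log —
whichever leaves the smaller absolute sample skewness.  Each gene's
transformed value is then scored against the stratum's empirical normal
distribution via the normal CDF,

    p = Phi((x - mu) / sigma),

giving its "occurrence probability" within the stratum.  A module's
response is summarized by the fraction of its gene-condition pairs with
p strictly above the threshold (default 0.75); the module maximizing
that fraction is called the key module, with mean p and then smallest
module id as tie-breakers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from cnmod.network import ModulePartition

__all__ = [
    "TransformSpec",
    "OccurrenceReport",
    "select_transform",
    "normcdf",
    "score_occurrence",
    "call_key_module",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class TransformSpec:
    """Normality transform chosen for one stratum.

    ``skew_sqrt``/``skew_ln`` record the adjusted Fisher-Pearson sample
    skewness of the candidate transforms (``skew_ln`` is None when a
    zero value makes ln ineligible).
    """

    name: str  # "sqrt" | "ln"
    skew_sqrt: float
    skew_ln: float | None

    def apply(self, values: np.ndarray) -> np.ndarray:
        if self.name == "sqrt":
            return np.sqrt(values)
        if self.name == "ln":
            return np.log(values)
        raise ValueError(f"unknown transform {self.name!r}")


def select_transform(values) -> TransformSpec:
    """Pick sqrt or ln, minimizing |sample skewness| after transform.

    Values must be nonnegative with at least 3 entries; ln is eligible
    only when all values are strictly positive.  Ties go to sqrt.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values to choose a transform")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.any(x < 0):
        raise ValueError("values must be nonnegative")
    with warnings.catch_warnings():
        # constant data makes skewness NaN; the tie rule then picks sqrt
        warnings.simplefilter("ignore", RuntimeWarning)
        skew_sqrt = float(stats.skew(np.sqrt(x), bias=False))
        if np.any(x == 0):
            return TransformSpec(name="sqrt", skew_sqrt=skew_sqrt, skew_ln=None)
        skew_ln = float(stats.skew(np.log(x), bias=False))
    name = "ln" if abs(skew_ln) < abs(skew_sqrt) else "sqrt"
    return TransformSpec(name=name, skew_sqrt=skew_sqrt, skew_ln=skew_ln)


def normcdf(x, mu: float = 0.0, sigma: float = 1.0):
    """Normal CDF Phi((x - mu)/sigma) via the complementary error function."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    z = (np.asarray(x, dtype=float) - mu) / sigma
    out = 0.5 * (1.0 + special.erf(z / _SQRT2))
    return float(out) if out.ndim == 0 else out


def score_occurrence(
    expr_aggregated: pd.DataFrame,
    genes: Sequence[str],
    tissue: str,
    conditions: Sequence[str],
) -> pd.DataFrame:
    """Occurrence probabilities per (gene, condition) in one tissue.

    ``expr_aggregated`` needs columns ``gene_id``, ``tissue``,
    ``condition_id``, ``mean_rel_expr``.  For each requested condition
    the mean relative expressions of all requested genes form the
    stratum: a normality transform is selected, mu-hat/sigma-hat are the
    stratum's sample mean and SD (n-1) of transformed values, and each
    gene is scored by the normal CDF.

    Returns a frame with columns gene_id, tissue, condition_id,
    transform, x_tilde, mu, sigma, p.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene set")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    rows = []
    sub = expr_aggregated.loc[expr_aggregated["tissue"] == tissue]
    for cond in conditions:
        stratum = sub.loc[sub["condition_id"] == cond].set_index("gene_id")["mean_rel_expr"]
        missing = sorted(set(genes) - set(stratum.index))
        if missing:
            raise ValueError(
                f"missing expression for genes {missing} in stratum ({tissue}, {cond})"
            )
        values = stratum.loc[genes].to_numpy(dtype=float)
        spec = select_transform(values)
        x = spec.apply(values)
        mu = float(np.mean(x))
        sigma = float(np.std(x, ddof=1))
        if sigma == 0.0:
            raise ValueError(
                f"degenerate stratum ({tissue}, {cond}): all transformed values identical"
            )
        p = normcdf(x, mu, sigma)
        for g, xt, pg in zip(genes, x, np.atleast_1d(p)):
            rows.append((g, tissue, cond, spec.name, float(xt), mu, sigma, float(pg)))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tissue", "condition_id", "transform", "x_tilde", "mu", "sigma", "p"],
    )


@dataclass
class OccurrenceReport:
    """Per-module exceedance aggregates and the key-module call.

    ``modules`` has one row per module: size, n_exceed (count of
    gene-condition probabilities strictly above the threshold),
    frac_exceed, mean_p, is_key_module.  ``tiebreak`` records which rule
    decided the call: "frac_exceed", "mean_p" or "module_id".
    """

    probabilities: pd.DataFrame
    modules: pd.DataFrame
    key_module: int
    threshold: float
    tiebreak: str


def call_key_module(
    probs: pd.DataFrame,
    partition: ModulePartition,
    threshold: float = 0.75,
) -> OccurrenceReport:
    """Identify the module whose genes most often exceed the threshold.

    frac_exceed(m) = #{(gene, condition): gene in m, p > threshold}
                     / (|m| x #conditions).

    The key module maximizes frac_exceed; exact ties fall back to the
    larger mean p, then to the smaller module id.  The comparison is
    strict: p equal to the threshold does not count as exceedance.
    """
    if len(probs) == 0:
        raise ValueError("empty probability set")
    missing = set(partition.membership) - set(probs["gene_id"])
    if missing:
        raise ValueError(f"probabilities missing for partitioned genes: {sorted(missing)}")
    df = probs.loc[probs["gene_id"].isin(partition.membership)].copy()
    df["module_id"] = df["gene_id"].map(partition.membership)
    n_conditions = df["condition_id"].nunique()
    sizes = partition.module_sizes

    recs = []
    for m, size in sizes.items():
        block = df.loc[df["module_id"] == m, "p"]
        n_exceed = int((block > threshold).sum())
        recs.append(
            {
                "module_id": m,
                "size": size,
                "n_exceed": n_exceed,
                "frac_exceed": n_exceed / (size * n_conditions),
                "mean_p": float(block.mean()),
            }
        )
    modules = pd.DataFrame(recs).sort_values("module_id").reset_index(drop=True)

    best_frac = modules["frac_exceed"].max()
    tied = modules.loc[np.isclose(modules["frac_exceed"], best_frac, rtol=0, atol=1e-12)]
    tiebreak = "frac_exceed"
    if len(tied) > 1:
        tiebreak = "mean_p"
        best_mean = tied["mean_p"].max()
        tied = tied.loc[np.isclose(tied["mean_p"], best_mean, rtol=0, atol=1e-12)]
        if len(tied) > 1:
            tiebreak = "module_id"
    key = int(tied["module_id"].min())
    modules["is_key_module"] = modules["module_id"] == key
    return OccurrenceReport(
        probabilities=df.reset_index(drop=True),
        modules=modules,
        key_module=key,
        threshold=threshold,
        tiebreak=tiebreak,
    )
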
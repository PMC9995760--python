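"""Relative growth rate and C/N% descriptive summaries.

RGR (%) = 100 x (W_final - W_initial) / W_initial on fresh weights.
Summaries are per-condition mean +/- sample SD (n-1 denominator); no
hypothesis testing is performed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rgr", "summarize_growth"]


def rgr(w_initial, w_final):
    """Relative growth rate in percent; accepts scalars or arrays."""
    w_initial = np.asarray(w_initial, dtype=float)
    w_final = np.asarray(w_final, dtype=float)
    if np.any(w_initial <= 0):
        raise ValueError("initial weight must be > 0")
    if np.any(w_final < 0):
        raise ValueError("final weight must be >= 0")
    out = 100.0 * (w_final - w_initial) / w_initial
    return float(out) if out.ndim == 0 else out


def summarize_growth(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and SD of RGR and (optional) C%/N%.

    Expects columns ``condition_id``, ``replicate``, ``w_initial``,
    ``w_final`` and optionally ``c_pct``/``n_pct``.  A condition with a
    single replicate reports SD as NaN, not 0.
    """
    required = {"condition_id", "replicate", "w_initial", "w_final"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"growth table missing columns: {sorted(missing)}")
    df = table.copy()
    df["rgr"] = rgr(df["w_initial"].to_numpy(), df["w_final"].to_numpy())
    metrics = ["rgr"] + [c for c in ("c_pct", "n_pct") if c in df.columns]
    pieces = {}
    grouped = df.groupby("condition_id", sort=False)
    for m in metrics:
        pieces[f"mean_{m}"] = grouped[m].mean()
        pieces[f"sd_{m}"] = grouped[m].std(ddof=1)
    pieces["n"] = grouped["replicate"].count()
    return pd.DataFrame(pieces).reset_index()
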
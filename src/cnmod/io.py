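"""TSV interchange helpers.

All artifacts are tab-separated UTF-8 text with a header row; lines
starting with '#' are comments.  Writers emit full double precision
(repr round-trip) so artifacts are byte-stable and reload exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = ["read_tsv", "write_tsv", "read_catalog"]


def write_tsv(df: pd.DataFrame, path, comments: Iterable[str] = ()) -> Path:
    """Write a frame as commented TSV; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    return path


def read_tsv(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv` ('#' comments ignored)."""
    return pd.read_csv(path, sep="\t", comment="#")


def read_catalog(path, with_truth: bool = False) -> pd.DataFrame:
    """Read a gene catalog TSV.

    The ``planted_module`` ground-truth column (present in synthetic
    catalogs) is dropped unless ``with_truth`` is set, so analysis code
    cannot accidentally consume it.
    """
    df = read_tsv(path)
    if not with_truth and "planted_module" in df.columns:
        df = df.drop(columns=["planted_module"])
    return df
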
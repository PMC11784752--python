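"""Tabular I/O: labeled CSV/TSV readers and writers with metadata sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .dataset import Dataset

__all__ = ["read_labeled_csv", "write_labeled_csv", "write_metadata"]


def read_labeled_csv(path, label_column: str = "label", sep: str = ",") -> Dataset:
    """Read a header-ed CSV/TSV of features plus one label column.

    All non-label cells must parse as finite reals; the first offending cell
    is reported with row/column coordinates.  Single-class files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep=sep, comment="#")
    return Dataset.from_dataframe(df, label_column)


def write_labeled_csv(
    dataset: Dataset, path, label_column: str = "label", sep: str = ","
) -> None:
    df = dataset.to_dataframe(label_column)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def write_metadata(out_path, params: dict) -> Path:
    """Write a ``<out>.meta.json`` sidecar recording version and parameters."""
    from . import __version__

    meta_path = Path(str(out_path) + ".meta.json")
    payload = {"version": __version__, **params}
    meta_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return meta_path
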
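"""Loaders for the small published reference tables shipped with the package.

These are the printed annotation of the Cerura menciana mitogenome and the
published 17-species composition/skew comparison, used as ground truth for
the arithmetic engines (the focal genome itself has no deposited sequence,
so sequence-level fixtures come from :mod:`mitochar.synthetic_data`).
"""

from __future__ import annotations

import io
from importlib import resources

import pandas as pd

from mitochar.mito_io import AnnotationTable, read_feature_table

__all__ = ["reference_annotation", "lepidoptera_composition"]


def _data_path(name: str):
    return resources.files("mitochar.data").joinpath(name)


def reference_annotation() -> AnnotationTable:
    """The printed C. menciana feature table (verbatim, anomalies included)."""
    with resources.as_file(_data_path("cerura_menciana_annotation.tsv")) as path:
        return read_feature_table(path, dialect="tsv")


def lepidoptera_composition() -> pd.DataFrame:
    """Published per-partition composition of 17 lepidopteran mitogenomes.

    Columns: species, partition (whole/PCG/tRNA/rRNA/control), size_bp,
    pct_A, pct_G, pct_T, pct_C, at_pct, and the printed at_skew/gc_skew.
    """
    text = _data_path("lepidoptera_composition.tsv").read_text()
    return pd.read_csv(io.StringIO(text), sep="\t", comment="#")
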
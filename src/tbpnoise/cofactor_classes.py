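"""Co-activator regulation classes from promoter occupancy tables.

Genes are called TFIID-regulated and/or SAGA-regulated by a median split
on promoter occupancy of a subunit specific to each co-activator (Taf1p
for TFIID, Spt20p for SAGA): a gene strictly above the across-gene median
for a factor is regulated by it.  The two calls combine into four classes
``+/+``, ``+/-``, ``-/+`` and ``-/-`` (TFIID / SAGA).  TBP turnover
values are binned into low/high halves around their median the same way.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "COACTIVATOR_CLASSES",
    "classify_coactivator",
    "rescale_center",
    "bin_turnover",
]

COACTIVATOR_CLASSES = ("+/+", "+/-", "-/+", "-/-")


def classify_coactivator(
    table: pd.DataFrame,
    tfiid_factor: str = "Taf1p",
    saga_factor: str = "Spt20p",
) -> pd.DataFrame:
    """Median-split co-activator classification of an occupancy table.

    Parameters
    ----------
    table
        One row per gene, indexed by gene id (or with a ``gene_id``
        column), one numeric column per factor; NaN marks a factor not
        detected at that promoter.

    Returns
    -------
    DataFrame indexed by gene id with columns ``tfiid_occ``, ``saga_occ``,
    ``tfiid_regulated``, ``saga_regulated`` and ``coactivator_class``.
    Genes missing either factor are excluded.  Each factor's median is
    taken over the genes where that factor was detected; occupancy
    exactly at the median counts as not regulated.
    """
    if "gene_id" in table.columns:
        table = table.set_index("gene_id")
    for col in (tfiid_factor, saga_factor):
        if col not in table.columns:
            raise ValueError(f"occupancy table lacks factor column {col!r}")
    tfiid = pd.to_numeric(table[tfiid_factor], errors="coerce")
    saga = pd.to_numeric(table[saga_factor], errors="coerce")
    tfiid_median = tfiid.median(skipna=True)
    saga_median = saga.median(skipna=True)
    keep = tfiid.notna() & saga.notna()
    out = pd.DataFrame(
        {
            "tfiid_occ": tfiid[keep],
            "saga_occ": saga[keep],
            "tfiid_regulated": tfiid[keep] > tfiid_median,
            "saga_regulated": saga[keep] > saga_median,
        }
    )
    out["coactivator_class"] = [
        f"{'+' if t else '-'}/{'+' if s else '-'}"
        for t, s in zip(out["tfiid_regulated"], out["saga_regulated"])
    ]
    out.attrs["tfiid_median"] = float(tfiid_median)
    out.attrs["saga_median"] = float(saga_median)
    return out


def rescale_center(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize every numeric factor column (subtract mean, divide by s.d.).

    Purely cosmetic for plotting: a per-column affine map cannot change
    which genes sit above the column median, so classification of the
    rescaled table equals that of the original.  Zero-variance columns
    are centered only, with a warning.
    """
    out = table.copy()
    num_cols = out.select_dtypes(include=[np.number]).columns
    for col in num_cols:
        values = out[col].astype(float)
        mean = values.mean(skipna=True)
        sd = values.std(skipna=True, ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            warnings.warn(
                f"column {col!r} has zero variance: centered only",
                stacklevel=2,
            )
            out[col] = values - mean
        else:
            out[col] = (values - mean) / sd
    return out


def bin_turnover(values: pd.Series | dict) -> pd.DataFrame:
    """Split TBP turnover values into low/high bins around their median.

    At or below the median is "low", above it "high".  The bin
    boundaries (min, median, max) are reported in ``DataFrame.attrs``.
    """
    series = pd.Series(values, dtype=float)
    if series.empty:
        raise ValueError("turnover table is empty")
    median = float(series.median())
    out = pd.DataFrame(
        {
            "turnover": series,
            "turnover_bin": np.where(series > median, "high", "low"),
        }
    )
    out.attrs["low_bin"] = (float(series.min()), median)
    out.attrs["high_bin"] = (median, float(series.max()))
    return out
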
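"""Protein-binding microarray (PBM) signal aggregation for TBS 8-mers.

PBM chips measure a protein's intrinsic affinity for every 8-mer via
many replicate probes.  Replicate intensities for the same motif are
collapsed to their median, and the per-motif medians are compared across
TBS classes (TATA-box vs TATA-like vs other, and the T5 vs A5 TATA-box
subsets) with rank-sum tests under Benjamini-Hochberg correction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .noise_metrics import bh_adjust, rank_sum_test
from .tbs_classify import classify_tbs

__all__ = ["aggregate_probe_signal", "class_signal_summary"]


def aggregate_probe_signal(probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate probe intensities to one median per motif.

    Parameters
    ----------
    probes
        Columns ``motif`` (8-mer) and ``intensity``; one row per probe.
        Replicate probes of the same motif are expected.

    Returns
    -------
    DataFrame with one row per motif: ``motif``, ``median_intensity``,
    ``n_probes`` and ``single_replicate`` (True when only one probe
    carried the motif — the median then is a lone measurement).  Even
    replicate counts use the midpoint of the central pair.
    """
    if probes.empty:
        raise ValueError("probe table is empty")
    if not np.isfinite(probes["intensity"]).all():
        raise ValueError("probe intensities must be finite")
    grouped = probes.groupby("motif", sort=True)["intensity"]
    out = grouped.agg(median_intensity="median", n_probes="size").reset_index()
    out["single_replicate"] = out["n_probes"] == 1
    return out


def class_signal_summary(
    medians: pd.DataFrame,
    probes: pd.DataFrame | None = None,
    min_class_size: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare PBM signal across TBS classes.

    Each motif is classified by sequence; motifs are grouped into
    TATA-box, TATA-like and other, plus the T5/A5 subsets of the exact
    TATA-box matches.  Class comparisons use the per-motif medians.
    Only 4 exact consensus 8-mers exist per T5/A5 subset, so when the
    raw ``probes`` table is supplied the subset comparison is run on the
    intensities of all probes hosting those motifs instead (the box-plot
    of probe signal per motif group).

    Returns ``(summary, comparisons)``:

    * ``summary`` — per group: n motifs, median and quartiles;
    * ``comparisons`` — pairwise groups with Wilcoxon rank-sum
      statistic, raw p-value and BH-adjusted p-value; pairs where either
      group has fewer than ``min_class_size`` values are flagged
      ``skipped`` with NaN statistics.
    """
    medians = medians.copy()
    classified = [classify_tbs(m) for m in medians["motif"]]
    medians["tbs_class"] = [c[0] for c in classified]
    medians["subset"] = [c[1] for c in classified]

    groups: dict[str, np.ndarray] = {}
    for cls in ("TATA-box", "TATA-like", "other"):
        groups[cls] = medians.loc[
            medians["tbs_class"] == cls, "median_intensity"
        ].to_numpy()
    for sub in ("T5", "A5"):
        if probes is not None:
            subset_motifs = set(medians.loc[medians["subset"] == sub, "motif"])
            groups[sub] = probes.loc[
                probes["motif"].isin(subset_motifs), "intensity"
            ].to_numpy()
        else:
            groups[sub] = medians.loc[
                medians["subset"] == sub, "median_intensity"
            ].to_numpy()

    summary = pd.DataFrame(
        [
            {
                "group": name,
                "n_motifs": values.size,
                "median": float(np.median(values)) if values.size else np.nan,
                "q1": float(np.percentile(values, 25)) if values.size else np.nan,
                "q3": float(np.percentile(values, 75)) if values.size else np.nan,
            }
            for name, values in groups.items()
        ]
    )

    pairs = [
        ("TATA-box", "TATA-like"),
        ("TATA-box", "other"),
        ("TATA-like", "other"),
        ("T5", "A5"),
    ]
    rows = []
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        if xa.size < min_class_size or xb.size < min_class_size:
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "n_a": xa.size,
                    "n_b": xb.size,
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "skipped": True,
                }
            )
            continue
        stat, p = rank_sum_test(xa, xb)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "n_a": xa.size,
                "n_b": xb.size,
                "statistic": stat,
                "p_value": p,
                "skipped": False,
            }
        )
    comparisons = pd.DataFrame(rows)
    tested = ~comparisons["skipped"]
    adjusted = np.full(len(comparisons), np.nan)
    if tested.any():
        adjusted[tested.to_numpy()] = bh_adjust(
            comparisons.loc[tested, "p_value"].to_list()
        )
    comparisons["p_adjusted"] = adjusted
    return summary, comparisons
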
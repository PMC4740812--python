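"""Flow-cytometry processing: gating, size correction and expression noise.

The chain mirrors the GFP reporter-noise protocol: (1) discard events
outside the open 18-bit ADC range on both scatter channels and trim the
top and bottom 5% by total scattering; (2) gate to the small (unbudded)
subpopulation below the median of total scattering (FSC-A x SSC-A);
(3) regress GFP on FSC-A and SSC-A and size-correct the fluorescence
with the fitted values; (4) report the CV of the corrected fluorescence
per replicate, averaged across replicates with a standard error.

All stages are deterministic subset selections or annotations: event
order is preserved and nothing is ever modified in place.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "ADC_CEILING",
    "filter_events",
    "gate_small_cells",
    "size_correct",
    "noise_from_events",
    "process_sample",
]

#: Exclusive upper bound of the 18-bit scatter digitizer, 2**18 - 1.
ADC_CEILING = 2**18 - 1

REQUIRED_COLUMNS = ("fsc_a", "ssc_a", "gfp")


def _check_events(events: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table lacks columns {missing}")


def _scatter_score(events: pd.DataFrame) -> pd.Series:
    return events["fsc_a"] * events["ssc_a"]


def filter_events(
    events: pd.DataFrame, tail_fraction: float = 0.05, per_channel: bool = False
) -> pd.DataFrame:
    """Remove out-of-range and extreme-scatter events.

    Keeps events with ``0 < FSC-A < 2**18 - 1`` and the same open bounds
    on SSC-A, then discards the ``tail_fraction`` of events with the
    lowest and highest scattering.  By default "the scattering" is the
    product FSC-A x SSC-A; with ``per_channel=True`` the tails are
    trimmed on each channel separately.  Tail counts are rank-based:
    ``floor(tail_fraction * n)`` events from each end.
    """
    _check_events(events)
    if events.empty:
        raise ValueError("empty event table")
    in_range = (
        (events["fsc_a"] > 0)
        & (events["fsc_a"] < ADC_CEILING)
        & (events["ssc_a"] > 0)
        & (events["ssc_a"] < ADC_CEILING)
    )
    kept = events[in_range]
    if kept.empty:
        raise ValueError("all events removed by the ADC range filter")

    def _trim(frame: pd.DataFrame, score: pd.Series) -> pd.DataFrame:
        n_drop = int(np.floor(tail_fraction * len(frame)))
        if n_drop == 0:
            return frame
        order = score.to_numpy().argsort(kind="stable")
        keep_pos = np.sort(order[n_drop : len(frame) - n_drop])
        return frame.iloc[keep_pos]

    if per_channel:
        for channel in ("fsc_a", "ssc_a"):
            kept = _trim(kept, kept[channel])
    else:
        kept = _trim(kept, _scatter_score(kept))
    if kept.empty:
        raise ValueError("all events removed by the scatter tail trim")
    return kept


def gate_small_cells(
    events: pd.DataFrame, cutoff: float = 0.5
) -> pd.DataFrame:
    """Gate to the small-cell subpopulation by total scattering.

    Keeps events whose FSC-A x SSC-A product lies strictly below the
    ``cutoff`` quantile of that product (default: the median).  If the
    strict rule would keep nothing (degenerate ties), falls back to
    ``<=`` with a warning.
    """
    _check_events(events)
    product = _scatter_score(events)
    if cutoff >= 1.0:
        return events
    threshold = product.quantile(cutoff)
    kept = events[product < threshold]
    if kept.empty:
        warnings.warn(
            "no event strictly below the scatter cutoff; "
            "falling back to <= (tied scatter values)",
            stacklevel=2,
        )
        kept = events[product <= threshold]
    return kept


def size_correct(
    events: pd.DataFrame, method: str = "squared"
) -> pd.DataFrame:
    """Regress out cell size from GFP fluorescence.

    Fits the ordinary least-squares model ``GFP ~ FSC-A + SSC-A`` (with
    intercept) and derives size-corrected fluorescence from the fitted
    values:

    * ``method="squared"`` (default): ``gfp_corrected = gfp**2 / fitted``,
      the protocol's printed correction;
    * ``method="ratio"``: ``gfp_corrected = gfp / fitted``, the
      conventional normalisation that recovers the underlying expression
      CV when fluorescence scales multiplicatively with size.

    Events with non-positive fitted values get ``corrected_valid=False``
    and are excluded from downstream CVs.  Residual summaries of the fit
    are attached in ``DataFrame.attrs["fit"]``.
    """
    _check_events(events)
    if len(events) < 3:
        raise ValueError("size correction needs at least 3 events to fit")
    if method not in ("squared", "ratio"):
        raise ValueError(f"unknown correction method {method!r}")
    design = sm.add_constant(events[["fsc_a", "ssc_a"]].astype(float))
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError("rank-deficient design (constant scatter channel?)")
    fit = sm.OLS(events["gfp"].astype(float), design).fit()
    fitted = fit.fittedvalues
    out = events.copy()
    valid = fitted > 0
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} events with non-positive fitted GFP "
            "flagged and excluded from CV",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "squared":
            corrected = events["gfp"] ** 2 / fitted
        else:
            corrected = events["gfp"] / fitted
    out["gfp_corrected"] = np.where(valid, corrected, np.nan)
    out["corrected_valid"] = valid
    out.attrs["fit"] = {
        "params": fit.params.to_dict(),
        "r_squared": float(fit.rsquared),
        "residual_mean": float(fit.resid.mean()),
        "residual_sd": float(fit.resid.std(ddof=1)),
        "method": method,
    }
    return out


def noise_from_events(events: pd.DataFrame) -> dict:
    """Per-replicate CV of corrected GFP, averaged across replicates.

    Requires :func:`size_correct` to have been applied.  Returns a dict
    with ``per_replicate`` (replicate id -> CV), ``mean_cv`` and
    ``se`` (s.d. of replicate CVs / sqrt(k); NaN for a single
    replicate).
    """
    if "gfp_corrected" not in events.columns:
        raise ValueError("run size_correct before computing noise")
    valid = events[events["corrected_valid"]]
    if "replicate" in valid.columns:
        groups = dict(tuple(valid.groupby("replicate")))
    else:
        groups = {1: valid}
    per_replicate: dict = {}
    for rep, frame in groups.items():
        if len(frame) < 2:
            raise ValueError(
                f"replicate {rep!r} has fewer than 2 valid events"
            )
        g = frame["gfp_corrected"].to_numpy()
        per_replicate[rep] = float(g.std(ddof=1) / g.mean())
    cvs = np.array(list(per_replicate.values()))
    if cvs.size > 1:
        se = float(cvs.std(ddof=1) / np.sqrt(cvs.size))
    else:
        warnings.warn("single replicate: standard error undefined", stacklevel=2)
        se = float("nan")
    return {
        "per_replicate": per_replicate,
        "mean_cv": float(cvs.mean()),
        "se": se,
        "n_replicates": int(cvs.size),
    }


def process_sample(
    events: pd.DataFrame,
    tail_fraction: float = 0.05,
    cutoff: float = 0.5,
    method: str = "squared",
) -> tuple[dict, pd.DataFrame]:
    """Run the full chain (filter -> gate -> correct -> CV) on one sample.

    Filtering, gating and regression are applied within each replicate
    so that gates adapt to per-run instrument drift.  Returns
    ``(noise summary, processed events)`` plus per-stage event counts in
    the summary under ``stage_counts``.
    """
    _check_events(events)
    if "replicate" in events.columns:
        replicates = dict(tuple(events.groupby("replicate")))
    else:
        replicates = {1: events}
    processed = []
    counts = {"input": len(events), "filtered": 0, "gated": 0}
    for rep, frame in replicates.items():
        filtered = filter_events(frame, tail_fraction=tail_fraction)
        gated = gate_small_cells(filtered, cutoff=cutoff)
        corrected = size_correct(gated, method=method)
        counts["filtered"] += len(filtered)
        counts["gated"] += len(gated)
        processed.append(corrected)
    merged = pd.concat(processed, axis=0)
    summary = noise_from_events(merged)
    summary["stage_counts"] = counts
    return summary, merged
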
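"""Per-contraction mechanics: normalized shortening (dL/L), fluorescence
change (dF/F), grouped summaries, and their correlation.

dL/L = 100 x (onset length - minimum length) / onset length, measured at
the minimum-length frame within the event window; dF/F = 100 x
(max fluorescence - onset fluorescence) / onset fluorescence.  Positive
dL/L is shortening; lengthening events (negative dL/L) are retained and
flagged, not clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, UndefinedStatisticError, ValidationError

REQUIRED = ("f_onset", "f_max", "length_onset_um", "length_min_um")


def contraction_metrics(events: pd.DataFrame) -> pd.DataFrame:
    """Append ``dl_l_pct``, ``df_f_pct`` and a ``lengthening`` flag to an
    event table carrying onset/max fluorescence and onset/min fiber length."""
    missing = [c for c in REQUIRED if c not in events.columns]
    if missing:
        raise ValidationError(f"missing columns {missing}")
    if (events["f_onset"] <= 0).any():
        raise ValidationError("nonpositive onset fluorescence")
    if (events["length_onset_um"] <= 0).any():
        raise ValidationError("nonpositive onset length")
    out = events.copy()
    out["dl_l_pct"] = 100.0 * (
        (out["length_onset_um"] - out["length_min_um"]) / out["length_onset_um"]
    )
    out["df_f_pct"] = 100.0 * ((out["f_max"] - out["f_onset"]) / out["f_onset"])
    out["lengthening"] = out["dl_l_pct"] < 0
    return out


def aggregate_metrics(metrics: pd.DataFrame, by=("muscle",)) -> pd.DataFrame:
    """Per-group mean, SD, and count of dL/L and dF/F; empty groups are
    omitted (with a warning when the grouping key has unused categories)."""
    by = list(by)
    for key in by:
        if key not in metrics.columns:
            raise ValidationError(f"missing grouping column {key!r}")
    if metrics.empty:
        warnings.warn("no contractions to aggregate")
        return pd.DataFrame(columns=by)
    agg = (
        metrics.groupby(by, observed=True)[["dl_l_pct", "df_f_pct"]]
        .agg(["mean", "std", "count"])
    )
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()


@dataclass
class CorrelationResult:
    """Pearson r between dF/F and shortening, under both sign codings.

    ``r_shortening`` correlates dF/F with positive-shortening dL/L;
    ``r_length_change`` uses the signed length change (negative when the
    fiber shortens), so the two differ only in sign.
    """

    r_shortening: float
    r_length_change: float
    p_value: float
    n: int


def shortening_fluorescence_correlation(metrics: pd.DataFrame) -> CorrelationResult:
    """Pearson correlation between dF/F and dL/L over contractions."""
    needed = {"dl_l_pct", "df_f_pct"}
    if not needed <= set(metrics.columns):
        raise ValidationError("run contraction_metrics first")
    x = metrics["df_f_pct"].to_numpy(float)
    y = metrics["dl_l_pct"].to_numpy(float)
    if x.size < 3:
        raise InsufficientDataError("need >= 3 contractions")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(-r), float(p), int(x.size))
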
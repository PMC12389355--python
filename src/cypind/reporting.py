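"""Outcome assembly: method-comparison tables, DDI band classification, and
optional plots.

AUC ratios are classified against two conventional bands: the average
bioequivalence range [0.8, 1.25] ("no interaction") and the wider [0.5, 2.0]
range outside of which an interaction is considered clinically significant.
Boundaries are closed on the inside of each band.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .pbpk import DDIOutcome

__all__ = ["classify_band", "build_comparison", "plot_aucr_bands", "plot_arms"]

BAND_BIOEQUIVALENT = (0.8, 1.25)
BAND_NON_SIGNIFICANT = (0.5, 2.0)


def classify_band(aucr: float) -> str:
    """``bioequivalent`` in [0.8, 1.25]; ``non-significant`` in [0.5, 2.0]
    outside the former; ``significant`` beyond that."""
    if not np.isfinite(aucr) or aucr <= 0:
        raise InvalidInputError("AUCR must be a positive finite number")
    if BAND_BIOEQUIVALENT[0] <= aucr <= BAND_BIOEQUIVALENT[1]:
        return "bioequivalent"
    if BAND_NON_SIGNIFICANT[0] <= aucr <= BAND_NON_SIGNIFICANT[1]:
        return "non-significant"
    return "significant"


def _as_aucr(value, victim: str) -> float:
    """Observed entries must state their convention explicitly:
    {"aucr": x} or {"pct_reduction": x}."""
    if isinstance(value, Mapping):
        if "aucr" in value:
            return float(value["aucr"])
        if "pct_reduction" in value:
            return 1.0 - float(value["pct_reduction"]) / 100.0
    raise InvalidInputError(
        f"observed value for {victim!r} must be a mapping with 'aucr' or "
        "'pct_reduction' (units/convention must be explicit)"
    )


def build_comparison(
    outcomes: Mapping[str, DDIOutcome | float],
    msm_results: Mapping[str, float] | None = None,
    observed: Mapping[str, Mapping] | None = None,
    order: list[str] | None = None,
) -> pd.DataFrame:
    """One row per victim comparing dynamic, static and (optionally)
    user-supplied observed AUC ratios.

    ``outcomes`` maps victim -> :class:`DDIOutcome` or a bare AUCR;
    ``msm_results`` maps victim -> static AUCR. Percent reductions are
    derived as 100*(1 - AUCR), so the columns are mutually consistent by
    construction. Fold error (dynamic vs observed) is max/min >= 1.
    """
    if not outcomes:
        raise InvalidInputError("at least one victim outcome required")
    victims = order or list(outcomes)
    rows = []
    for victim in victims:
        out = outcomes[victim]
        aucr = out.aucr if isinstance(out, DDIOutcome) else float(out)
        row: dict[str, object] = {
            "victim": victim,
            "aucr_dynamic": aucr,
            "pct_reduction_dynamic": 100.0 * (1.0 - aucr),
            "band_dynamic": classify_band(aucr),
        }
        if msm_results and victim in msm_results:
            m = float(msm_results[victim])
            row["aucr_static"] = m
            row["pct_reduction_static"] = 100.0 * (1.0 - m)
            row["band_static"] = classify_band(m)
        if observed and victim in observed:
            obs = _as_aucr(observed[victim], victim)
            row["aucr_observed"] = obs
            row["pct_reduction_observed"] = 100.0 * (1.0 - obs)
            row["band_observed"] = classify_band(obs)
            row["fold_error_dynamic"] = max(aucr, obs) / min(aucr, obs)
        rows.append(row)
    return pd.DataFrame(rows)


def plot_aucr_bands(comparison: pd.DataFrame, ax=None):
    """Dot plot of AUC ratios per victim with the 0.8-1.25 and 0.5-2.0 bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    x = np.arange(len(comparison))
    styles = {
        "aucr_dynamic": ("o", "tab:green", "dynamic"),
        "aucr_static": ("s", "tab:red", "static"),
        "aucr_observed": ("^", "tab:blue", "observed"),
    }
    for col, (marker, color, label) in styles.items():
        if col in comparison:
            ax.scatter(x, comparison[col], marker=marker, color=color, label=label)
    for y in BAND_BIOEQUIVALENT:
        ax.axhline(y, color="red", ls="--", lw=0.8)
    for y in BAND_NON_SIGNIFICANT:
        ax.axhline(y, color="blue", ls=":", lw=0.8)
    ax.set_yscale("log")
    ax.set_xticks(x, comparison["victim"], rotation=45, ha="right")
    ax.set_ylabel("AUC ratio (with / without perpetrator)")
    ax.legend()
    return ax


def plot_arms(outcome: DDIOutcome, ax=None, log_y: bool = True):
    """Two-arm victim concentration-time overlay."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for arm, grp in outcome.series.groupby("arm"):
        ax.plot(grp["time_h"], grp["conc_uM"], label=arm)
    if log_y:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("victim concentration (uM)")
    ax.legend()
    return ax
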
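"""Mechanistic static model (MSM) for induction-mediated DDI risk.

Per enzyme the basic induction ratio follows the ICH M12 basic model

    R3 = 1 / (1 + d * (Emax - 1) * I / (EC50 + I)),

where ``I`` is the inducer exposure used as input, here ``multiplier x
Imax,u`` (the regulatory convention applies a 10x correction to the maximal
unbound plasma concentration for CYP3A4; this implementation applies 10x to
every enzyme by default, with a per-enzyme override). The fitted Emax in this
package is the *total* fold induction (baseline 1), so the induction
amplitude entering R3 is ``Emax - 1``; the guidance-style convention that
treats Emax itself as the amplitude is available via
``emax_convention="fold"``.

Victim exposure is then the fm-weighted net effect,

    AUCR = 1 / (sum_i fm_i * FC_i + (1 - sum_i fm_i)),   FC_i = 1 / R3_i,

i.e. induced pathways speed up by their fold clearance change while the
residual (non-induced) clearance fraction is untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError, NoCallError

__all__ = [
    "EnzymeInduction",
    "StaticInput",
    "FmMap",
    "r3",
    "fold_cl_change",
    "net_auc_ratio",
    "msm_table",
]


@dataclass(frozen=True)
class EnzymeInduction:
    """Induction parameters for one enzyme: EC50 (uM) and total-fold Emax."""

    ec50_uM: float
    emax_fold: float

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0:
            raise InvalidInputError("EC50 must be > 0")
        if self.emax_fold < 1:
            raise InvalidInputError("Emax (total fold) must be >= 1")


@dataclass(frozen=True)
class StaticInput:
    """Inputs to the static model for one perpetrator.

    ``induction`` maps enzyme name to :class:`EnzymeInduction`, or ``None``
    for an explicit no-call. ``imax_u_uM`` is the maximal unbound plasma
    concentration of the perpetrator; ``input_multiplier`` scales it into the
    exposure term I (default 10, the regulatory correction factor), either as
    a scalar applied to all enzymes or as a per-enzyme mapping.
    """

    induction: Mapping[str, EnzymeInduction | None]
    imax_u_uM: float
    d: float = 1.0
    input_multiplier: float | Mapping[str, float] = 10.0
    emax_convention: str = "fold_minus_one"

    def __post_init__(self) -> None:
        if self.imax_u_uM <= 0:
            raise InvalidInputError("Imax,u must be > 0")
        if self.d <= 0:
            raise InvalidInputError("scaling factor d must be > 0")
        mult = self.input_multiplier
        vals = mult.values() if isinstance(mult, Mapping) else [mult]
        if any(m <= 0 for m in vals):
            raise InvalidInputError("input multiplier must be > 0")
        if self.emax_convention not in ("fold_minus_one", "fold"):
            raise InvalidInputError(
                "emax_convention must be 'fold_minus_one' or 'fold'"
            )

    def exposure(self, enzyme: str) -> float:
        mult = self.input_multiplier
        m = mult.get(enzyme, 10.0) if isinstance(mult, Mapping) else mult
        return m * self.imax_u_uM


@dataclass(frozen=True)
class FmMap:
    """Fraction of a victim drug's clearance carried by each CYP.

    The residual ``1 - sum(fm)`` is the non-induced clearance fraction
    (other enzymes, renal, biliary)."""

    victim: str
    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        for enz, fm in self.entries.items():
            if not 0.0 <= fm <= 1.0:
                raise InvalidInputError(f"fm[{enz}] = {fm} outside [0, 1]")
        if sum(self.entries.values()) > 1.0 + 1e-9:
            raise InvalidInputError("fm values sum to more than 1")

    @property
    def residual(self) -> float:
        return max(0.0, 1.0 - sum(self.entries.values()))


def r3(static_input: StaticInput, enzyme: str) -> float:
    """Basic static induction ratio for one enzyme; in (0, 1], equal to 1
    when Emax = 1 (no induction) or exposure is nil. Raises
    :class:`NoCallError` for an NC enzyme -- an undefined ratio, deliberately
    distinct from R3 = 1."""
    if enzyme not in static_input.induction:
        raise InvalidInputError(f"no induction entry for {enzyme}")
    params = static_input.induction[enzyme]
    if params is None:
        raise NoCallError(
            f"{enzyme} induction is a no-call; R3 is undefined (not 1)"
        )
    exposure = static_input.exposure(enzyme)
    amplitude = (
        params.emax_fold - 1.0
        if static_input.emax_convention == "fold_minus_one"
        else params.emax_fold
    )
    return 1.0 / (
        1.0 + static_input.d * amplitude * exposure / (params.ec50_uM + exposure)
    )


def fold_cl_change(static_input: StaticInput, enzyme: str) -> float:
    """Fold increase of the enzyme's clearance pathway, 1/R3 (>= 1)."""
    return 1.0 / r3(static_input, enzyme)


def net_auc_ratio(fm_map: FmMap, fold_changes: Mapping[str, float]) -> float:
    """fm-weighted net AUC ratio in (0, 1].

    ``fold_changes`` maps enzyme to its fold clearance change (>= 1). An fm
    entry lacking a fold-change entry is treated as uninduced (FC = 1) with a
    warning, so a victim metabolized by an enzyme the perpetrator does not
    touch dilutes the interaction rather than invalidating it.
    """
    denom = fm_map.residual
    for enzyme, fm in fm_map.entries.items():
        if enzyme in fold_changes:
            fc = fold_changes[enzyme]
            if fc < 1.0:
                raise InvalidInputError(f"fold change for {enzyme} must be >= 1")
        else:
            warnings.warn(
                f"{fm_map.victim}: no fold-change for {enzyme}; treated as uninduced",
                stacklevel=2,
            )
            fc = 1.0
        denom += fm * fc
    if denom <= 0:
        raise InvalidInputError("degenerate fm map (all-zero weights)")
    return 1.0 / denom


def msm_table(
    donor_induction: Mapping[str, Mapping[str, EnzymeInduction | None]],
    fm_maps: Iterable[FmMap],
    imax_u_uM: float,
    d: float = 1.0,
    input_multiplier: float | Mapping[str, float] = 10.0,
    emax_convention: str = "fold_minus_one",
) -> pd.DataFrame:
    """Static-model AUC ratios per victim, computed per donor then summarised.

    ``donor_induction`` maps donor label -> enzyme -> parameters (None = NC).
    Enzymes that are NC in a given donor are treated as uninduced for that
    donor's net ratio; a victim whose every fm enzyme is NC in every donor is
    reported as a no-call row (NaN ratios).

    Returns one row per victim with per-donor AUCRs, the across-donor mean and
    range, and the percent AUC reduction (100 * (1 - mean AUCR)).
    """
    donors = list(donor_induction)
    if not donors:
        raise InvalidInputError("at least one donor required")
    rows = []
    for fm_map in fm_maps:
        per_donor: dict[str, float] = {}
        for donor in donors:
            si = StaticInput(
                induction=donor_induction[donor],
                imax_u_uM=imax_u_uM,
                d=d,
                input_multiplier=input_multiplier,
                emax_convention=emax_convention,
            )
            fcs: dict[str, float] = {}
            any_called = False
            for enzyme in fm_map.entries:
                params = donor_induction[donor].get(enzyme)
                if params is None:
                    continue  # NC or absent: uninduced for this donor
                fcs[enzyme] = fold_cl_change(si, enzyme)
                any_called = True
            if any_called:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    per_donor[donor] = net_auc_ratio(fm_map, fcs)
        row: dict[str, object] = {"victim": fm_map.victim}
        for donor in donors:
            row[f"aucr_{donor}"] = per_donor.get(donor, np.nan)
        if per_donor:
            vals = np.array(list(per_donor.values()))
            row["aucr_mean"] = float(vals.mean())
            row["aucr_min"] = float(vals.min())
            row["aucr_max"] = float(vals.max())
            row["pct_auc_reduction"] = 100.0 * (1.0 - float(vals.mean()))
            row["no_call"] = False
        else:
            row["aucr_mean"] = np.nan
            row["aucr_min"] = np.nan
            row["aucr_max"] = np.nan
            row["pct_auc_reduction"] = np.nan
            row["no_call"] = True
        rows.append(row)
    return pd.DataFrame(rows)
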
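"""Dynamic induction DDI engine: perpetrator PK, enzyme turnover, victim
disposition.

Model structure
---------------
*Perpetrator* kinetics are linear one-compartment with first-order oral
absorption (or a zero-order infusion), solved in closed form by superposition
of doses. The induction driver is the unbound hepatic-inlet concentration

    C_driver(t) = Kp,uu * fu * (C_plasma(t) + ka * A_gut(t) / Q_h),

where the absorption-rate term is the classical hepatic-inlet correction and
Kp,uu is an optional hepatocellular unbound partition (e.g. OATP-mediated
uptake for rifampicin). A systemic-only driver is available via settings.

*Enzymes* follow zero-order synthesis / first-order degradation turnover:

    dE/dt = kdeg * (1 + (Emax - 1) * C(t) / (EC50 + C(t))) - kdeg * E,

with E the relative abundance (baseline 1). The stimulation term is
hyperbolic (slope 1) irrespective of the fitted Hill slope, matching static
induction models. An optional enterocyte CYP3A4 pool with its own kdeg is
driven by a gut-lumen surrogate concentration ka * A_gut(t) / Q_gut.

*Victim* disposition is a semi-physiological one-compartment oral model with
a well-stirred liver: the instantaneous intrinsic clearance is partitioned
across enzymes by fm,

    CL_int(t) = CL_int,0 * (sum_i fm_i * E_i(t) + 1 - sum_i fm_i),
    CL_h(t)   = Q_h * fu * CL_int(t) / (Q_h + fu * CL_int(t)),

absorbed drug passes sequentially through gut wall (F_g) and liver (F_h)
before reaching the systemic compartment, so the oral exposure obeys
AUC_po = Fa * Fg * Dose / (fu * CL_int) in the static limit. AUC is computed
by the trapezoid rule on a fine output grid plus C_last/k_el extrapolation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator
from scipy.integrate import solve_ivp

from .errors import InvalidInputError, ValidationError
from .static import EnzymeInduction, FmMap

__all__ = [
    "CompoundPK",
    "DosingRegimen",
    "DDIDesign",
    "EnzymeSettings",
    "CompoundModel",
    "PerpetratorExposure",
    "DDIOutcome",
    "simulate_perpetrator",
    "enzyme_dynamics",
    "victim_clearance",
    "run_ddi",
    "sensitivity_scan",
]

#: default hepatic blood flow, L/h (70 kg adult)
Q_HEPATIC_L_H = 97.0
#: default enterocyte (villous) blood flow for the gut-wall surrogate, L/h
Q_GUT_L_H = 18.0


class CompoundPK(BaseModel):
    """Base pharmacokinetic parameters of one compound.

    ``cl_L_h`` is the systemic (hepatic + renal) clearance used to derive the
    baseline intrinsic clearance; ``fg0`` is the baseline fraction escaping
    gut-wall metabolism (1 = no gut extraction); ``liver_kpuu`` scales the
    unbound hepatic driver for compounds with active hepatic uptake.
    """

    model_config = ConfigDict(frozen=True)

    mw_g_mol: float
    ka_per_h: float
    fa: float
    v_L: float
    cl_L_h: float
    fu_plasma: float
    bp_ratio: float = 1.0
    fg0: float = 1.0
    cl_renal_L_h: float = 0.0
    liver_kpuu: float = 1.0

    @field_validator("mw_g_mol", "ka_per_h", "v_L", "cl_L_h", "bp_ratio", "liver_kpuu")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("fa", "fu_plasma", "fg0")
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("must be in (0, 1]")
        return v

    @field_validator("cl_renal_L_h")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    def dose_umol(self, dose_mg: float) -> float:
        return dose_mg * 1000.0 / self.mw_g_mol


class DosingRegimen(BaseModel):
    """Repeated-dose schedule. ``route`` is ``oral`` or ``infusion``
    (zero-order input over ``duration_h``, used for steady-exposure
    analyses)."""

    model_config = ConfigDict(frozen=True)

    dose_mg: float
    interval_h: float = 24.0
    n_doses: int = 1
    start_h: float = 0.0
    route: str = "oral"
    duration_h: float | None = None

    @field_validator("dose_mg")
    @classmethod
    def _nonneg_dose(cls, v: float) -> float:
        if v < 0:
            raise ValueError("dose must be >= 0")
        return v

    @field_validator("interval_h")
    @classmethod
    def _pos_interval(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("interval must be > 0")
        return v

    @field_validator("n_doses")
    @classmethod
    def _pos_n(cls, v: int) -> int:
        if v < 1:
            raise ValueError("n_doses must be >= 1")
        return v

    @model_validator(mode="after")
    def _check_route(self) -> "DosingRegimen":
        if self.route not in ("oral", "infusion"):
            raise ValueError("route must be 'oral' or 'infusion'")
        if self.route == "infusion" and (self.duration_h is None or self.duration_h <= 0):
            raise ValueError("infusion requires duration_h > 0")
        return self

    @property
    def dose_times(self) -> np.ndarray:
        return self.start_h + self.interval_h * np.arange(self.n_doses)

    @property
    def end_h(self) -> float:
        return float(self.dose_times[-1]) + (
            self.duration_h if self.route == "infusion" and self.duration_h else 0.0
        )


class DDIDesign(BaseModel):
    """A paired perpetrator/victim dosing design. The victim regimen's
    ``start_h`` is on the perpetrator clock (e.g. 97 h = one hour after the
    day-5 perpetrator dose)."""

    model_config = ConfigDict(frozen=True)

    perpetrator: DosingRegimen
    victim: DosingRegimen
    label: str = ""


@dataclass(frozen=True)
class EnzymeSettings:
    """Turnover and physiology configuration shared by a simulation.

    kdeg values are first-order enzyme degradation rate constants (1/h); the
    gut CYP3A4 pool turns over faster than the hepatic pool. ``driver`` picks
    the hepatic induction driver: unbound hepatic inlet (default) or unbound
    systemic plasma.
    """

    kdeg_per_h: Mapping[str, float]
    kdeg_gut_cyp3a4_per_h: float = 0.03
    q_hepatic_L_h: float = Q_HEPATIC_L_H
    q_gut_L_h: float = Q_GUT_L_H
    driver: str = "inlet"
    rtol: float = 1e-8
    atol: float = 1e-10
    output_step_h: float = 0.05

    def __post_init__(self) -> None:
        for enz, k in self.kdeg_per_h.items():
            if k <= 0:
                raise ValidationError(f"kdeg[{enz}] must be > 0")
        if self.kdeg_gut_cyp3a4_per_h <= 0:
            raise ValidationError("gut kdeg must be > 0")
        if self.q_hepatic_L_h <= 0 or self.q_gut_L_h <= 0:
            raise ValidationError("blood flows must be > 0")
        if self.driver not in ("inlet", "systemic"):
            raise ValidationError("driver must be 'inlet' or 'systemic'")

    @classmethod
    def default(cls) -> "EnzymeSettings":
        from .library import default_enzyme_settings

        return default_enzyme_settings()


@dataclass(frozen=True)
class CompoundModel:
    """A perpetrator (PK + induction map) and/or victim (PK + fm map).

    ``induction`` holds the aggregated (across-donor) parameters used by the
    dynamic engine; ``induction_by_donor`` retains the per-donor table for
    per-donor runs and the static model. ``None`` marks a no-call.
    """

    name: str
    role: str  # "perpetrator" | "victim" | "both"
    pk: CompoundPK
    induction: Mapping[str, EnzymeInduction | None] = field(default_factory=dict)
    induction_by_donor: Mapping[str, Mapping[str, EnzymeInduction | None]] = field(
        default_factory=dict
    )
    fm: FmMap | None = None
    experimental: bool = False
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("perpetrator", "victim", "both"):
            raise ValidationError("role must be perpetrator, victim or both")
        if self.role in ("victim", "both") and self.fm is None:
            raise ValidationError(f"{self.name}: victim role requires an fm map")

    # -- round-trip serialization ---------------------------------------------

    def to_dict(self) -> dict:
        def ind_block(block):
            return {
                enz: (None if p is None else {"ec50_uM": p.ec50_uM, "emax_fold": p.emax_fold})
                for enz, p in block.items()
            }

        return {
            "name": self.name,
            "role": self.role,
            "pk": self.pk.model_dump(),
            "induction": ind_block(self.induction),
            "induction_by_donor": {
                d: ind_block(b) for d, b in self.induction_by_donor.items()
            },
            "fm": None if self.fm is None else dict(self.fm.entries),
            "experimental": self.experimental,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompoundModel":
        def parse_block(block):
            return {
                enz: (None if p is None else EnzymeInduction(**p))
                for enz, p in block.items()
            }

        return cls(
            name=d["name"],
            role=d["role"],
            pk=CompoundPK(**d["pk"]),
            induction=parse_block(d.get("induction", {})),
            induction_by_donor={
                don: parse_block(b) for don, b in d.get("induction_by_donor", {}).items()
            },
            fm=None if d.get("fm") is None else FmMap(victim=d["name"], entries=d["fm"]),
            experimental=d.get("experimental", False),
            provenance=d.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# perpetrator exposure (closed-form superposition)
# ---------------------------------------------------------------------------


class PerpetratorExposure:
    """Closed-form perpetrator concentration profiles.

    All methods accept scalar or array time (h, on the study clock) and
    return micromolar concentrations (amounts in umol internally).
    """

    def __init__(
        self,
        pk: CompoundPK,
        regimen: DosingRegimen,
        settings: EnzymeSettings | None = None,
    ):
        self.pk = pk
        self.regimen = regimen
        self.settings = settings or EnzymeSettings.default()
        self.ke = pk.cl_L_h / pk.v_L
        self.dose_umol = pk.dose_umol(regimen.dose_mg)

    # closed-form pieces -------------------------------------------------------

    def _oral_terms(self, t: np.ndarray):
        """Central concentration and gut amount by superposition."""
        pk, ke = self.pk, self.ke
        conc = np.zeros_like(t, dtype=float)
        gut = np.zeros_like(t, dtype=float)
        fa_d = pk.fa * self.dose_umol
        for t0 in self.regimen.dose_times:
            tau = t - t0
            on = tau >= 0
            tau = np.where(on, tau, 0.0)
            eka = np.exp(-pk.ka_per_h * tau)
            gut += np.where(on, fa_d * eka, 0.0)
            if abs(pk.ka_per_h - ke) < 1e-9 * pk.ka_per_h:
                c = fa_d * pk.ka_per_h * tau * eka / pk.v_L
            else:
                c = (
                    fa_d
                    * pk.ka_per_h
                    / (pk.v_L * (pk.ka_per_h - ke))
                    * (np.exp(-ke * tau) - eka)
                )
            conc += np.where(on, c, 0.0)
        return conc, gut

    def _infusion_terms(self, t: np.ndarray):
        pk, ke = self.pk, self.ke
        dur = float(self.regimen.duration_h or 0.0)
        rate = self.dose_umol / dur if dur > 0 else 0.0
        conc = np.zeros_like(t, dtype=float)
        for t0 in self.regimen.dose_times:
            tau = np.clip(t - t0, 0.0, None)
            t_on = np.minimum(tau, dur)
            # during: R/CL (1 - e^{-ke t}); after: decay from end-of-infusion
            c = rate / pk.cl_L_h * (1.0 - np.exp(-ke * t_on)) * np.exp(
                -ke * np.clip(tau - dur, 0.0, None)
            )
            conc += np.where(tau > 0, c, 0.0)
        return conc, np.zeros_like(t, dtype=float)

    def conc_total(self, t) -> np.ndarray:
        """Total plasma concentration (uM)."""
        arr = np.asarray(t, dtype=float)
        conc, _ = (
            self._oral_terms(arr)
            if self.regimen.route == "oral"
            else self._infusion_terms(arr)
        )
        return conc

    def gut_amount(self, t) -> np.ndarray:
        arr = np.asarray(t, dtype=float)
        _, gut = (
            self._oral_terms(arr)
            if self.regimen.route == "oral"
            else self._infusion_terms(arr)
        )
        return gut

    def conc_unbound(self, t) -> np.ndarray:
        return self.pk.fu_plasma * self.conc_total(t)

    def conc_inlet_unbound(self, t) -> np.ndarray:
        """Unbound hepatic-inlet concentration: systemic plus the
        absorption-rate term ka*A_gut/Q_h."""
        arr = np.asarray(t, dtype=float)
        conc, gut = (
            self._oral_terms(arr)
            if self.regimen.route == "oral"
            else self._infusion_terms(arr)
        )
        q_h = self.settings.q_hepatic_L_h
        return self.pk.fu_plasma * (conc + self.pk.ka_per_h * gut / q_h)

    def hepatic_driver(self, t) -> np.ndarray:
        """Concentration driving hepatic enzyme turnover (uM, unbound,
        scaled by the hepatocellular partition Kp,uu)."""
        base = (
            self.conc_inlet_unbound(t)
            if self.settings.driver == "inlet"
            else self.conc_unbound(t)
        )
        return self.pk.liver_kpuu * base

    def enterocyte_driver(self, t) -> np.ndarray:
        """Gut-wall surrogate concentration ka*A_gut/Q_gut (uM)."""
        return self.pk.ka_per_h * self.gut_amount(t) / self.settings.q_gut_L_h

    def cumulative_absorbed_umol(self, t_end: float) -> float:
        """Drug absorbed from the gut depot through ``t_end`` (umol)."""
        if self.regimen.route != "oral":
            raise InvalidInputError("absorption balance applies to oral dosing")
        fa_d = self.pk.fa * self.dose_umol
        total = 0.0
        for t0 in self.regimen.dose_times:
            if t_end >= t0:
                total += fa_d * (1.0 - math.exp(-self.pk.ka_per_h * (t_end - t0)))
        return total

    def to_frame(self, t_end: float | None = None, step: float | None = None) -> pd.DataFrame:
        step = step or self.settings.output_step_h
        t_end = t_end if t_end is not None else self.regimen.end_h + 48.0
        t = np.arange(0.0, t_end + step / 2, step)
        return pd.DataFrame(
            {
                "time_h": t,
                "conc_total_uM": self.conc_total(t),
                "conc_unbound_uM": self.conc_unbound(t),
                "conc_inlet_unbound_uM": self.conc_inlet_unbound(t),
            }
        )


def simulate_perpetrator(
    pk: CompoundPK,
    regimen: DosingRegimen,
    settings: EnzymeSettings | None = None,
    t_end: float | None = None,
    grid_step: float | None = None,
) -> tuple[pd.DataFrame, PerpetratorExposure]:
    """Simulate perpetrator plasma (total and unbound) and hepatic-inlet
    unbound concentration series. Returns the sampled frame plus the
    closed-form exposure object for downstream use."""
    exposure = PerpetratorExposure(pk, regimen, settings)
    return exposure.to_frame(t_end=t_end, step=grid_step), exposure


# ---------------------------------------------------------------------------
# enzyme turnover
# ---------------------------------------------------------------------------


def enzyme_dynamics(
    driver: Callable[[float], float],
    emax_fold: float,
    ec50_uM: float,
    kdeg_per_h: float,
    t_span: tuple[float, float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_step_h: float = 1.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Integrate the turnover model for a single enzyme and return a dense
    interpolant E(t) with E(t0) = 1.

    With a constant driver C the solution approaches
    E_ss = 1 + (Emax - 1) * C / (EC50 + C) with first-order rate kdeg.
    """
    if kdeg_per_h <= 0:
        raise ValidationError("kdeg must be > 0")
    if ec50_uM <= 0 or emax_fold < 1:
        raise ValidationError("induction parameters invalid (EC50 > 0, Emax >= 1)")
    if emax_fold == 1.0:
        return lambda t: np.ones_like(np.asarray(t, dtype=float))

    def rhs(t, y):
        c = float(np.asarray(driver(t)).reshape(-1)[0])
        stim = 1.0 + (emax_fold - 1.0) * c / (ec50_uM + c)
        return [kdeg_per_h * (stim - y[0])]

    sol = solve_ivp(
        rhs,
        t_span,
        [1.0],
        method="LSODA",
        dense_output=True,
        rtol=rtol,
        atol=atol,
        max_step=max_step_h,
    )
    if not sol.success:  # pragma: no cover - LSODA failure is exceptional
        raise RuntimeError(f"enzyme turnover integration failed: {sol.message}")

    t0, t1 = t_span

    def interp(t):
        tt = np.clip(np.asarray(t, dtype=float), t0, t1)
        return np.clip(sol.sol(tt)[0], 1.0, emax_fold)

    return interp


def _solve_liver_enzymes(
    exposure: PerpetratorExposure,
    induction: Mapping[str, EnzymeInduction | None],
    enzymes: Sequence[str],
    settings: EnzymeSettings,
    t_end: float,
) -> dict[str, Callable]:
    """One interpolant per requested enzyme; uninduced or NC enzymes map to
    the constant-1 profile."""
    ones = lambda t: np.ones_like(np.asarray(t, dtype=float))  # noqa: E731
    out: dict[str, Callable] = {}
    driver = lambda t: exposure.hepatic_driver(t)  # noqa: E731
    for enz in enzymes:
        params = induction.get(enz)
        if params is None or params.emax_fold <= 1.0:
            out[enz] = ones
            continue
        kdeg = settings.kdeg_per_h.get(enz)
        if kdeg is None:
            raise ValidationError(f"no kdeg configured for {enz}")
        out[enz] = enzyme_dynamics(
            driver,
            params.emax_fold,
            params.ec50_uM,
            kdeg,
            (0.0, t_end),
            rtol=settings.rtol,
            atol=settings.atol,
        )
    return out


# ---------------------------------------------------------------------------
# victim disposition
# ---------------------------------------------------------------------------


def victim_clearance(
    fm_map: FmMap,
    enzyme_abundance: Mapping[str, float],
    cl_int0_L_h: float,
    fu: float,
    q_h_L_h: float = Q_HEPATIC_L_H,
) -> tuple[float, float, float]:
    """Instantaneous hepatic clearance under the current enzyme state.

    Returns ``(cl_int, cl_h, f_h)`` where
    CL_int = CL_int,0 * (sum fm_i E_i + residual), CL_h is the well-stirred
    hepatic clearance (< Q_h always) and F_h the hepatic availability.
    """
    if sum(fm_map.entries.values()) > 1.0 + 1e-9:
        raise ValidationError("fm values sum to more than 1")
    if q_h_L_h <= 0 or cl_int0_L_h <= 0 or not 0 < fu <= 1:
        raise ValidationError("cl_int0, fu, Q_h must be positive (fu <= 1)")
    scale = fm_map.residual
    for enz, fm in fm_map.entries.items():
        scale += fm * float(enzyme_abundance.get(enz, 1.0))
    cl_int = cl_int0_L_h * scale
    cl_h = q_h_L_h * fu * cl_int / (q_h_L_h + fu * cl_int)
    f_h = q_h_L_h / (q_h_L_h + fu * cl_int)
    return cl_int, cl_h, f_h


def _cl_int0_from_systemic(pk: CompoundPK, q_h: float) -> float:
    """Back-calculate baseline CL_int from the fixture's systemic clearance
    (hepatic part = cl_L_h - cl_renal_L_h) via the well-stirred model."""
    cl_h = pk.cl_L_h - pk.cl_renal_L_h
    if cl_h <= 0:
        raise ValidationError("hepatic clearance must be > 0")
    if cl_h >= q_h:
        raise ValidationError("hepatic clearance must be below hepatic blood flow")
    return cl_h / (pk.fu_plasma * (1.0 - cl_h / q_h))


@dataclass(frozen=True)
class DDIOutcome:
    """Victim exposure with and without the perpetrator."""

    auc_alone_uM_h: float
    auc_with_uM_h: float
    aucr: float
    series: pd.DataFrame  # columns: arm, time_h, conc_uM
    extrap_frac_alone: float
    extrap_frac_with: float
    auc_is_extrapolated: bool = True

    @property
    def percent_reduction(self) -> float:
        return 100.0 * (1.0 - self.aucr)


def _terminal_kel(t: np.ndarray, c: np.ndarray) -> float | None:
    """Log-linear terminal slope from the final decade of the profile; None
    if the tail is not a clean monotone decline."""
    mask = c > 0
    if np.count_nonzero(mask) < 5:
        return None
    t, c = t[mask], c[mask]
    n_tail = max(5, int(0.1 * len(t)))
    tt, cc = t[-n_tail:], c[-n_tail:]
    slope = np.polyfit(tt, np.log(cc), 1)[0]
    if slope >= -1e-10:
        return None
    return -float(slope)


def _simulate_victim_arm(
    victim: CompoundModel,
    regimen: DosingRegimen,
    liver_e: Mapping[str, Callable] | None,
    gut_e: Callable | None,
    settings: EnzymeSettings,
    t_end: float,
    clint_factor: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Integrate one victim arm. Returns (t grid, conc, auc_inf, extrapolated
    fraction). ``liver_e=None`` / ``gut_e=None`` denote baseline enzymes."""
    pk = victim.pk
    fm = victim.fm
    assert fm is not None
    q_h = settings.q_hepatic_L_h
    cl_int0 = _cl_int0_from_systemic(pk, q_h) * clint_factor
    fg0 = pk.fg0
    enz_names = list(fm.entries)
    fm_vals = np.array([fm.entries[e] for e in enz_names])
    residual = fm.residual

    def coeffs(t: float) -> tuple[float, float, float]:
        if liver_e is None:
            scale = 1.0
        else:
            evals = np.array([float(liver_e[e](t)) for e in enz_names])
            scale = float(np.dot(fm_vals, evals)) + residual
        cl_int = cl_int0 * scale
        fu_clint = pk.fu_plasma * cl_int
        cl_h = q_h * fu_clint / (q_h + fu_clint)
        f_h = q_h / (q_h + fu_clint)
        if fg0 >= 1.0 or gut_e is None:
            f_g = fg0
        else:
            eg = float(gut_e(t))
            f_g = fg0 / (fg0 + (1.0 - fg0) * eg)
        return cl_h, f_h, f_g

    ke_renal = pk.cl_renal_L_h / pk.v_L

    def rhs(t, y):
        a_gut, a_c = y
        cl_h, f_h, f_g = coeffs(t)
        absorbed = pk.ka_per_h * a_gut
        return [
            -absorbed,
            absorbed * f_g * f_h - (cl_h / pk.v_L + ke_renal) * a_c,
        ]

    t0 = float(regimen.dose_times[0])
    step = settings.output_step_h
    grid = np.arange(t0, t_end + step / 2, step)
    dose_events = {float(td) for td in regimen.dose_times if td < t_end}
    seg_bounds = sorted(dose_events | {t_end})
    if seg_bounds[0] != t0:  # pragma: no cover - defensive
        seg_bounds = [t0] + seg_bounds
    y = np.array([0.0, 0.0])
    ts_all: list[np.ndarray] = []
    cs_all: list[np.ndarray] = []
    for t_cur, t_next in zip(seg_bounds[:-1], seg_bounds[1:]):
        if t_cur in dose_events:
            y = y + np.array([pk.fa * pk.dose_umol(regimen.dose_mg), 0.0])
        inner = grid[(grid > t_cur) & (grid < t_next)]
        t_eval = np.concatenate(([t_cur], inner, [t_next]))
        sol = solve_ivp(
            rhs,
            (t_cur, t_next),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=2.0,
        )
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"victim integration failed: {sol.message}")
        ts_all.append(sol.t)
        cs_all.append(sol.y[1] / pk.v_L)
        y = sol.y[:, -1]
    t_arr = np.concatenate(ts_all)
    c_arr = np.concatenate(cs_all)
    t_arr, idx = np.unique(t_arr, return_index=True)
    c_arr = np.clip(c_arr[idx], 0.0, None)

    auc_last = float(np.trapezoid(c_arr, t_arr))
    kel = _terminal_kel(t_arr, c_arr)
    if kel is None:
        warnings.warn(
            "terminal slope not estimable; reporting AUC to last time point",
            stacklevel=2,
        )
        return t_arr, c_arr, auc_last, float("nan")
    tail = float(c_arr[-1]) / kel
    auc_inf = auc_last + tail
    frac = tail / auc_inf if auc_inf > 0 else 0.0
    if frac >= 0.2:
        warnings.warn(
            f"extrapolated AUC fraction {frac:.1%} exceeds 20%", stacklevel=2
        )
    return t_arr, c_arr, auc_inf, frac


def run_ddi(
    perpetrator: CompoundModel,
    victim: CompoundModel,
    design: DDIDesign,
    settings: EnzymeSettings | None = None,
    window_h: float | None = None,
    induction_override: Mapping[str, EnzymeInduction | None] | None = None,
    clint_factor: float = 1.0,
) -> DDIOutcome:
    """Simulate the victim arm with and without the perpetrator regimen and
    return the AUC ratio.

    ``window_h`` is the victim observation window after its (first) dose;
    by default 10 baseline half-lives, at least 72 h. ``induction_override``
    substitutes the perpetrator induction block (used for per-donor runs and
    sensitivity scans); ``clint_factor`` scales the victim baseline CL_int.
    """
    settings = settings or EnzymeSettings.default()
    if victim.fm is None:
        raise ValidationError(f"{victim.name} has no fm map")
    induction = (
        induction_override if induction_override is not None else perpetrator.induction
    )

    # victim observation window from baseline kinetics
    pk = victim.pk
    kel0 = pk.cl_L_h / pk.v_L
    if window_h is None:
        window_h = max(72.0, 10.0 * math.log(2.0) / kel0)
    t_end = float(design.victim.dose_times[-1]) + window_h

    induced_enzymes = [
        e
        for e in victim.fm.entries
        if induction.get(e) is not None and induction[e].emax_fold > 1.0
    ]
    gut_active = (
        pk.fg0 < 1.0
        and "CYP3A4" in victim.fm.entries
        and induction.get("CYP3A4") is not None
        and induction["CYP3A4"].emax_fold > 1.0
    )
    has_effect = (
        design.perpetrator.dose_mg > 0 and (induced_enzymes or gut_active)
    )

    t_b, c_b, auc_alone, frac_b = _simulate_victim_arm(
        victim, design.victim, None, None, settings, t_end, clint_factor
    )

    if not has_effect:
        # identical arms by construction: AUCR is exactly 1
        series = pd.concat(
            [
                pd.DataFrame({"arm": "alone", "time_h": t_b, "conc_uM": c_b}),
                pd.DataFrame({"arm": "with_perpetrator", "time_h": t_b, "conc_uM": c_b}),
            ],
            ignore_index=True,
        )
        return DDIOutcome(
            auc_alone_uM_h=auc_alone,
            auc_with_uM_h=auc_alone,
            aucr=1.0,
            series=series,
            extrap_frac_alone=frac_b,
            extrap_frac_with=frac_b,
            auc_is_extrapolated=not math.isnan(frac_b),
        )

    exposure = PerpetratorExposure(perpetrator.pk, design.perpetrator, settings)
    liver_e = _solve_liver_enzymes(
        exposure, induction, list(victim.fm.entries), settings, t_end
    )
    gut_e = None
    if gut_active:
        gut_e = enzyme_dynamics(
            lambda t: exposure.enterocyte_driver(t),
            induction["CYP3A4"].emax_fold,
            induction["CYP3A4"].ec50_uM,
            settings.kdeg_gut_cyp3a4_per_h,
            (0.0, t_end),
            rtol=settings.rtol,
            atol=settings.atol,
        )

    t_w, c_w, auc_with, frac_w = _simulate_victim_arm(
        victim, design.victim, liver_e, gut_e, settings, t_end, clint_factor
    )

    series = pd.concat(
        [
            pd.DataFrame({"arm": "alone", "time_h": t_b, "conc_uM": c_b}),
            pd.DataFrame({"arm": "with_perpetrator", "time_h": t_w, "conc_uM": c_w}),
        ],
        ignore_index=True,
    )
    return DDIOutcome(
        auc_alone_uM_h=auc_alone,
        auc_with_uM_h=auc_with,
        aucr=auc_with / auc_alone,
        series=series,
        extrap_frac_alone=frac_b,
        extrap_frac_with=frac_w,
        auc_is_extrapolated=not (math.isnan(frac_b) or math.isnan(frac_w)),
    )


def sensitivity_scan(
    perpetrator: CompoundModel,
    victim: CompoundModel,
    design: DDIDesign,
    parameter: str | Sequence[str],
    factors: Sequence[float] | Sequence[Sequence[float]],
    settings: EnzymeSettings | None = None,
    window_h: float | None = None,
) -> pd.DataFrame:
    """AUCR as a function of multiplicative perturbations of ``Emax``,
    ``EC50`` (perpetrator induction, all enzymes) or ``CL_int`` (victim).

    ``parameter`` may be a single name or a sequence for joint perturbations,
    with ``factors`` entries matching its shape. An Emax factor scales the
    induction amplitude (Emax - 1), so factor 1 reproduces the base case
    bit-identically and Emax = 1 stays uninduced.
    """
    params = [parameter] if isinstance(parameter, str) else list(parameter)
    for p in params:
        if p not in ("Emax", "EC50", "CL_int"):
            raise InvalidInputError(f"unknown scan parameter {p!r}")
    rows = []
    for factor in factors:
        fvec = [factor] if isinstance(factor, (int, float)) else list(factor)
        if len(fvec) != len(params):
            raise InvalidInputError("factor shape must match parameter shape")
        pmap = dict(zip(params, fvec))
        emax_f = pmap.get("Emax", 1.0)
        ec50_f = pmap.get("EC50", 1.0)
        clint_f = pmap.get("CL_int", 1.0)
        if emax_f == 1.0 and ec50_f == 1.0:
            override = None
        else:
            override = {
                enz: (
                    None
                    if p is None
                    else EnzymeInduction(
                        ec50_uM=p.ec50_uM * ec50_f,
                        emax_fold=1.0 + (p.emax_fold - 1.0) * emax_f,
                    )
                )
                for enz, p in perpetrator.induction.items()
            }
        outcome = run_ddi(
            perpetrator,
            victim,
            design,
            settings=settings,
            window_h=window_h,
            induction_override=override,
            clint_factor=clint_f,
        )
        rows.append(
            {
                **{f"factor_{p}": f for p, f in zip(params, fvec)},
                "aucr": outcome.aucr,
                "pct_auc_reduction": outcome.percent_reduction,
            }
        )
    return pd.DataFrame(rows)
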
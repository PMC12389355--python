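"""In vitro CYP induction: concentration-response data, stability metrics,
and Emax/EC50 estimation.

The data model mirrors a hepatocyte-triculture induction experiment: a test
compound is applied at several nominal concentrations (quadruplicate wells),
and the readout is the fold change of CYP mRNA or marker activity relative to
the vehicle control. Fold changes are therefore dimensionless with baseline 1.

Two sigmoid parameterisations are supported:

``logistic_logC`` (default)
    Y = 1 + (Emax - 1) / (1 + exp(-(x - log10 EC50) / slope)),  x = log10 C.
    A GraphPad-style three-parameter sigmoid on log concentration, anchored at
    the vehicle baseline of 1. EC50 is reported on the linear micromolar scale.

``hill``
    Y = 1 + (Emax - 1) * C**h / (EC50**h + C**h).

Datasets whose maximum mean fold change is below 2 are flagged as no-call
(NC) and no parameters are estimated; this mirrors standard regulatory
practice where sub-2-fold responses are not quantifiable induction signals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitRefusedError, InvalidInputError

__all__ = [
    "ENZYMES",
    "READOUTS",
    "InductionDataset",
    "InductionFit",
    "StabilityResult",
    "DonorSummary",
    "trapezoid_auc",
    "stability_metrics",
    "apply_nc_rule",
    "fit_induction_curve",
    "summarize_donors",
]

ENZYMES = ("CYP3A4", "CYP2C8", "CYP2C9", "CYP2C19", "CYP2B6")
READOUTS = ("mRNA", "activity")

#: fold-change threshold below which an enzyme/donor response is a no-call
NC_THRESHOLD = 2.0


@dataclass(frozen=True)
class InductionDataset:
    """One compound x enzyme x donor x readout concentration-response table.

    ``responses[i]`` holds the replicate fold-change values observed at
    ``concentrations[i]`` (nominal, micromolar). Fold changes are positive by
    construction (they are ratios to the vehicle control).
    """

    compound: str
    enzyme: str
    donor: str
    readout: str
    concentrations: tuple[float, ...]
    responses: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        if self.enzyme not in ENZYMES:
            raise InvalidInputError(
                f"unknown enzyme {self.enzyme!r}; expected one of {ENZYMES}"
            )
        if self.readout not in READOUTS:
            raise InvalidInputError(
                f"unknown readout {self.readout!r}; expected one of {READOUTS}"
            )
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.ndim != 1 or conc.size == 0:
            raise InvalidInputError("at least one concentration required")
        if np.any(conc < 0):
            raise InvalidInputError("concentrations must be >= 0")
        if np.any(np.diff(conc) <= 0):
            raise InvalidInputError("concentrations must be strictly increasing")
        if len(self.responses) != conc.size:
            raise InvalidInputError("one replicate tuple required per concentration")
        for reps in self.responses:
            arr = np.asarray(reps, dtype=float)
            if arr.size == 0 or np.any(arr <= 0) or not np.all(np.isfinite(arr)):
                raise InvalidInputError("fold-change values must be finite and > 0")

    # -- convenience accessors -------------------------------------------------

    @property
    def mean_response(self) -> np.ndarray:
        return np.array([float(np.mean(r)) for r in self.responses])

    @property
    def sd_response(self) -> np.ndarray:
        return np.array(
            [float(np.std(r, ddof=1)) if len(r) > 1 else 0.0 for r in self.responses]
        )

    @property
    def n_replicates(self) -> np.ndarray:
        return np.array([len(r) for r in self.responses])

    def to_long_frame(self) -> pd.DataFrame:
        """Long format used for CSV interchange:
        compound, enzyme, donor, readout, conc_uM, fold_change, replicate."""
        rows = []
        for c, reps in zip(self.concentrations, self.responses):
            for j, y in enumerate(reps, start=1):
                rows.append(
                    dict(
                        compound=self.compound,
                        enzyme=self.enzyme,
                        donor=self.donor,
                        readout=self.readout,
                        conc_uM=c,
                        fold_change=y,
                        replicate=j,
                    )
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "InductionDataset":
        """Build a dataset from the long CSV format. The frame must describe a
        single compound/enzyme/donor/readout combination."""
        keys = ["compound", "enzyme", "donor", "readout"]
        uniq = frame[keys].drop_duplicates()
        if len(uniq) != 1:
            raise InvalidInputError(
                "frame must contain exactly one compound/enzyme/donor/readout group"
            )
        meta = uniq.iloc[0]
        conc: list[float] = []
        reps: list[tuple[float, ...]] = []
        for c, grp in frame.groupby("conc_uM", sort=True):
            conc.append(float(c))
            reps.append(tuple(float(v) for v in grp["fold_change"]))
        return cls(
            compound=str(meta["compound"]),
            enzyme=str(meta["enzyme"]),
            donor=str(meta["donor"]),
            readout=str(meta["readout"]),
            concentrations=tuple(conc),
            responses=tuple(reps),
        )


@dataclass(frozen=True)
class InductionFit:
    """Fitted induction parameters for one dataset.

    ``emax_fold`` is the *total* maximum fold induction (baseline 1, so an
    inactive compound has Emax = 1); ``ec50_uM`` is on the linear micromolar
    scale regardless of the fitted form. ``nc`` marks the sub-2-fold no-call;
    NC fits carry no parameters.
    """

    nc: bool
    converged: bool
    ec50_uM: float | None = None
    emax_fold: float | None = None
    hill_slope: float | None = None
    rss: float | None = None
    form: str | None = None
    compound: str | None = None
    enzyme: str | None = None
    donor: str | None = None
    readout: str | None = None

    def __post_init__(self) -> None:
        if not self.nc and self.converged:
            if self.ec50_uM is None or self.ec50_uM <= 0:
                raise InvalidInputError("converged fit requires EC50 > 0")
            if self.emax_fold is None or self.emax_fold < 1:
                raise InvalidInputError("converged fit requires Emax >= 1")


@dataclass(frozen=True)
class StabilityResult:
    """Dosing-interval stability of a test compound in culture medium."""

    auc_uM_h: float
    avg_concentration_uM: float
    extent_of_loss: float  # fraction of nominal, clipped at 0


def trapezoid_auc(series: Sequence[tuple[float, float]]) -> float:
    """Linear trapezoidal AUC of a (time h, concentration uM) series.

    Exact for piecewise-linear profiles; times must be strictly increasing
    and concentrations non-negative.
    """
    pts = np.asarray(series, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InvalidInputError("series must contain at least 2 (time, conc) points")
    t, c = pts[:, 0], pts[:, 1]
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("times must be strictly increasing")
    if np.any(c < 0):
        raise InvalidInputError("concentrations must be >= 0")
    return float(np.trapezoid(c, t))


def stability_metrics(
    series: Sequence[tuple[float, float]], nominal: float, window_h: float = 96.0
) -> StabilityResult:
    """Average exposure and extent of loss over the incubation window.

    ``avg = AUC / window`` and ``extent_of_loss = 1 - avg/nominal`` (clipped at
    zero, so measured accumulation above nominal reads as zero loss).
    """
    if nominal <= 0:
        raise InvalidInputError("nominal concentration must be > 0")
    if window_h <= 0:
        raise InvalidInputError("window must be > 0")
    auc = trapezoid_auc(series)
    avg = auc / window_h
    loss = max(0.0, 1.0 - avg / nominal)
    return StabilityResult(auc_uM_h=auc, avg_concentration_uM=avg, extent_of_loss=loss)


def apply_nc_rule(dataset: InductionDataset) -> bool:
    """True iff the maximum over concentrations of the mean fold change is
    strictly below 2 (the no-call threshold). A maximum of exactly 2.0 is a
    call."""
    return bool(np.max(dataset.mean_response) < NC_THRESHOLD)


def _dedupe(conc: np.ndarray, mean: np.ndarray, sd: np.ndarray, n: np.ndarray):
    """Average duplicate concentrations before fitting (pooled mean; SD kept
    as the max of the duplicates as a conservative weight)."""
    out_c, out_m, out_s, out_n = [], [], [], []
    for c in np.unique(conc):
        sel = conc == c
        w = n[sel].astype(float)
        out_c.append(c)
        out_m.append(float(np.average(mean[sel], weights=w)))
        out_s.append(float(np.max(sd[sel])))
        out_n.append(int(np.sum(n[sel])))
    return (np.array(out_c), np.array(out_m), np.array(out_s), np.array(out_n))


def _model_logistic_logc(x: np.ndarray, log_ec50: float, emax: float, slope: float):
    return 1.0 + (emax - 1.0) / (1.0 + np.exp(-(x - log_ec50) / slope))


def _model_hill(c: np.ndarray, log_ec50: float, emax: float, h: float):
    ec50 = 10.0**log_ec50
    ch = np.power(c, h)
    return 1.0 + (emax - 1.0) * ch / (np.power(ec50, h) + ch)


def fit_induction_curve(
    dataset: InductionDataset,
    form: str = "logistic_logC",
    weighting: str = "relative",
    fix_slope: float | None = None,
) -> InductionFit:
    """Weighted least-squares fit of mean fold change versus nominal
    concentration.

    The no-call rule is applied first; NC datasets return immediately with
    ``nc=True`` and no parameters. ``weighting`` selects the error model:
    ``relative`` (default) weights means by 1/response, matching the
    multiplicative error structure of fold-change data; ``sd`` weights by the
    replicate SD (requires n >= 2 with positive SD everywhere, else falls
    back to unweighted); ``none`` is unweighted. ``fix_slope`` pins the
    slope/Hill coefficient (e.g. 1.0 for a hyperbolic recovery experiment)
    instead of estimating it. The fitted EC50 must fall within
    [min tested conc / 10, max tested conc x 10]; estimates escaping that
    window are reported with ``converged=False``.
    """
    if form not in ("logistic_logC", "hill"):
        raise InvalidInputError(f"unknown form {form!r}")
    if weighting not in ("relative", "sd", "none"):
        raise InvalidInputError(f"unknown weighting {weighting!r}")
    meta = dict(
        compound=dataset.compound,
        enzyme=dataset.enzyme,
        donor=dataset.donor,
        readout=dataset.readout,
    )
    if apply_nc_rule(dataset):
        return InductionFit(nc=True, converged=False, form=form, **meta)

    conc = np.asarray(dataset.concentrations, dtype=float)
    mean = dataset.mean_response
    sd = dataset.sd_response
    n = dataset.n_replicates
    conc, mean, sd, n = _dedupe(conc, mean, sd, n)

    nz = conc > 0
    if np.count_nonzero(nz) < 4:
        raise FitRefusedError("at least 4 distinct non-zero concentrations required")

    c_fit, y_fit, sd_fit, n_fit = conc[nz], mean[nz], sd[nz], n[nz]
    if weighting == "relative":
        sigma = y_fit
    elif weighting == "sd" and np.all(n_fit >= 2) and np.all(sd_fit > 0):
        sigma = sd_fit
    else:
        sigma = None

    max_fold = float(np.max(mean))
    emax0 = max_fold
    # initial EC50: tested concentration whose response is nearest half-maximal
    half = 1.0 + (max_fold - 1.0) / 2.0
    ec50_0 = float(c_fit[np.argmin(np.abs(y_fit - half))])
    p0 = [math.log10(ec50_0), emax0, 1.0]
    # Emax upper bound: 2x the max observed mean fold (fit sanity constraint)
    bounds = (
        [math.log10(c_fit.min()) - 3.0, 1.0, 0.3],
        [math.log10(c_fit.max()) + 3.0, 2.0 * max_fold, 5.0],
    )
    base_model = _model_logistic_logc if form == "logistic_logC" else _model_hill
    x = np.log10(c_fit) if form == "logistic_logC" else c_fit
    if fix_slope is None:
        model = base_model
    else:
        if fix_slope <= 0:
            raise InvalidInputError("fix_slope must be > 0")
        model = lambda xx, lec, emax: base_model(xx, lec, emax, fix_slope)  # noqa: E731
        p0 = p0[:2]
        bounds = (bounds[0][:2], bounds[1][:2])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                model, x, y_fit, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
            )
    except (RuntimeError, ValueError):
        return InductionFit(nc=False, converged=False, form=form, **meta)

    if fix_slope is None:
        log_ec50, emax, slope = popt
    else:
        (log_ec50, emax), slope = popt, fix_slope
    ec50 = 10.0**log_ec50
    converged = bool(c_fit.min() / 10.0 <= ec50 <= c_fit.max() * 10.0)
    if not converged:
        return InductionFit(nc=False, converged=False, form=form, **meta)
    rss = float(np.sum((y_fit - model(x, *popt)) ** 2))
    return InductionFit(
        nc=False,
        converged=True,
        ec50_uM=float(ec50),
        emax_fold=float(emax),
        hill_slope=float(slope),
        rss=rss,
        form=form,
        **meta,
    )


@dataclass(frozen=True)
class DonorSummary:
    """Across-donor summary for one enzyme. NC fits are excluded from the
    numeric statistics but counted in ``n_nc``."""

    enzyme: str
    n_fits: int
    n_nc: int
    ec50_mean: float | None = None
    ec50_min: float | None = None
    ec50_max: float | None = None
    emax_mean: float | None = None
    emax_min: float | None = None
    emax_max: float | None = None

    @property
    def all_nc(self) -> bool:
        return self.n_nc == self.n_fits


def summarize_donors(fits: Iterable[InductionFit]) -> dict[str, DonorSummary]:
    """Per-enzyme mean/min/max of EC50 and Emax across donors.

    Non-converged non-NC fits are dropped with a warning; all-NC enzymes are
    flagged via ``DonorSummary.all_nc`` with no numeric range.
    """
    fits = list(fits)
    if not fits:
        raise InvalidInputError("at least one fit required")
    out: dict[str, DonorSummary] = {}
    for enzyme in sorted({f.enzyme or "?" for f in fits}):
        group = [f for f in fits if (f.enzyme or "?") == enzyme]
        nc = [f for f in group if f.nc]
        usable = [f for f in group if not f.nc and f.converged]
        dropped = len(group) - len(nc) - len(usable)
        if dropped:
            warnings.warn(
                f"{enzyme}: dropped {dropped} non-converged fit(s) from summary",
                stacklevel=2,
            )
        if not usable:
            out[enzyme] = DonorSummary(enzyme=enzyme, n_fits=len(group), n_nc=len(nc))
            continue
        ec = np.array([f.ec50_uM for f in usable])
        em = np.array([f.emax_fold for f in usable])
        out[enzyme] = DonorSummary(
            enzyme=enzyme,
            n_fits=len(group),
            n_nc=len(nc),
            ec50_mean=float(ec.mean()),
            ec50_min=float(ec.min()),
            ec50_max=float(ec.max()),
            emax_mean=float(em.mean()),
            emax_min=float(em.min()),
            emax_max=float(em.max()),
        )
    return out
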
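"""Synthetic data generators emulating the study's data-generating processes.

Two generators cover the two experimental layers:

* quadruplicate sigmoidal fold-change responses with multiplicative
  log-normal replicate noise (the hepatocyte induction assay), and
* noisy sampled concentration-time observations of a compartmental PK
  profile (clinical-style PK data for AUC and overlay checks).

Both are pure functions of (spec, seed): the same seed always reproduces the
same dataset, and the noise is mean-one so the expected response equals the
truth curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .induction import InductionDataset
from .pbpk import CompoundPK, DosingRegimen, PerpetratorExposure

__all__ = ["ResponseSimSpec", "gen_concentration_response", "gen_pk_observations"]


@dataclass(frozen=True)
class ResponseSimSpec:
    """Truth and design for a simulated concentration-response experiment.

    ``cv`` is the multiplicative (log-normal) replicate coefficient of
    variation; ``additive_sd`` adds optional Gaussian noise on the fold-change
    scale (default none). The truth curve is the Hill form with total-fold
    Emax and baseline 1.
    """

    ec50_uM: float
    emax_fold: float
    hill: float = 1.0
    concentrations_uM: Sequence[float] = field(
        default_factory=lambda: tuple(np.logspace(-2, 1, 8))
    )
    n_replicates: int = 4
    cv: float = 0.1
    additive_sd: float = 0.0
    compound: str = "synthetic"
    enzyme: str = "CYP3A4"
    donor: str = "donor1"
    readout: str = "mRNA"

    def __post_init__(self) -> None:
        if self.ec50_uM <= 0 or self.emax_fold < 1 or self.hill <= 0:
            raise InvalidInputError("truth requires EC50 > 0, Emax >= 1, hill > 0")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")
        if self.cv < 0 or self.additive_sd < 0:
            raise InvalidInputError("noise parameters must be >= 0")

    def truth(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        ch = np.power(c, self.hill)
        return 1.0 + (self.emax_fold - 1.0) * ch / (
            self.ec50_uM**self.hill + ch
        )


def gen_concentration_response(spec: ResponseSimSpec, seed: int) -> InductionDataset:
    """Simulate one quadruplicate-style induction dataset.

    Multiplicative noise is mean-one log-normal (sigma^2 = ln(1 + cv^2)), so
    E[response] equals the truth curve at every concentration; cv = 0
    reproduces the truth exactly.
    """
    rng = np.random.default_rng(seed)
    conc = np.asarray(sorted(spec.concentrations_uM), dtype=float)
    responses = []
    sigma = np.sqrt(np.log1p(spec.cv**2))
    for c in conc:
        y = np.full(spec.n_replicates, spec.truth(c))
        if spec.cv > 0:
            y = y * rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=y.size)
        if spec.additive_sd > 0:
            y = y + rng.normal(0.0, spec.additive_sd, size=y.size)
        responses.append(tuple(np.clip(y, 1e-9, None)))
    return InductionDataset(
        compound=spec.compound,
        enzyme=spec.enzyme,
        donor=spec.donor,
        readout=spec.readout,
        concentrations=tuple(conc),
        responses=tuple(responses),
    )


def gen_pk_observations(
    pk: CompoundPK,
    regimen: DosingRegimen,
    sample_times_h: Sequence[float],
    residual_cv: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Sampled perpetrator-style concentration observations with mean-one
    log-normal residual error. ``residual_cv = 0`` returns the model curve at
    the sample times exactly. A seed is mandatory for any stochastic call."""
    if residual_cv < 0:
        raise InvalidInputError("residual_cv must be >= 0")
    if residual_cv > 0 and seed is None:
        raise InvalidInputError("seed is mandatory for a stochastic call")
    t = np.asarray(sample_times_h, dtype=float)
    conc = PerpetratorExposure(pk, regimen).conc_total(t)
    if residual_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(residual_cv**2))
        conc = conc * rng.lognormal(-(sigma**2) / 2, sigma, size=conc.size)
    return pd.DataFrame({"time_h": t, "conc_uM": conc})
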
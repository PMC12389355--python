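"""Typed registry of vendored study parameters and literature PK fixtures.

Everything ships with the package as plain-text data files:

* ``induction_mrna.csv`` / ``induction_activity.csv`` -- per-donor EC50/Emax
  induction parameters (no-call cells flagged);
* ``compounds.json`` -- base PK fixtures with citation metadata, victim fm
  maps, and perpetrator Imax,u values;
* ``regimens.json`` -- the clinical DDI trial designs (perpetrator schedule +
  victim dose timing);
* ``enzyme_settings.json`` -- enzyme turnover and physiology defaults;
* ``observed_outcomes_transcription.csv`` -- published outcome numbers for
  comparison tables (never used as computational input).

Nothing is fetched at runtime.
"""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ValidationError
from .pbpk import CompoundModel, CompoundPK, DDIDesign, DosingRegimen, EnzymeSettings
from .static import EnzymeInduction, FmMap

__all__ = [
    "list_compounds",
    "list_designs",
    "load_compound",
    "load_design",
    "load_induction_table",
    "donor_induction",
    "aggregate_induction",
    "imax_u",
    "validate_params",
    "registry_dump",
    "registry_checksum",
    "default_enzyme_settings",
    "observed_outcomes",
]

PERPETRATORS = ("rifampicin", "efavirenz", "carbamazepine", "apalutamide")


def _data_text(name: str) -> str:
    return resources.files("cypind.data").joinpath(name).read_text()


@lru_cache(maxsize=None)
def _compounds_raw() -> dict:
    raw = json.loads(_data_text("compounds.json"))
    raw.pop("_comment", None)
    return raw


@lru_cache(maxsize=None)
def _regimens_raw() -> dict:
    raw = json.loads(_data_text("regimens.json"))
    raw.pop("_comment", None)
    return raw


@lru_cache(maxsize=None)
def _induction_frame(readout: str) -> pd.DataFrame:
    if readout not in ("mRNA", "activity"):
        raise InvalidInputError("readout must be 'mRNA' or 'activity'")
    fname = "induction_mrna.csv" if readout == "mRNA" else "induction_activity.csv"
    import io

    frame = pd.read_csv(io.StringIO(_data_text(fname)))
    frame["nc"] = frame["nc"].astype(bool)
    return frame


def load_induction_table(readout: str = "mRNA") -> pd.DataFrame:
    """The vendored per-donor induction parameter table (copy)."""
    return _induction_frame(readout).copy()


def list_compounds() -> list[str]:
    return sorted(_compounds_raw())


def list_designs() -> list[str]:
    return sorted(_regimens_raw())


def default_enzyme_settings() -> EnzymeSettings:
    raw = json.loads(_data_text("enzyme_settings.json"))
    raw.pop("_comment", None)
    return EnzymeSettings(**raw)


def donor_induction(
    compound: str, readout: str = "mRNA"
) -> dict[str, dict[str, EnzymeInduction | None]]:
    """Per-donor induction blocks: donor -> enzyme -> parameters (None = NC)."""
    frame = _induction_frame(readout)
    sub = frame[frame["compound"] == compound]
    if sub.empty:
        raise InvalidInputError(
            f"no induction data for {compound!r}; perpetrators: {PERPETRATORS}"
        )
    out: dict[str, dict[str, EnzymeInduction | None]] = {}
    for _, row in sub.iterrows():
        block = out.setdefault(row["donor"], {})
        block[row["enzyme"]] = (
            None
            if row["nc"]
            else EnzymeInduction(
                ec50_uM=float(row["ec50_uM"]), emax_fold=float(row["emax_fold"])
            )
        )
    return out


def aggregate_induction(
    compound: str, readout: str = "mRNA", method: str = "geomean"
) -> dict[str, EnzymeInduction | None]:
    """Across-donor aggregate induction parameters.

    Default is the geometric mean of non-NC donors (EC50 and Emax-1 are
    log-scale quantities; the geometric mean of total fold is taken directly,
    matching common practice for donor pooling). All-NC enzymes map to None.
    """
    if method not in ("geomean", "mean"):
        raise InvalidInputError("method must be 'geomean' or 'mean'")
    by_donor = donor_induction(compound, readout)
    enzymes = sorted({e for block in by_donor.values() for e in block})
    out: dict[str, EnzymeInduction | None] = {}
    for enz in enzymes:
        vals = [
            block[enz] for block in by_donor.values() if block.get(enz) is not None
        ]
        if not vals:
            out[enz] = None
            continue
        ec = np.array([v.ec50_uM for v in vals])
        em = np.array([v.emax_fold for v in vals])
        if method == "geomean":
            out[enz] = EnzymeInduction(
                ec50_uM=float(np.exp(np.mean(np.log(ec)))),
                emax_fold=float(np.exp(np.mean(np.log(em)))),
            )
        else:
            out[enz] = EnzymeInduction(
                ec50_uM=float(ec.mean()), emax_fold=float(em.mean())
            )
    return out


def imax_u(compound: str) -> float:
    """Fixture maximal unbound plasma concentration of a perpetrator (uM)."""
    raw = _compounds_raw()
    if compound not in raw or "imax_u_uM" not in raw[compound]:
        raise InvalidInputError(f"no Imax,u fixture for {compound!r}")
    return float(raw[compound]["imax_u_uM"])


def load_compound(
    name: str, readout: str = "mRNA", donor: str | None = None
) -> CompoundModel:
    """Build a validated :class:`CompoundModel` from the vendored registry.

    Perpetrators carry induction blocks (aggregated across non-NC donors by
    geometric mean, or a single donor if ``donor`` is given); victims carry
    their fm map. Unknown names raise with the list of alternatives.
    """
    raw = _compounds_raw()
    if name not in raw:
        raise InvalidInputError(
            f"unknown compound {name!r}; available: {', '.join(sorted(raw))}"
        )
    entry = raw[name]
    role = entry["role"]
    pk = CompoundPK(**entry["pk"])
    induction: dict[str, EnzymeInduction | None] = {}
    by_donor: dict[str, dict[str, EnzymeInduction | None]] = {}
    if role in ("perpetrator", "both"):
        by_donor = donor_induction(name, readout)
        if donor is not None:
            if donor not in by_donor:
                raise InvalidInputError(
                    f"unknown donor {donor!r}; available: {sorted(by_donor)}"
                )
            induction = dict(by_donor[donor])
        else:
            induction = aggregate_induction(name, readout)
    fm = None
    if entry.get("fm"):
        fm = FmMap(victim=name, entries=entry["fm"])
    return CompoundModel(
        name=name,
        role=role,
        pk=pk,
        induction=induction,
        induction_by_donor=by_donor,
        fm=fm,
        experimental=entry.get("experimental", False),
        provenance=entry.get("provenance", {}),
    )


def load_design(victim: str) -> DDIDesign:
    """The packaged clinical DDI design for a victim drug."""
    raw = _regimens_raw()
    if victim not in raw:
        raise InvalidInputError(
            f"no packaged design for {victim!r}; available: {', '.join(sorted(raw))}"
        )
    entry = raw[victim]
    return DDIDesign(
        perpetrator=DosingRegimen(**entry["perpetrator_regimen"]),
        victim=DosingRegimen(**entry["victim_regimen"]),
        label=entry["label"],
    )


def observed_outcomes() -> pd.DataFrame:
    """Published percent-AUC-reduction numbers (transcription; reference
    only, never a computational input)."""
    import io

    return pd.read_csv(
        io.StringIO(_data_text("observed_outcomes_transcription.csv")), comment="#"
    )


# ---------------------------------------------------------------------------
# validation and registry integrity
# ---------------------------------------------------------------------------


def validate_params(model: CompoundModel) -> list[str]:
    """Machine-readable invariant violations for a compound model (empty
    list = clean). Pydantic already rejects ill-typed PK blocks; this checks
    the cross-field invariants."""
    issues: list[str] = []
    pk = model.pk
    if pk.cl_L_h - pk.cl_renal_L_h <= 0:
        issues.append("hepatic clearance (cl_L_h - cl_renal_L_h) must be > 0")
    if model.fm is not None:
        total = sum(model.fm.entries.values())
        if total > 1.0 + 1e-9:
            issues.append(f"fm sum {total:.3f} exceeds 1")
        for enz, v in model.fm.entries.items():
            if not 0 <= v <= 1:
                issues.append(f"fm[{enz}] = {v} outside [0, 1]")
    for donor_block in list(model.induction_by_donor.values()) + [model.induction]:
        for enz, params in donor_block.items():
            if params is None:
                continue
            if params.ec50_uM <= 0:
                issues.append(f"{enz}: EC50 must be > 0")
            if params.emax_fold < 1:
                issues.append(f"{enz}: Emax (total fold) must be >= 1")
    if model.role in ("victim", "both") and model.fm is None:
        issues.append("victim without fm map")
    return issues


def registry_dump() -> pd.DataFrame:
    """Canonical long-format dump of every vendored parameter value with
    units and provenance; the basis of the registry integrity checksum."""
    rows: list[dict] = []
    for readout in ("mRNA", "activity"):
        frame = _induction_frame(readout)
        for _, r in frame.iterrows():
            base = dict(
                compound=r["compound"],
                context=f"induction:{readout}:{r['enzyme']}:{r['donor']}",
                provenance="study-table",
            )
            if r["nc"]:
                rows.append({**base, "parameter": "nc", "value": "NC", "units": ""})
            else:
                rows.append(
                    {
                        **base,
                        "parameter": "ec50",
                        "value": f"{float(r['ec50_uM']):.6g}",
                        "units": "uM",
                    }
                )
                rows.append(
                    {
                        **base,
                        "parameter": "emax",
                        "value": f"{float(r['emax_fold']):.6g}",
                        "units": "fold",
                    }
                )
    for name in sorted(_compounds_raw()):
        entry = _compounds_raw()[name]
        for key, val in sorted(entry["pk"].items()):
            rows.append(
                dict(
                    compound=name,
                    context="pk",
                    provenance="literature",
                    parameter=key,
                    value=f"{float(val):.6g}",
                    units="",
                )
            )
        if "imax_u_uM" in entry:
            rows.append(
                dict(
                    compound=name,
                    context="pk",
                    provenance="literature",
                    parameter="imax_u",
                    value=f"{float(entry['imax_u_uM']):.6g}",
                    units="uM",
                )
            )
        for enz, fmv in sorted((entry.get("fm") or {}).items()):
            rows.append(
                dict(
                    compound=name,
                    context="fm",
                    provenance="study-table",
                    parameter=enz,
                    value=f"{float(fmv):.6g}",
                    units="fraction",
                )
            )
    for victim in sorted(_regimens_raw()):
        entry = _regimens_raw()[victim]
        for block in ("perpetrator_regimen", "victim_regimen"):
            for key, val in sorted(entry[block].items()):
                rows.append(
                    dict(
                        compound=victim,
                        context=f"regimen:{block}",
                        provenance="study-table",
                        parameter=key,
                        value=f"{float(val):.6g}",
                        units="",
                    )
                )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["compound", "context", "parameter", "value"]
    ).reset_index(drop=True)


def registry_checksum() -> str:
    """SHA-256 over the canonical registry dump CSV."""
    dump = registry_dump().to_csv(index=False)
    return hashlib.sha256(dump.encode()).hexdigest()
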
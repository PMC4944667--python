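"""File formats and run configuration for reproducible command-line runs.

All user-facing tabular files are comma-separated text with unit-suffixed
column headers; concentrations are ng/ml in every file and converted to
canonical mg/L at the boundary.  Parameter files are flat ``key = value``
text using the same keys as the packaged fitted-parameter table, plus the
unit dialect under which the values are to be read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .pk_core import (
    EffectSiteParams,
    PKParameters,
    UnitDialect,
    convert_concentration,
    get_dialect,
)
from .protocol import ProtocolSpec
from .simulation import DoseEvent, DosingRegimen, SimulationResult

__all__ = [
    "RunConfig",
    "FormatError",
    "read_regimen",
    "write_regimen",
    "read_cohort",
    "write_cohort",
    "write_trajectory",
    "read_trajectory",
    "read_params",
    "write_params",
    "save_protocol",
    "load_protocol",
    "write_manifest",
]


class FormatError(ValueError):
    """Malformed input file, with file/line context where available."""


@dataclass
class RunConfig:
    """Configuration of one CLI run; recorded in the output manifest."""

    subcommand: str
    seed: int = 0
    dialect: str = "rescaled"
    rtol: float = 1e-8
    atol: float = 1e-10
    params_file: Optional[str] = None
    regimen_file: Optional[str] = None
    out_dir: Optional[str] = None
    force: bool = False
    verbosity: int = 0
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------- regimens

_REGIMEN_COLUMNS = {"start_min", "duration_min"}


def read_regimen(path) -> DosingRegimen:
    """Read a dosing regimen table (start_min, duration_min, and
    rate_mg_per_min or amount_mg per row; optional weight_kg column)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse regimen file: {exc}") from exc
    missing = _REGIMEN_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if "rate_mg_per_min" not in df.columns and "amount_mg" not in df.columns:
        raise FormatError(f"{path}: need rate_mg_per_min or amount_mg column")
    events = []
    for i, row in df.iterrows():
        try:
            rate = row.get("rate_mg_per_min")
            amount = row.get("amount_mg")
            rate = None if rate is None or pd.isna(rate) else float(rate)
            amount = None if amount is None or pd.isna(amount) else float(amount)
            events.append(DoseEvent(start=float(row["start_min"]),
                                    duration=float(row["duration_min"]),
                                    rate=rate, amount=amount))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {i + 2}: {exc}") from exc
    weight = None
    if "weight_kg" in df.columns and df["weight_kg"].notna().any():
        weight = float(df["weight_kg"].dropna().iloc[0])
    return DosingRegimen(tuple(events), weight_kg=weight)


def write_regimen(regimen: DosingRegimen, path) -> None:
    df = pd.DataFrame([{
        "start_min": e.start,
        "duration_min": e.duration,
        "rate_mg_per_min": e.rate if e.duration > 0 else None,
        "amount_mg": e.amount,
        "weight_kg": regimen.weight_kg,
    } for e in regimen.events])
    df.to_csv(path, index=False)


# ----------------------------------------------------------------- cohorts

_COHORT_COLUMNS = {"subject_id", "dose_mg_per_kg", "weight_kg", "time_min", "conc_ng_ml"}


def read_cohort(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse cohort file: {exc}") from exc
    missing = _COHORT_COLUMNS - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if (df["conc_ng_ml"] < 0).any():
        line = int(df.index[df["conc_ng_ml"] < 0][0]) + 2
        raise FormatError(f"{path}: line {line}: negative concentration")
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


# -------------------------------------------------------------- trajectories

def write_trajectory(result: SimulationResult, path) -> None:
    result.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"{path}: cannot parse trajectory file: {exc}") from exc


# ---------------------------------------------------------------- parameters

_PARAM_KEYS = ("Vc_L", "Vp_L", "Q12_L_per_min", "Vm_mg_per_min", "Km", "Km_unit",
               "CL_L_per_min", "k1e_per_min", "ke0_per_min", "dialect",
               "Vp2_L", "Q13_L_per_min")


def read_params(path) -> tuple[PKParameters, Optional[EffectSiteParams], UnitDialect]:
    """Read a flat key/value parameter file.

    Printed values are interpreted under the file's dialect (default
    rescaled): volumes and clearances are scaled, Km is read in the
    stated unit and converted to canonical mg/L.
    """
    path = Path(path)
    kv: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}: line {lineno}: expected 'key = value'")
            k, v = (s.strip() for s in line.split("=", 1))
            if k not in _PARAM_KEYS:
                raise FormatError(f"{path}: line {lineno}: unknown key {k!r}")
            kv[k] = v
    dialect = get_dialect(kv.get("dialect", "rescaled"))
    scale = dialect.volume_scale

    def f(key):
        return float(kv[key]) if key in kv else None

    km = f("Km")
    if km is not None:
        km_unit = kv.get("Km_unit", dialect.km_unit)
        km = convert_concentration(km, km_unit, "mg/L")
    vp2 = f("Vp2_L")
    n_peripheral = 2 if vp2 is not None else (1 if f("Vp_L") is not None else 0)
    try:
        params = PKParameters(
            Vc=f("Vc_L") * scale,
            Vp=None if f("Vp_L") is None else f("Vp_L") * scale,
            Q12=None if f("Q12_L_per_min") is None else f("Q12_L_per_min") * scale,
            Vm=f("Vm_mg_per_min"),
            Km=km,
            CL=None if f("CL_L_per_min") is None else f("CL_L_per_min") * scale,
            Vp2=None if vp2 is None else vp2 * scale,
            Q13=None if f("Q13_L_per_min") is None else f("Q13_L_per_min") * scale,
            n_peripheral=n_peripheral,
            meta={"dialect": dialect.name, "source": str(path)},
        )
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: invalid parameter set: {exc}") from exc
    effect = None
    if "k1e_per_min" in kv or "ke0_per_min" in kv:
        k1e = f("k1e_per_min")
        ke0 = f("ke0_per_min")
        effect = EffectSiteParams(k1e=k1e if k1e is not None else ke0, ke0=ke0,
                                  allow_unlinked=True)
    return params, effect, dialect


def write_params(params: PKParameters, path, effect: Optional[EffectSiteParams] = None,
                 dialect_name: str = "rescaled") -> None:
    """Write a parameter file in canonical-to-dialect printed form."""
    dialect = get_dialect(dialect_name)
    scale = dialect.volume_scale
    lines = [f"dialect = {dialect.name}", f"Vc_L = {params.Vc / scale!r}"]
    if params.n_peripheral >= 1:
        lines += [f"Vp_L = {params.Vp / scale!r}", f"Q12_L_per_min = {params.Q12 / scale!r}"]
    if params.n_peripheral == 2:
        lines += [f"Vp2_L = {params.Vp2 / scale!r}", f"Q13_L_per_min = {params.Q13 / scale!r}"]
    if params.is_saturable:
        km_printed = convert_concentration(params.Km, "mg/L", dialect.km_unit)
        lines += [f"Vm_mg_per_min = {params.Vm!r}", f"Km = {km_printed!r}",
                  f"Km_unit = {dialect.km_unit}"]
    else:
        lines.append(f"CL_L_per_min = {params.CL / scale!r}")
    if effect is not None:
        lines += [f"k1e_per_min = {effect.k1e!r}", f"ke0_per_min = {effect.ke0!r}"]
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------ protocol specs

def save_protocol(spec: ProtocolSpec, path) -> None:
    doc = {
        "target_ng_ml": spec.target_ng_ml,
        "bolus_mg": spec.bolus_mg,
        "bolus_duration_min": spec.bolus_duration_min,
        "infusion_start_min": spec.infusion_start_min,
        "update_interval_min": spec.update_interval_min,
        "schedule": [{"start_min": t0, "end_min": t1, "rate_mg_per_min": r}
                     for t0, t1, r in spec.schedule],
        "rss_mg_per_min": spec.rss_mg_per_min,
        "steady_state_time_min": spec.steady_state_time_min,
        "horizon_min": spec.horizon_min,
        "warnings": list(spec.warnings),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_protocol(path) -> ProtocolSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return ProtocolSpec(
            target_ng_ml=doc["target_ng_ml"],
            bolus_mg=doc["bolus_mg"],
            bolus_duration_min=doc["bolus_duration_min"],
            infusion_start_min=doc["infusion_start_min"],
            update_interval_min=doc["update_interval_min"],
            schedule=[(d["start_min"], d["end_min"], d["rate_mg_per_min"])
                      for d in doc["schedule"]],
            rss_mg_per_min=doc["rss_mg_per_min"],
            steady_state_time_min=doc["steady_state_time_min"],
            horizon_min=doc["horizon_min"],
            warnings=list(doc.get("warnings", [])),
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: invalid protocol spec: {exc}") from exc


# ---------------------------------------------------------------- manifests

def write_manifest(config: RunConfig, out_dir, inputs: dict, outputs: list[str]) -> Path:
    """Record everything needed to reproduce a run bit-identically."""
    from . import __version__

    doc = {
        "package": "dmtpk",
        "version": __version__,
        "config": asdict(config),
        "inputs": inputs,
        "outputs": outputs,
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return path
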
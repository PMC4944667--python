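"""Core domain types and algebra for compartmental DMT pharmacokinetics.

Canonical internal units throughout the package: time in minutes, mass in
milligrams, volume in litres, concentration in mg/L.  Nanograms per
millilitre (the unit plasma DMT assays report, identical to µg/L) are
accepted and emitted at user-facing boundaries via
:func:`convert_concentration`.

The shipped parameter table prints central volumes of ~0.1 L, yet the same
source's own worked bolus arithmetic (a 25 mg bolus producing a plasma spike
of just over 200 ng/ml) requires an apparent central volume near 100 L.  The
two readings are irreconcilable; :class:`UnitDialect` exposes both, and the
``rescaled`` dialect (volumes and inter-compartmental clearance ×1000, Km
read in µg/L) is the default because it is the only reading that reproduces
the published simulation narrative.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

__all__ = [
    "PKParameters",
    "EffectSiteParams",
    "UnitDialect",
    "LITERAL",
    "RESCALED",
    "mm_elimination_rate",
    "derive_micro_rate_constants",
    "convert_concentration",
    "load_table2",
]

# conversion factors to the canonical concentration unit, mg/L
_CONC_TO_MG_PER_L = {
    "mg/L": 1.0,
    "ug/L": 1e-3,
    "µg/L": 1e-3,
    "ng/ml": 1e-3,
    "ng/mL": 1e-3,
}


def convert_concentration(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a concentration between ng/ml, µg/L and mg/L.

    ng/ml and µg/L are the same unit; mg/L = 1000 µg/L.  Identity
    conversions return the input unchanged (bit-identical round trips).
    """
    try:
        f = _CONC_TO_MG_PER_L[from_unit]
        t = _CONC_TO_MG_PER_L[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown concentration unit: {exc.args[0]!r}") from None
    if f == t:
        return value
    # explicit multiply/divide by the exact integer factor keeps round
    # trips bit-identical for decimally-printed values
    return value * 1000.0 if f > t else value / 1000.0


def mm_elimination_rate(C: float, Vm: float, Km: float) -> float:
    """Michaelis-Menten (saturable enzymatic) elimination rate, mg/min.

    ``Vm * C / (Km + C)`` with plasma concentration ``C`` and ``Km`` in
    mg/L and maximum rate ``Vm`` in mg/min.  Strictly increasing and
    concave in C, bounded above by Vm; equals Vm/2 at C = Km.
    """
    if C < 0:
        raise ValueError(f"negative concentration: {C}")
    if Vm <= 0 or Km <= 0:
        raise ValueError("Vm and Km must be strictly positive")
    return Vm * C / (Km + C)


@dataclass(frozen=True)
class UnitDialect:
    """Interpretation applied to the printed parameter table.

    ``literal`` takes the table at face value (volumes in L, Km in mg/L);
    ``rescaled`` multiplies volumes and Q12 by 1000 and reads Km in µg/L,
    the reading consistent with the published bolus/plasma-spike narrative.
    """

    name: str
    volume_scale: float
    km_unit: str

    def __post_init__(self) -> None:
        if self.name == "literal":
            if self.volume_scale != 1.0 or self.km_unit != "mg/L":
                raise ValueError("literal dialect requires volume_scale=1, Km in mg/L")
        elif self.name == "rescaled":
            if self.volume_scale != 1000.0 or self.km_unit not in ("ug/L", "µg/L"):
                raise ValueError("rescaled dialect requires volume_scale=1000, Km in µg/L")
        else:
            raise ValueError(f"unknown dialect: {self.name!r}")


LITERAL = UnitDialect("literal", 1.0, "mg/L")
RESCALED = UnitDialect("rescaled", 1000.0, "ug/L")

_DIALECTS = {"literal": LITERAL, "rescaled": RESCALED}


def get_dialect(name: str) -> UnitDialect:
    try:
        return _DIALECTS[name]
    except KeyError:
        raise ValueError(f"unknown dialect: {name!r} (expected literal or rescaled)") from None


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters of a mammillary compartmental model.

    All values in canonical units: volumes L, clearances L/min, Vm mg/min,
    Km mg/L.  Exactly one elimination description must be present: either
    linear clearance ``CL`` or the Michaelis-Menten pair ``(Vm, Km)``.
    ``n_peripheral`` is 0, 1 or 2; the second peripheral compartment
    (Vp2, Q13) exists only for the 3-compartment candidate in model
    selection.
    """

    Vc: float
    Vp: Optional[float] = None
    Q12: Optional[float] = None
    Vm: Optional[float] = None
    Km: Optional[float] = None
    CL: Optional[float] = None
    Vp2: Optional[float] = None
    Q13: Optional[float] = None
    n_peripheral: int = 1
    meta: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.Vc > 0:
            raise ValueError("Vc must be strictly positive")
        has_mm = self.Vm is not None or self.Km is not None
        has_cl = self.CL is not None
        if has_mm and has_cl:
            raise ValueError("CL is exclusive with (Vm, Km)")
        if has_mm and (self.Vm is None or self.Km is None):
            raise ValueError("Vm and Km must be set together")
        if not (has_mm or has_cl):
            raise ValueError("one of CL or (Vm, Km) must be set")
        if has_mm and (self.Vm <= 0 or self.Km <= 0):
            raise ValueError("Vm and Km must be strictly positive")
        if has_cl and self.CL <= 0:
            raise ValueError("CL must be strictly positive")
        if self.n_peripheral not in (0, 1, 2):
            raise ValueError("n_peripheral must be 0, 1 or 2")
        if self.n_peripheral >= 1:
            if self.Vp is None or self.Q12 is None or self.Vp <= 0 or self.Q12 < 0:
                raise ValueError("peripheral compartment requires Vp > 0 and Q12 >= 0")
        if self.n_peripheral == 2:
            if self.Vp2 is None or self.Q13 is None or self.Vp2 <= 0 or self.Q13 < 0:
                raise ValueError("second peripheral compartment requires Vp2 > 0 and Q13 >= 0")

    @property
    def is_saturable(self) -> bool:
        return self.Vm is not None

    def elimination_rate(self, C: float) -> float:
        """Elimination rate (mg/min) at plasma concentration C (mg/L)."""
        if self.is_saturable:
            return mm_elimination_rate(C, self.Vm, self.Km)
        if C < 0:
            raise ValueError(f"negative concentration: {C}")
        return self.CL * C


def derive_micro_rate_constants(params: PKParameters) -> tuple[float, float]:
    """Micro rate constants (k12, k21) = (Q12/Vc, Q12/Vp), 1/min.

    Invariant under unit-dialect rescaling since numerator and denominator
    scale together.
    """
    if params.n_peripheral == 0:
        return (0.0, 0.0)
    return (params.Q12 / params.Vc, params.Q12 / params.Vp)


@dataclass(frozen=True)
class EffectSiteParams:
    """First-order effect-site link: dCe/dt = k1e*Cc - ke0*Ce.

    The effect site is a mass-less link compartment (draws no mass from
    plasma).  At the effect-site peak, dCe/dt = 0 forces
    Ce = (k1e/ke0)*Cc, so the observed equality of plasma and effect-site
    concentration at peak effect holds identically iff k1e = ke0; default
    construction therefore sets ke0 = k1e, and deliberately unequal
    constants must be requested with ``allow_unlinked=True``.
    """

    k1e: float
    ke0: Optional[float] = None
    allow_unlinked: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if self.ke0 is None:
            object.__setattr__(self, "ke0", self.k1e)
        if self.k1e <= 0 or self.ke0 <= 0:
            raise ValueError("k1e and ke0 must be strictly positive")
        if self.ke0 != self.k1e and not self.allow_unlinked:
            raise ValueError(
                "k1e != ke0 breaks the peak-equality constraint; "
                "pass allow_unlinked=True to override"
            )

    @classmethod
    def linked(cls, k: float) -> "EffectSiteParams":
        return cls(k1e=k, ke0=k)


def _read_fitted_table() -> configparser.ConfigParser:
    cp = configparser.ConfigParser()
    with resources.files("dmtpk.data").joinpath("fitted_params.txt").open() as fh:
        cp.read_file(fh)
    return cp


def load_table2(dose_group: float, dialect: UnitDialect = RESCALED) -> PKParameters:
    """Load the packaged fitted parameter set for a dose group (mg/kg).

    ``dialect`` controls the unit interpretation of the printed values:
    under ``rescaled`` (default) volumes and Q12 are multiplied by 1000
    and Km is read in µg/L, then converted to canonical mg/L.  Provenance
    (dialect, source section) is recorded in ``meta``.
    """
    if dose_group not in (0.2, 0.4):
        raise ValueError(f"no fitted parameter set for dose group {dose_group}")
    cp = _read_fitted_table()
    section = f"dose_{dose_group}_mg_per_kg"
    row = cp[section]
    km_printed = float(row["Km"])
    km_mg_per_l = convert_concentration(km_printed, dialect.km_unit, "mg/L")
    return PKParameters(
        Vc=float(row["Vc_L"]) * dialect.volume_scale,
        Vp=float(row["Vp_L"]) * dialect.volume_scale,
        Q12=float(row["Q12_L_per_min"]) * dialect.volume_scale,
        Vm=float(row["Vm_mg_per_min"]),
        Km=km_mg_per_l,
        meta={"dialect": dialect.name, "source": section},
    )
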
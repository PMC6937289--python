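"""Culm biomechanics of rice internodes.

Rice lodging studies characterise each elongated internode as a hollow
cylinder loaded in three-point bending.  This module implements the standard
quantities derived from caliper geometry and a portable bending tester:

* ``section_moment_of_area`` — second moment of area *I* of the annular
  cross-section,
* ``elastic_modulus`` — Young's modulus *E* from the elastic mid-span
  deflection,
* ``flexural_rigidity`` — bending stiffness *E·I*,
* ``bending_moment`` — self-load moment at the internode base (lever arm to
  the panicle tip times the fresh weight above),
* ``lodging_index`` — bending moment over breaking resistance, the field's
  standard lodging-tendency score,
* ``culm_volume`` and ``densities`` — shell volume and dry-matter plumpness.

Boundary units follow field convention: mm for diameter and wall thickness,
cm for lengths and deflection, N for forces, g/mg for masses.  Results are
reported in GPa (E), 10^-3 N·m^2 (E·I), gf·cm (bending moment), cm^3
(volume) and cm·g·g^-1 (lodging index); all internal computation is SI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "GF_TO_N",
    "InternodeRecord",
    "MechanicalProfile",
    "section_moment_of_area",
    "elastic_modulus",
    "flexural_rigidity",
    "culm_volume",
    "bending_moment",
    "lodging_index",
    "breaking_bending_moment",
    "densities",
    "mech_profile",
    "profile_table",
    "newton_to_gf",
    "gf_to_newton",
]

#: One gram-force in newtons (standard gravity).
GF_TO_N = 9.80665e-3

DEFAULT_SPAN_CM = 5.0


def newton_to_gf(force_n: float) -> float:
    """Convert newtons to gram-force."""
    return force_n / GF_TO_N


def gf_to_newton(force_gf: float) -> float:
    """Convert gram-force to newtons."""
    return force_gf * GF_TO_N


def section_moment_of_area(a: float, t: float) -> float:
    """Second moment of area of a hollow circular culm section.

    Parameters
    ----------
    a : float
        Outer radius at mid-internode, mm.
    t : float
        Culm wall thickness, mm.  ``t == a`` is the solid-rod limit.

    Returns
    -------
    float
        I = pi*a^4/4 * [1 - (1 - t/a)^4], in mm^4.  Algebraically identical
        to the shell difference pi/4*(a^4 - (a-t)^4).
    """
    if a <= 0 or t <= 0:
        raise ValueError(f"radius and wall thickness must be positive (a={a}, t={t})")
    if t > a:
        raise ValueError(f"wall thickness t={t} exceeds radius a={a}")
    return math.pi * a**4 / 4.0 * (1.0 - (1.0 - t / a) ** 4)


def elastic_modulus(force_n: float, span_cm: float, deflect_cm: float, i_mm4: float) -> float:
    """Young's modulus from elastic three-point bending.

    E = F*L^3 / (48*delta*I) with the load F in N, the support span L in cm
    (the distance between the two braces, not the internode length), the
    mid-span deflection delta in cm, and I in mm^4.  Returns GPa.
    """
    if force_n <= 0 or span_cm <= 0:
        raise ValueError("load and span must be positive")
    if deflect_cm <= 0:
        raise ValueError("deflection must be positive")
    if i_mm4 <= 0:
        raise ValueError("section moment of area must be positive")
    pa = force_n * (span_cm / 100.0) ** 3 / (48.0 * (deflect_cm / 100.0) * (i_mm4 * 1e-12))
    return pa / 1e9


def flexural_rigidity(e_gpa: float, i_mm4: float, *, milli: bool = True) -> float:
    """Bending stiffness E*I.

    Returns 10^-3 N*m^2 by default (the unit lodging tables print);
    ``milli=False`` returns plain N*m^2.  E in GPa times I in mm^4 gives
    E*I*1e-3 N*m^2 exactly.
    """
    if e_gpa < 0 or i_mm4 < 0:
        raise ValueError("E and I must be non-negative")
    ei_nm2 = e_gpa * i_mm4 * 1e-3
    return ei_nm2 * 1e3 if milli else ei_nm2


def culm_volume(length_cm: float, a_cm: float, t_cm: float) -> float:
    """Shell volume of the internode, pi*L*(2*a*t - t^2), in cm^3.

    All arguments in cm.  Identical to the cylinder difference
    pi*L*(a^2 - (a-t)^2).
    """
    if length_cm <= 0:
        raise ValueError("length must be positive")
    if t_cm <= 0 or a_cm <= 0:
        raise ValueError("radius and wall must be positive")
    if t_cm > a_cm:
        raise ValueError(f"wall t={t_cm} cm exceeds radius a={a_cm} cm")
    return math.pi * length_cm * (2.0 * a_cm * t_cm - t_cm**2)


def bending_moment(dist_tip_cm: float, fresh_above_g: float) -> float:
    """Self-load bending moment at the internode base, gf*cm.

    Lever arm = distance from the internode base to the panicle tip (cm);
    load = fresh weight of that whole section (g, i.e. gram-force).
    """
    if dist_tip_cm < 0 or fresh_above_g < 0:
        raise ValueError("distance and weight must be non-negative")
    return dist_tip_cm * fresh_above_g


def breaking_bending_moment(break_n: float, span_cm: float = DEFAULT_SPAN_CM) -> float:
    """Mid-span bending moment at failure in three-point bending, gf*cm.

    M = F*L/4 with the breaking force converted to gram-force.  Provided as
    an alternative lodging-index denominator that puts numerator and
    denominator on the same moment scale.
    """
    if break_n < 0:
        raise ValueError("breaking force must be non-negative")
    if span_cm <= 0:
        raise ValueError("span must be positive")
    return newton_to_gf(break_n) * span_cm / 4.0


def lodging_index(
    bm_gfcm: float,
    break_n: float,
    *,
    mode: str = "force",
    span_cm: float = DEFAULT_SPAN_CM,
) -> float:
    """Lodging index: bending moment over breaking resistance, cm*g*g^-1.

    ``mode="force"`` (default) divides by the breaking force converted
    N -> gram-force, the literal reading of moment/resistance.
    ``mode="moment"`` divides by the breaking bending moment F*span/4,
    which renders the index dimensionless.  Higher values mean greater
    lodging tendency.
    """
    if break_n <= 0:
        raise ValueError("breaking force must be positive")
    if bm_gfcm < 0:
        raise ValueError("bending moment must be non-negative")
    if mode == "force":
        return bm_gfcm / newton_to_gf(break_n)
    if mode == "moment":
        return bm_gfcm / breaking_bending_moment(break_n, span_cm)
    raise ValueError(f"unknown lodging-index mode {mode!r} (use 'force' or 'moment')")


def densities(dry_mg: float, length_cm: float, vol_cm3: float) -> tuple[float, float]:
    """Dry weight per unit length (mg/cm) and per unit volume (mg/cm^3)."""
    if length_cm <= 0 or vol_cm3 <= 0:
        raise ValueError("length and volume must be positive")
    if dry_mg < 0:
        raise ValueError("dry weight must be non-negative")
    return dry_mg / length_cm, dry_mg / vol_cm3


@dataclass
class InternodeRecord:
    """One internode of one culm with its field measurements.

    Internodes are indexed 1..5 counting upward from the base; I1–I3 are the
    lower internodes that govern lodging.  Optional fields are None when the
    measurement was not taken (breaking resistance is not measured on
    internodes shorter than the 5 cm support span).
    """

    variety: str
    treatment: str
    replicate: int
    culm: int
    internode: int
    length_cm: float
    diameter_mm: float
    wall_mm: float
    fresh_g: Optional[float] = None
    dry_mg: Optional[float] = None
    dist_tip_cm: Optional[float] = None
    fresh_above_g: Optional[float] = None
    break_N: Optional[float] = None
    deflect_cm: Optional[float] = None
    elastic_F_N: Optional[float] = None
    span_cm: float = DEFAULT_SPAN_CM

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 1 <= int(self.internode) <= 5:
            raise ValueError(f"internode index {self.internode} outside 1..5")
        if self.length_cm <= 0:
            raise ValueError(f"length_cm must be positive, got {self.length_cm}")
        if self.diameter_mm <= 0:
            raise ValueError(f"diameter_mm must be positive, got {self.diameter_mm}")
        if not 0 < self.wall_mm <= self.diameter_mm / 2.0:
            raise ValueError(
                f"wall_mm={self.wall_mm} must lie in (0, diameter/2={self.diameter_mm / 2}]"
            )
        if self.break_N is not None and self.length_cm < self.span_cm:
            raise ValueError(
                f"breaking force recorded for a {self.length_cm} cm internode "
                f"shorter than the {self.span_cm} cm support span"
            )

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass
class MechanicalProfile:
    """Derived per-internode mechanics; None where inputs were absent."""

    I_mm4: float
    vol_cm3: float
    E_GPa: Optional[float] = None
    EI_mNm2: Optional[float] = None
    BM_gfcm: Optional[float] = None
    break_BM_gfcm: Optional[float] = None
    LI: Optional[float] = None
    dwl_mg_per_cm: Optional[float] = None
    dwv_mg_per_cm3: Optional[float] = None
    li_mode: str = field(default="force")


def mech_profile(record: InternodeRecord, *, li_mode: str = "force") -> MechanicalProfile:
    """Compute every derivable mechanical quantity for one internode.

    Geometry-only fields (I, volume) are always present; fields depending on
    optional measurements are None when their inputs are absent — never a
    silent zero.
    """
    record.validate()
    a_mm = record.radius_mm
    i_mm4 = section_moment_of_area(a_mm, record.wall_mm)
    vol = culm_volume(record.length_cm, a_mm / 10.0, record.wall_mm / 10.0)

    e_gpa = None
    if record.elastic_F_N is not None and record.deflect_cm is not None:
        e_gpa = elastic_modulus(record.elastic_F_N, record.span_cm, record.deflect_cm, i_mm4)
    ei = flexural_rigidity(e_gpa, i_mm4) if e_gpa is not None else None

    bm = None
    if record.dist_tip_cm is not None and record.fresh_above_g is not None:
        bm = bending_moment(record.dist_tip_cm, record.fresh_above_g)

    bbm = None
    li = None
    if record.break_N is not None:
        bbm = breaking_bending_moment(record.break_N, record.span_cm)
        if bm is not None:
            li = lodging_index(bm, record.break_N, mode=li_mode, span_cm=record.span_cm)

    dwl = dwv = None
    if record.dry_mg is not None:
        dwl, dwv = densities(record.dry_mg, record.length_cm, vol)

    return MechanicalProfile(
        I_mm4=i_mm4,
        vol_cm3=vol,
        E_GPa=e_gpa,
        EI_mNm2=ei,
        BM_gfcm=bm,
        break_BM_gfcm=bbm,
        LI=li,
        dwl_mg_per_cm=dwl,
        dwv_mg_per_cm3=dwv,
        li_mode=li_mode,
    )


_OPTIONAL_COLS = (
    "fresh_g",
    "dry_mg",
    "dist_tip_cm",
    "fresh_above_g",
    "break_N",
    "deflect_cm",
    "elastic_F_N",
)

_PROFILE_COLS = (
    "I_mm4",
    "vol_cm3",
    "E_GPa",
    "EI_mNm2",
    "BM_gfcm",
    "break_BM_gfcm",
    "LI",
    "dwl_mg_per_cm",
    "dwv_mg_per_cm3",
)


def profile_table(records, *, li_mode: str = "force"):
    """Apply :func:`mech_profile` to every row of an internode table.

    ``records`` is a pandas DataFrame in the internode CSV schema (NaN for
    absent optional measurements).  Returns the input columns plus one column
    per :class:`MechanicalProfile` field; absent inputs give NaN outputs.
    """
    import pandas as pd

    derived = []
    for row in records.itertuples(index=False):
        kwargs = {}
        for col in _OPTIONAL_COLS:
            val = getattr(row, col, None)
            if val is not None and not pd.isna(val):
                kwargs[col] = float(val)
        rec = InternodeRecord(
            variety=row.variety,
            treatment=row.treatment,
            replicate=int(row.replicate),
            culm=int(row.culm),
            internode=int(row.internode),
            length_cm=float(row.length_cm),
            diameter_mm=float(row.diameter_mm),
            wall_mm=float(row.wall_mm),
            span_cm=float(getattr(row, "span_cm", DEFAULT_SPAN_CM)),
            **kwargs,
        )
        prof = mech_profile(rec, li_mode=li_mode)
        derived.append({c: getattr(prof, c) for c in _PROFILE_COLS})
    out = records.reset_index(drop=True).join(pd.DataFrame(derived))
    return out
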
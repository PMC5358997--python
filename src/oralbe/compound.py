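"""Drug-specific parameters and scalar pharmacokinetic algebra.

A :class:`CompoundProfile` carries the physicochemical, binding, clearance,
permeability and transporter parameters of one drug. The functions in this
module implement the closed-form algebra that connects them: ionization
(Henderson--Hasselbalch), plasma-to-blood unbound-fraction conversion, the
well-stirred hepatic extraction model, the oral bioavailability decomposition
``Foral = fa * fg * fh``, and the retrograde calculation of intrinsic
metabolic clearance from in vivo oral clearance.

Bundled presets (``amlodipine``, ``atorvastatin``) are YAML files shipped
with the package; load them with :func:`load_compound`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import yaml

__all__ = [
    "CompoundProfile",
    "SystemPhysiology",
    "fraction_unionized",
    "fu_blood",
    "hepatic_extraction",
    "oral_bioavailability",
    "retrograde_clint",
    "systemic_intrinsic_clearance",
    "load_compound",
    "compound_from_dict",
    "compound_to_dict",
]

logger = logging.getLogger(__name__)

_IONIZATION_CLASSES = ("diprotic_base", "monoprotic_acid", "neutral")


@dataclass(frozen=True)
class CompoundProfile:
    """All drug-specific model inputs for one compound.

    Units: ``mw`` g/mol; ``fu`` unbound fraction in plasma (0-1];
    ``bp_ratio`` blood-to-plasma concentration ratio; ``vss`` L/kg
    (plasma-referenced); ``clpo`` oral (apparent plasma) clearance, unit given
    by ``clpo_unit``; ``clint_3a4`` uL/min/pmol CYP3A4; ``peff`` human
    jejunal effective permeability, cm/s; P-gp kinetics ``jmax_pgp``
    pmol/cm^2/min, ``km_pgp`` uM, ``raf_pgp`` dimensionless.

    ``retrograde_fa`` / ``retrograde_fg`` are the absorbed / gut-escape
    fractions assumed when back-calculating intrinsic clearance from
    ``clpo`` (for atorvastatin the literature assumption fa=1, fg=0.24).
    """

    name: str
    ionization_class: str
    mw: float
    logp: float
    pka: tuple[float, ...]
    fu: float
    bp_ratio: float
    vss: float
    clpo: float
    peff: float
    clpo_unit: str = "L/h"
    clint_3a4: Optional[float] = None
    jmax_pgp: Optional[float] = None
    km_pgp: Optional[float] = None
    raf_pgp: Optional[float] = None
    retrograde_fa: float = 1.0
    retrograde_fg: float = 1.0

    def __post_init__(self) -> None:
        if self.ionization_class not in _IONIZATION_CLASSES:
            raise ValueError(
                f"unknown ionization class {self.ionization_class!r}; "
                f"expected one of {_IONIZATION_CLASSES}"
            )
        if not (0.0 < self.fu <= 1.0):
            raise ValueError(f"fu must be in (0, 1], got {self.fu}")
        if self.bp_ratio <= 0:
            raise ValueError("bp_ratio must be > 0")
        if self.vss <= 0:
            raise ValueError("vss must be > 0")
        if self.mw <= 0:
            raise ValueError("mw must be > 0")
        pka = tuple(float(p) for p in self.pka)
        if list(pka) != sorted(pka, reverse=True):
            raise ValueError("pka values must be sorted descending")
        object.__setattr__(self, "pka", pka)
        pgp = (self.jmax_pgp, self.km_pgp, self.raf_pgp)
        if any(v is not None for v in pgp) and not all(v is not None for v in pgp):
            raise ValueError(
                "transporter kinetics must be all-present or all-absent "
                "(jmax_pgp, km_pgp, raf_pgp)"
            )

    @property
    def has_pgp(self) -> bool:
        return self.jmax_pgp is not None

    @property
    def clpo_l_per_h(self) -> float:
        """Oral plasma clearance in L/h regardless of the stored unit tag."""
        if self.clpo_unit == "L/h":
            return self.clpo
        if self.clpo_unit == "L/min":
            return self.clpo * 60.0
        if self.clpo_unit == "mL/min":
            return self.clpo * 60.0 / 1000.0
        raise ValueError(f"unsupported clpo_unit {self.clpo_unit!r}")

    @property
    def fu_blood(self) -> float:
        return fu_blood(self.fu, self.bp_ratio)

    def with_(self, **kwargs) -> "CompoundProfile":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SystemPhysiology:
    """System (drug-independent) parameters of the disposition model.

    ``hepatic_blood_flow`` L/h; CYP3A4 abundances in pmol (whole liver and
    whole small-intestinal mucosa); ``liver_volume`` L of well-stirred liver
    compartment; ``renal_fraction`` fraction of systemic clearance that is
    renal (both bundled drugs are modeled as hepatically cleared, so 0).
    """

    hepatic_blood_flow: float = 90.0
    liver_cyp3a4_abundance: float = 9.0e6
    gut_cyp3a4_abundance: float = 7.0e4
    body_weight: float = 70.0
    liver_volume: float = 2.0
    renal_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("hepatic_blood_flow", "liver_cyp3a4_abundance",
                     "gut_cyp3a4_abundance", "body_weight", "liver_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.renal_fraction < 1.0):
            raise ValueError("renal_fraction must be in [0, 1)")


def fraction_unionized(compound: CompoundProfile, ph: float) -> float:
    """Fraction of the compound in its neutral (un-ionized) form at ``ph``.

    Henderson--Hasselbalch for the compound's stated ionization class. A
    diprotic base uses both pKa values (B, BH+, BH2++ species); a neutral
    compound returns 1.
    """
    if not (0.0 <= ph <= 14.0):
        raise ValueError("pH must lie in [0, 14]")
    cls = compound.ionization_class
    if cls == "neutral":
        return 1.0
    if cls == "monoprotic_acid":
        (pka,) = compound.pka[:1]
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    if cls == "diprotic_base":
        if len(compound.pka) < 2:
            raise ValueError("diprotic base requires two pKa values")
        pka1, pka2 = compound.pka[0], compound.pka[1]
        # species ratios relative to neutral base B:
        # [BH+]/[B] = 10^(pka1-pH), [BH2++]/[B] = 10^(pka1+pka2-2 pH)
        return 1.0 / (
            1.0 + 10.0 ** (pka1 - ph) + 10.0 ** (pka1 + pka2 - 2.0 * ph)
        )
    raise ValueError(f"unsupported ionization class {cls!r}")


def fu_blood(fu_plasma: float, bp_ratio: float, hematocrit: float = 0.45) -> float:
    """Unbound fraction referenced to whole blood: fu_b = fu_p / (B:P)."""
    if not (0.0 < fu_plasma <= 1.0):
        raise ValueError("fu_plasma must be in (0, 1]")
    if bp_ratio <= 0:
        raise ValueError("bp_ratio must be > 0")
    return fu_plasma / bp_ratio


def hepatic_extraction(
    fu_b: float, clu_int_liver: float, q_h: float
) -> tuple[float, float, float]:
    """Well-stirred hepatic clearance.

    Returns ``(CL_h, E_h, f_h)`` with CL_h = Q_h*fu_b*CLu_int /
    (Q_h + fu_b*CLu_int); all clearances/flows in the same unit (L/h).
    """
    if fu_b <= 0 or clu_int_liver <= 0 or q_h <= 0:
        raise ValueError("fu_b, clu_int_liver and q_h must all be > 0")
    x = fu_b * clu_int_liver
    cl_h = q_h * x / (q_h + x)
    e_h = cl_h / q_h
    return cl_h, e_h, 1.0 - e_h


def oral_bioavailability(fa: float, fg: float, fh: float) -> float:
    """Foral = fa * fg * fh."""
    for name, v in (("fa", fa), ("fg", fg), ("fh", fh)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return fa * fg * fh


def retrograde_clint(
    clpo: float,
    fa: float,
    fg: float,
    fu_b: float,
    q_h: float,
    enzyme_abundance: float,
) -> float:
    """Back-calculate per-pmol intrinsic clearance from in vivo oral clearance.

    Inverts ``CLpo = CL_h / (fa * fg * fh)`` under the well-stirred liver
    model. Because CL_h / fh = fu_b * CLu_int identically, the inversion is
    closed-form: ``CLu_int = CLpo * fa * fg / fu_b`` (whole liver, same unit
    as ``clpo``, blood-referenced). The result is divided by
    ``enzyme_abundance`` (pmol) and converted to uL/min/pmol.

    The round trip through :func:`hepatic_extraction` and
    :func:`oral_bioavailability` reproduces ``clpo`` exactly.
    """
    if clpo <= 0:
        raise ValueError("clpo must be > 0")
    for name, v in (("fa", fa), ("fg", fg)):
        if not (0.0 < v <= 1.0):
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    if fu_b <= 0 or q_h <= 0 or enzyme_abundance <= 0:
        raise ValueError("fu_b, q_h and enzyme_abundance must be > 0")
    clu_int_l_h = clpo * fa * fg / fu_b  # whole liver, L/h
    # L/h -> uL/min, then per pmol of enzyme
    return clu_int_l_h * 1.0e6 / 60.0 / enzyme_abundance


def systemic_intrinsic_clearance(
    compound: CompoundProfile, system: SystemPhysiology
) -> float:
    """Whole-liver unbound intrinsic clearance (blood-referenced, L/h).

    Derived retrograde from the compound's oral clearance using its stored
    fa/fg assumptions: fu_b*CLu_int = CLpo_blood * fa * fg. This is the
    quantity the minimal PBPK disposition model consumes (as fu_b*CLu_int).
    """
    clpo_blood = compound.clpo_l_per_h / compound.bp_ratio
    x = clpo_blood * compound.retrograde_fa * compound.retrograde_fg
    return x / compound.fu_blood


# ---------------------------------------------------------------------------
# YAML IO

_FIELDS = [
    "name", "ionization_class", "mw", "logp", "pka", "fu", "bp_ratio",
    "vss", "clpo", "clpo_unit", "peff", "clint_3a4", "jmax_pgp",
    "km_pgp", "raf_pgp", "retrograde_fa", "retrograde_fg",
]


def compound_from_dict(d: dict) -> CompoundProfile:
    kwargs = {k: d[k] for k in _FIELDS if k in d}
    kwargs["pka"] = tuple(kwargs.get("pka", ()))
    if kwargs.get("clpo_unit", "L/h") != "L/h":
        logger.warning(
            "compound %s: clpo given in %s; converting to L/h",
            kwargs.get("name"), kwargs["clpo_unit"],
        )
    return CompoundProfile(**kwargs)


def compound_to_dict(compound: CompoundProfile) -> dict:
    d = {}
    for k in _FIELDS:
        v = getattr(compound, k)
        if v is None:
            continue
        d[k] = list(v) if isinstance(v, tuple) else v
    return d


def load_compound(name_or_path: str) -> CompoundProfile:
    """Load a compound file: a bundled preset name or a YAML file path."""
    try:
        ref = resources.files("oralbe.presets").joinpath(f"{name_or_path}.yaml")
        if ref.is_file():
            data = yaml.safe_load(ref.read_text())
            return compound_from_dict(data)
    except (ModuleNotFoundError, FileNotFoundError):
        pass
    with open(name_or_path) as fh:
        data = yaml.safe_load(fh)
    return compound_from_dict(data)


def save_compound(compound: CompoundProfile, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(compound_to_dict(compound), fh, sort_keys=False)
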
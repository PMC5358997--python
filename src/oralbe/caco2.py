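"""Caco-2 monolayer transport analysis.

TEER monolayer-integrity values, sampling-corrected cumulative mass
transfer, apparent permeability Papp = (dQ/dt) / (C0 * A) from the linear
portion of the cumulative-mass curve, efflux ratio Papp(B->A)/Papp(A->B),
and donor/receiver mass balance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransportExperiment",
    "PermeabilityResult",
    "TeerRecord",
    "teer_value",
    "cumulative_mass",
    "apparent_permeability",
    "efflux_ratio",
    "mass_balance",
    "dose_solution_concentration",
    "read_transport_csv",
    "write_transport_csv",
]

#: 12-well Transwell insert membrane area, cm^2
DEFAULT_AREA = 1.12


@dataclass
class TransportExperiment:
    """One monolayer flux run.

    ``times`` in minutes; receiver concentrations in ug/mL as measured at
    each withdrawal (before replacement with fresh medium); donor endpoint
    concentrations at t=0 and the final time support the mass balance.
    """

    direction: Literal["A->B", "B->A"]
    c0: float                         # donor concentration at t=0, ug/mL
    donor_volume: float               # mL
    receiver_volume: float            # mL
    sample_volume: float              # mL withdrawn per receiver sample
    times: np.ndarray                 # min
    receiver_concentrations: np.ndarray  # ug/mL
    area: float = DEFAULT_AREA        # cm^2
    donor_conc_t0: Optional[float] = None
    donor_conc_end: Optional[float] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.receiver_concentrations = np.asarray(
            self.receiver_concentrations, dtype=float
        )
        if self.direction not in ("A->B", "B->A"):
            raise ValueError("direction must be 'A->B' or 'B->A'")
        if self.c0 <= 0 or self.area <= 0:
            raise ValueError("c0 and area must be > 0")
        if min(self.donor_volume, self.receiver_volume) <= 0:
            raise ValueError("volumes must be > 0")
        if not (0 <= self.sample_volume < self.receiver_volume):
            raise ValueError("require 0 <= sample_volume < receiver_volume")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.receiver_concentrations < 0):
            raise ValueError("receiver concentrations must be >= 0")
        if self.times.shape != self.receiver_concentrations.shape:
            raise ValueError("times and receiver_concentrations must align")


@dataclass(frozen=True)
class PermeabilityResult:
    papp: float                 # cm/s
    papp_sd: float              # cm/s, from the slope standard error
    linear_window: tuple[int, int]  # [start, stop) indices into times
    r2: float
    mass_balance: Optional[float] = None
    flagged: bool = False       # r2 < 0.9 on the best window


@dataclass(frozen=True)
class TeerRecord:
    raw_resistance: float       # ohm
    blank_resistance: float     # ohm
    area: float                 # cm^2

    @property
    def teer(self) -> float:
        return teer_value(self.raw_resistance, self.blank_resistance, self.area)


def teer_value(raw: float, blank: float, area: float) -> float:
    """TEER = (resistance - blank resistance) * membrane area, ohm*cm^2."""
    if area <= 0:
        raise ValueError("area must be > 0")
    value = (raw - blank) * area
    if value < 0:
        warnings.warn(
            f"raw resistance {raw} below blank {blank}: monolayer QC failure",
            stacklevel=2,
        )
    return value


def cumulative_mass(
    receiver_concentrations: Sequence[float],
    receiver_volume: float,
    sample_volume: float,
) -> np.ndarray:
    """Cumulative transferred mass (ug), corrected for sampling withdrawal.

    M_n = C_n * V_r + v_s * sum_{i<n} C_i. Each withdrawn sample removes
    analyte that would otherwise remain in the receiver, so earlier
    concentrations are added back scaled by the sample volume.
    """
    conc = np.asarray(receiver_concentrations, dtype=float)
    if np.any(conc < 0):
        raise ValueError("negative receiver concentration")
    if not (0 <= sample_volume < receiver_volume):
        raise ValueError("require 0 <= sample_volume < receiver_volume")
    withdrawn = np.zeros_like(conc)
    withdrawn[1:] = sample_volume * np.cumsum(conc[:-1])
    return conc * receiver_volume + withdrawn


def _fit_window(times_min: np.ndarray, masses: np.ndarray,
                i0: int, i1: int) -> tuple[float, float, float]:
    """Slope (ug/min), its SE, and r^2 of the linear-window flux fit.

    The cumulative curve passes through the origin by construction and the
    assay error is multiplicative (constant CV), so the efficient estimator
    is the relative-variance-weighted through-origin slope, i.e. the mean of
    the per-point rates m_i/t_i. r^2 is reported for the fitted line against
    the measured masses as the linearity diagnostic.
    """
    t = times_min[i0:i1]
    m = masses[i0:i1]
    rates = m / t
    slope = float(np.mean(rates))
    se = float(np.std(rates, ddof=1) / np.sqrt(len(rates))) if len(rates) > 1 else 0.0
    ss_res = float(np.sum((m - slope * t) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return slope, se, r2


def apparent_permeability(
    exp: TransportExperiment,
    window: Literal["auto", "sink", "all"] = "auto",
) -> PermeabilityResult:
    """Papp (cm/s) from the linear window of the cumulative-mass curve.

    The ``sink`` window keeps points while cumulative receiver mass is
    below 10% of the initial donor mass (sink conditions guaranteed); the
    default ``auto`` window starts there and extends forward while the
    curve remains linear (window r^2 does not degrade), since the linear
    portion often outlasts the nominal sink bound. If fewer than 3 sink
    points qualify, the best-r^2 contiguous window of >= 4 points is used.
    dQ/dt is the weighted through-origin slope of the window (see
    ``_fit_window``); units: ug/min -> ug/s, then / (C0 [ug/mL=ug/cm^3] *
    A [cm^2]) -> cm/s.
    """
    if len(exp.times) < 3:
        raise ValueError("need at least 3 time points")
    masses = cumulative_mass(
        exp.receiver_concentrations, exp.receiver_volume, exp.sample_volume
    )
    if np.allclose(masses, 0.0):
        return PermeabilityResult(0.0, 0.0, (0, len(masses)), 1.0)
    donor_mass0 = exp.c0 * exp.donor_volume
    n = len(masses)
    if window == "all":
        i0, i1 = 0, n
        slope, se, r2 = _fit_window(exp.times, masses, i0, i1)
    else:
        sink = masses < 0.10 * donor_mass0
        stop = int(np.argmin(sink)) if not sink.all() else n
        if window == "sink" or stop >= 3:
            i0, i1 = 0, max(stop, 3)
            slope, se, r2 = _fit_window(exp.times, masses, i0, i1)
            if window == "auto":
                # extend past the nominal sink bound while linearity holds
                while i1 < n:
                    s_ext, e_ext, r_ext = _fit_window(exp.times, masses, i0, i1 + 1)
                    if r_ext < min(0.98, r2 - 2e-3):
                        break
                    slope, se, r2 = s_ext, e_ext, r_ext
                    i1 += 1
        else:
            # fallback: best-r^2 contiguous window of >= 4 points
            best = (0, min(4, n), -np.inf, 0.0, 0.0)
            for a in range(0, n - 3):
                for b in range(a + 4, n + 1):
                    s, e, r = _fit_window(exp.times, masses, a, b)
                    if r > best[2]:
                        best = (a, b, r, s, e)
            i0, i1, r2, slope, se = best
    papp = (slope / 60.0) / (exp.c0 * exp.area)
    papp_sd = (se / 60.0) / (exp.c0 * exp.area)
    return PermeabilityResult(
        papp=max(papp, 0.0),
        papp_sd=papp_sd,
        linear_window=(i0, i1),
        r2=r2,
        flagged=bool(r2 < 0.9),
    )


def efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """Papp(B->A) / Papp(A->B); >> 1 indicates apically directed efflux."""
    if papp_ab <= 0:
        raise ValueError("papp_ab must be > 0")
    if papp_ba < 0:
        raise ValueError("papp_ba must be >= 0")
    return papp_ba / papp_ab


def mass_balance(
    exp: TransportExperiment,
    receiver_masses: Optional[Sequence[float]] = None,
) -> float:
    """Recovered fraction of the initial donor mass at the final time point.

    (donor mass at end + receiver mass at end + mass withdrawn in receiver
    samples) / donor mass at t=0. Values well below 1 indicate cellular
    retention or nonspecific binding.
    """
    if exp.donor_conc_t0 is None or exp.donor_conc_end is None:
        raise ValueError("donor endpoint concentrations are required")
    conc = exp.receiver_concentrations
    if receiver_masses is None:
        receiver_masses = cumulative_mass(
            conc, exp.receiver_volume, exp.sample_volume
        )
    donor0 = exp.donor_conc_t0 * exp.donor_volume
    donor_end = exp.donor_conc_end * exp.donor_volume
    # receiver content at end + everything previously withdrawn
    withdrawn = exp.sample_volume * float(np.sum(conc[:-1]))
    receiver_end = float(conc[-1]) * exp.receiver_volume
    return (donor_end + receiver_end + withdrawn) / donor0


def dose_solution_concentration(dose: float, volume: float) -> float:
    """Donor concentration (ug/mL) of ``dose`` mg dissolved in ``volume`` mL."""
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    return dose * 1000.0 / volume


# ---------------------------------------------------------------------------
# CSV IO


def write_transport_csv(exp: TransportExperiment, path: str) -> None:
    df = pd.DataFrame(
        {"time_min": exp.times, "receiver_conc": exp.receiver_concentrations}
    )
    df["direction"] = exp.direction
    df["c0"] = exp.c0
    df["area"] = exp.area
    df["donor_volume"] = exp.donor_volume
    df["receiver_volume"] = exp.receiver_volume
    df["sample_volume"] = exp.sample_volume
    df["donor_conc_t0"] = exp.donor_conc_t0
    df["donor_conc_end"] = exp.donor_conc_end
    df["label"] = exp.label
    df.to_csv(path, index=False)


def read_transport_csv(path: str) -> TransportExperiment:
    df = pd.read_csv(path)
    first = df.iloc[0]
    donor_t0 = first.get("donor_conc_t0")
    donor_end = first.get("donor_conc_end")
    return TransportExperiment(
        direction=str(first["direction"]),
        c0=float(first["c0"]),
        donor_volume=float(first["donor_volume"]),
        receiver_volume=float(first["receiver_volume"]),
        sample_volume=float(first["sample_volume"]),
        times=df["time_min"].to_numpy(float),
        receiver_concentrations=df["receiver_conc"].to_numpy(float),
        area=float(first.get("area", DEFAULT_AREA)),
        donor_conc_t0=None if pd.isna(donor_t0) else float(donor_t0),
        donor_conc_end=None if pd.isna(donor_end) else float(donor_end),
        label=str(first.get("label", "")),
    )
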
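"""Dissolution profiles: sampling correction, f1/f2 similarity, release models.

The regulatory difference factor f1 and similarity factor f2 compare a test
formulation's dissolution profile against a reference:

    f1 = 100 * sum(|R_t - T_t|) / sum(R_t)
    f2 = 50 * log10(100 / sqrt(1 + mean((R_t - T_t)^2)))

Profiles are declared similar when f1 < 15 and f2 > 50; when both products
release more than 85% of dose within 15 minutes the comparison is waived
(rapidly dissolving products).

A fitted :class:`ReleaseModel` (Weibull, first-order, or tabulated) turns a
measured profile into the release-rate input of the gut absorption model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

__all__ = [
    "DissolutionProfile",
    "ReleaseModel",
    "SimilarityResult",
    "correct_cumulative",
    "f1_factor",
    "f2_factor",
    "similarity_verdict",
    "fit_release_model",
    "fraction_dissolved",
    "release_hazard",
    "read_profiles_csv",
    "write_profiles_csv",
]

MEDIA = ("FaSSIF", "FeSSIF", "FaSSGF", "custom")

#: scheduled sampling grid of the 2 h paddle-apparatus protocol, minutes
DEFAULT_TIMES = np.array([2.0, 5.0, 10.0, 15.0, 20.0, 30.0, 45.0, 60.0, 90.0, 120.0])


@dataclass
class DissolutionProfile:
    """Percent of dose dissolved over time, one row per replicate."""

    times: np.ndarray                # min, strictly increasing, first > 0
    percent_dissolved: np.ndarray    # shape (n_replicates, n_times), % of dose
    medium: str = "FaSSIF"
    label: str = ""
    dose: float = 5.0                # mg
    vessel_volume: float = 900.0     # mL

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        pct = np.asarray(self.percent_dissolved, dtype=float)
        if pct.ndim == 1:
            pct = pct[np.newaxis, :]
        self.percent_dissolved = pct
        if self.medium not in MEDIA:
            raise ValueError(f"medium must be one of {MEDIA}")
        if self.times.ndim != 1 or len(self.times) < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if self.times[0] <= 0:
            raise ValueError("first sampling time must be > 0")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if pct.shape[1] != len(self.times):
            raise ValueError("percent_dissolved columns must match times")
        if np.any(pct < 0) or np.any(pct > 115):
            raise ValueError("percent dissolved must lie in [0, 115]")

    @property
    def n_replicates(self) -> int:
        return self.percent_dissolved.shape[0]

    @property
    def means(self) -> np.ndarray:
        return self.percent_dissolved.mean(axis=0)

    @property
    def sds(self) -> np.ndarray:
        return self.percent_dissolved.std(axis=0, ddof=1)


@dataclass
class ReleaseModel:
    """Parametric or tabulated description of the release time course.

    ``plateau`` is the asymptotic percent of dose released in vitro; ``td``
    the Weibull time scale (min); ``beta`` the shape (beta = 1 recovers
    first-order release). The tabulated family carries the monotonized
    mean profile and interpolates it piecewise-linearly, clamping to the
    plateau beyond the last observation.
    """

    family: Literal["weibull", "first-order", "tabulated"]
    plateau: float
    td: float = float("nan")
    beta: float = float("nan")
    residual_sse: float = 0.0
    times: Optional[np.ndarray] = None     # tabulated only
    values: Optional[np.ndarray] = None    # tabulated only, % of dose

    def __post_init__(self) -> None:
        if self.family in ("weibull", "first-order"):
            if not (self.plateau > 0 and self.td > 0 and self.beta > 0):
                raise ValueError("plateau, td, beta must be > 0")
            if self.family == "first-order" and abs(self.beta - 1.0) > 1e-12:
                raise ValueError("first-order release requires beta = 1")
        elif self.family == "tabulated":
            if self.times is None or self.values is None:
                raise ValueError("tabulated family requires times and values")
            self.times = np.asarray(self.times, dtype=float)
            self.values = np.maximum.accumulate(np.asarray(self.values, dtype=float))
            self.plateau = float(self.values[-1])
            if self.plateau <= 0:
                raise ValueError("tabulated plateau must be > 0")
        else:
            raise ValueError(f"unknown family {self.family!r}")

    def to_dict(self) -> dict:
        d = {"family": self.family, "plateau": float(self.plateau),
             "residual_sse": float(self.residual_sse)}
        if self.family == "tabulated":
            d["times"] = [float(t) for t in self.times]
            d["values"] = [float(v) for v in self.values]
        else:
            d["td"] = float(self.td)
            d["beta"] = float(self.beta)
        return d

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str) -> "ReleaseModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass(frozen=True)
class SimilarityResult:
    f1: float
    f2: float
    n_points: int
    rapid_both: bool
    verdict: Literal["pass", "fail", "waived"]
    included_times: tuple[float, ...] = ()


def correct_cumulative(
    raw_concentrations: Sequence[float],
    sample_volume: float,
    vessel_volume: float,
    dose: float,
    times: Optional[Sequence[float]] = None,
    medium: str = "custom",
    label: str = "",
) -> DissolutionProfile:
    """Convert sampled concentrations to cumulative percent of dose dissolved.

    Each withdrawal removes ``sample_volume`` mL of medium (replaced with
    fresh), so analyte already withdrawn must be added back:

        M_n = C_n * V + v_s * sum_{i<n} C_i    [ug]

    with concentrations in ug/mL and volumes in mL; the result is expressed
    as % of the ``dose`` (mg).
    """
    conc = np.asarray(raw_concentrations, dtype=float)
    if conc.ndim == 1:
        conc = conc[np.newaxis, :]
    if np.any(conc < 0):
        bad = int(np.argwhere(conc < 0)[0][1])
        raise ValueError(f"negative concentration at time index {bad}")
    if not (0 <= sample_volume < vessel_volume):
        raise ValueError("require 0 <= sample_volume < vessel_volume")
    if dose <= 0:
        raise ValueError("dose must be > 0")
    withdrawn = np.zeros_like(conc)
    withdrawn[:, 1:] = sample_volume * np.cumsum(conc[:, :-1], axis=1)
    masses_ug = conc * vessel_volume + withdrawn
    percent = masses_ug / (dose * 1000.0) * 100.0
    if times is None:
        times = DEFAULT_TIMES[: conc.shape[1]]
    return DissolutionProfile(
        times=np.asarray(times, dtype=float),
        percent_dissolved=percent,
        medium=medium,
        label=label,
        dose=dose,
        vessel_volume=vessel_volume,
    )


def _check_grids(reference: np.ndarray, test: np.ndarray) -> None:
    if reference.shape != test.shape:
        raise ValueError("reference and test must share a common time grid")


def f1_factor(reference: Sequence[float], test: Sequence[float]) -> float:
    """Difference factor f1 on mean profiles sharing a time grid."""
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    _check_grids(r, t)
    denom = r.sum()
    if denom <= 0:
        raise ValueError("sum of reference values must be > 0")
    return float(np.abs(r - t).sum() / denom * 100.0)


def f2_factor(reference: Sequence[float], test: Sequence[float]) -> float:
    """Similarity factor f2 on mean profiles sharing a time grid."""
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    _check_grids(r, t)
    msd = float(np.mean((r - t) ** 2))
    return float(50.0 * math.log10(100.0 / math.sqrt(1.0 + msd)))


def _select_points(
    times: np.ndarray, ref: np.ndarray, test: np.ndarray, apply_85_rule: bool
) -> np.ndarray:
    """Indices of time points included in the comparison.

    Regulatory convention: use the scheduled points up to (and including) the
    first point at which both products exceed 85% dissolved; later points
    carry no discriminating information once both curves have plateaued.
    """
    idx = np.arange(len(times))
    if not apply_85_rule:
        return idx
    both85 = (ref > 85.0) & (test > 85.0)
    if both85.any():
        first = int(np.argmax(both85))
        return idx[: first + 1]
    return idx


def verdict_from_factors(
    f1: float, f2: float, rapid_both: bool = False
) -> Literal["pass", "fail", "waived"]:
    """Decision rule applied to already-computed (f1, f2) factors.

    ``waived`` when both products are rapidly dissolving (>85% within
    15 min), else ``pass`` iff f1 < 15 and f2 > 50.
    """
    if rapid_both:
        return "waived"
    return "pass" if (f1 < 15.0 and f2 > 50.0) else "fail"


def similarity_verdict(
    reference: DissolutionProfile,
    test: DissolutionProfile,
    apply_85_rule: bool = True,
) -> SimilarityResult:
    """f1/f2 comparison with the biowaiver and pass/fail decision rules.

    Verdict is ``waived`` when both mean profiles exceed 85% of dose within
    15 min (rapidly dissolving; f1/f2 still reported), otherwise ``pass``
    iff f1 < 15 and f2 > 50. Computed on replicate means.
    """
    if not np.array_equal(reference.times, test.times):
        raise ValueError(
            "profiles are on different time grids; f1/f2 are grid-sensitive "
            "and no interpolation is performed"
        )
    r_mean, t_mean = reference.means, test.means
    early = reference.times <= 15.0
    rapid_both = bool(
        early.any()
        and (r_mean[early] > 85.0).any()
        and (t_mean[early] > 85.0).any()
    )
    idx = _select_points(reference.times, r_mean, t_mean, apply_85_rule)
    if len(idx) < 3:
        raise ValueError(
            f"only {len(idx)} usable common time points; need at least 3"
        )
    f1 = f1_factor(r_mean[idx], t_mean[idx])
    f2 = f2_factor(r_mean[idx], t_mean[idx])
    verdict = verdict_from_factors(f1, f2, rapid_both)
    return SimilarityResult(
        f1=f1,
        f2=f2,
        n_points=len(idx),
        rapid_both=rapid_both,
        verdict=verdict,
        included_times=tuple(float(t) for t in reference.times[idx]),
    )


# ---------------------------------------------------------------------------
# Release models


def _weibull(t, plateau, td, beta):
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = plateau * (1.0 - np.exp(-((t[pos] / td) ** beta)))
    return out


def fit_release_model(
    profile: DissolutionProfile,
    family: Literal["weibull", "first-order", "tabulated"] = "weibull",
) -> ReleaseModel:
    """Least-squares fit of a release model to the replicate-mean profile."""
    t = profile.times
    y = profile.means
    if family == "tabulated":
        return ReleaseModel(family="tabulated", plateau=float(np.max(y)),
                            times=t.copy(), values=y.copy())
    if len(t) < 4:
        raise ValueError("need at least 4 time points for a parametric fit")
    plateau0 = max(float(y.max()), 1.0)
    half = plateau0 / 2.0
    above = np.nonzero(y >= half)[0]
    td0 = float(t[above[0]]) if len(above) else float(t[len(t) // 2])
    try:
        if family == "weibull":
            popt, _ = curve_fit(
                _weibull, t, y, p0=[plateau0, td0, 1.0],
                bounds=([1e-6, 1e-6, 0.05], [150.0, 1e4, 10.0]),
                maxfev=20000,
            )
            plateau, td, beta = popt
        elif family == "first-order":
            popt, _ = curve_fit(
                lambda tt, plateau, td: _weibull(tt, plateau, td, 1.0),
                t, y, p0=[plateau0, td0],
                bounds=([1e-6, 1e-6], [150.0, 1e4]), maxfev=20000,
            )
            plateau, td = popt
            beta = 1.0
        else:
            raise ValueError(f"unknown family {family!r}")
    except RuntimeError as err:
        raise RuntimeError(f"release-model fit did not converge: {err}") from err
    sse = float(np.sum((y - _weibull(t, plateau, td, beta)) ** 2))
    return ReleaseModel(family=family, plateau=float(plateau), td=float(td),
                        beta=float(beta), residual_sse=sse)


def fraction_dissolved(model: ReleaseModel, t: float) -> float:
    """In vitro fraction of dose dissolved at time ``t`` (min), in [0, plateau/100]."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if model.family == "tabulated":
        if t <= 0:
            return 0.0
        v = float(np.interp(t, model.times, model.values,
                            left=0.0, right=model.plateau))
        return v / 100.0
    return float(_weibull(np.array([t]), model.plateau, model.td, model.beta)[0]) / 100.0


def release_hazard(model: ReleaseModel, t: float, hazard_cap: float = 100.0) -> float:
    """Instantaneous release hazard (1/h) of remaining solid at time ``t`` (h).

    The in vivo release kinetics follow the *normalized* in vitro profile
    F(t)/F_inf (the in vitro plateau reflects the closed-vessel assay, not an
    unreleasable fraction), so remaining solid dissolves with hazard
    h(t) = f_n(t) / (1 - F_n(t)). For the Weibull family this is the closed
    form (beta/td) * (t/td)^(beta-1); for tabulated profiles it is evaluated
    by finite differences of the normalized curve. Capped at ``hazard_cap``
    to keep the ODE system well-posed at t -> 0 for beta < 1.
    """
    t_min = t * 60.0  # model time in h, release curves in min
    if model.family in ("weibull", "first-order"):
        if t_min <= 0:
            h_per_min = (model.beta / model.td) if model.beta <= 1 else 0.0
            if model.beta < 1:
                h_per_min = hazard_cap / 60.0
        else:
            h_per_min = (model.beta / model.td) * (t_min / model.td) ** (model.beta - 1.0)
    else:
        eps = 1e-3
        fn0 = np.interp(t_min, model.times, model.values, left=0.0,
                        right=model.plateau) / model.plateau
        fn1 = np.interp(t_min + eps, model.times, model.values, left=0.0,
                        right=model.plateau) / model.plateau
        surv = max(1.0 - fn0, 1e-12)
        h_per_min = (fn1 - fn0) / eps / surv
    return float(min(h_per_min * 60.0, hazard_cap))


# ---------------------------------------------------------------------------
# CSV IO (long format: label, medium, replicate, time_min, percent)


def write_profiles_csv(profiles: Sequence[DissolutionProfile], path: str) -> None:
    rows = []
    for p in profiles:
        for rep in range(p.n_replicates):
            for t, v in zip(p.times, p.percent_dissolved[rep]):
                rows.append(
                    {"label": p.label, "medium": p.medium, "replicate": rep + 1,
                     "time_min": t, "percent": v, "dose_mg": p.dose,
                     "vessel_volume_ml": p.vessel_volume}
                )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_profiles_csv(path: str) -> list[DissolutionProfile]:
    df = pd.read_csv(path)
    out = []
    for (label, medium), grp in df.groupby(["label", "medium"], sort=False):
        piv = grp.pivot_table(index="replicate", columns="time_min",
                              values="percent").sort_index()
        times = np.asarray(piv.columns, dtype=float)
        out.append(
            DissolutionProfile(
                times=times,
                percent_dissolved=piv.to_numpy(),
                medium=str(medium),
                label=str(label),
                dose=float(grp["dose_mg"].iloc[0]) if "dose_mg" in grp else 5.0,
                vessel_volume=float(grp["vessel_volume_ml"].iloc[0])
                if "vessel_volume_ml" in grp else 900.0,
            )
        )
    return out
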
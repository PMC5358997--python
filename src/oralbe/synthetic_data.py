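"""Synthetic study-data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:
Weibull-shaped dissolution curves reaching the plateaus observed for the
amlodipine/atorvastatin single and fixed-dose-combination formulations,
linear-phase Caco-2 monolayer transport with receiver sampling and
replacement, single-dose oral plasma profiles with log-normal
between-subject variability, and virtual populations.

Each generator consumes a single integer seed and derives a named,
independent stream from it, so modules can be tested in isolation and the
same seed reproduces every table bit-for-bit.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .caco2 import TransportExperiment
from .compound import CompoundProfile
from .dissolution import DEFAULT_TIMES, DissolutionProfile, ReleaseModel
from .gut_absorption import DoseEvent
from .trial_engine import SubjectParameters, TrialDesign, simulate_subject

__all__ = [
    "DissolutionTruth",
    "TransportTruth",
    "PlasmaTruth",
    "PopulationCV",
    "gen_dissolution",
    "gen_transport",
    "gen_plasma",
    "gen_population",
    "DISSOLUTION_PRESETS",
    "TRANSPORT_PRESETS",
    "dissolution_preset",
    "release_model_for",
    "dose_event_for",
    "write_truth_yaml",
]

logger = logging.getLogger(__name__)

#: default transport sampling grid, minutes
TRANSPORT_TIMES = np.array([15.0, 30.0, 45.0, 60.0, 90.0, 120.0])


def _stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG stream derived from one integer seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF,
                                  zlib.crc32(name.encode()) & 0x7FFFFFFF])


# ---------------------------------------------------------------------------
# Dissolution


@dataclass(frozen=True)
class DissolutionTruth:
    """Ground truth of a Weibull release curve.

    plateau_percent: asymptotic % of dose; weibull_td min; weibull_beta
    dimensionless; noise_sd additive Gaussian noise in % of dose (truncated
    at 0); sampling grid in minutes.
    """

    plateau_percent: float
    weibull_td: float
    weibull_beta: float = 1.0
    noise_sd: float = 1.5
    n_replicates: int = 3
    sampling_times: tuple[float, ...] = tuple(DEFAULT_TIMES)
    medium: str = "custom"
    label: str = ""
    dose: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.plateau_percent <= 110):
            raise ValueError("plateau_percent must be in (0, 110]")
        if self.weibull_td <= 0 or self.weibull_beta <= 0:
            raise ValueError("weibull_td and weibull_beta must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        t = np.asarray(self.sampling_times, dtype=float)
        if t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be strictly increasing, first > 0")

    def mean_curve(self, times: Optional[np.ndarray] = None) -> np.ndarray:
        t = np.asarray(self.sampling_times if times is None else times, float)
        return self.plateau_percent * (
            1.0 - np.exp(-((t / self.weibull_td) ** self.weibull_beta))
        )

    def release_model(self) -> ReleaseModel:
        family = "first-order" if self.weibull_beta == 1.0 else "weibull"
        return ReleaseModel(family=family, plateau=self.plateau_percent,
                            td=self.weibull_td, beta=self.weibull_beta)


def gen_dissolution(truth: DissolutionTruth, seed: int = 0) -> DissolutionProfile:
    """Noisy replicate dissolution curves around the true Weibull mean."""
    rng = _stream(seed, f"dissolution:{truth.label}:{truth.medium}")
    mean = truth.mean_curve()
    noise = rng.normal(0.0, truth.noise_sd,
                       size=(truth.n_replicates, len(mean))) if truth.noise_sd > 0 \
        else np.zeros((truth.n_replicates, len(mean)))
    pct = np.maximum(mean[np.newaxis, :] + noise, 0.0)
    return DissolutionProfile(
        times=np.asarray(truth.sampling_times, float),
        percent_dissolved=pct,
        medium=truth.medium if truth.medium in
        ("FaSSIF", "FeSSIF", "FaSSGF") else "custom",
        label=truth.label,
        dose=truth.dose,
    )


# Preset release curves for the two drugs x two media x two formulations.
# Plateaus are the observed in vitro values; Weibull time scales are chosen
# so the fasted-state curves are rapid (amlodipine >50% at 5 min, >85% at
# 15 min for both formulations) and the fed-state curves markedly slower,
# with single/FDC kinetics close enough to pass f1/f2 for atorvastatin and
# different enough to fail for amlodipine in FeSSIF.
DISSOLUTION_PRESETS: dict[str, DissolutionTruth] = {
    "amlodipine-FaSSIF-single": DissolutionTruth(94.9, 4.0, medium="FaSSIF",
                                                 label="amlodipine-single", dose=5.0),
    "amlodipine-FaSSIF-FDC": DissolutionTruth(101.2, 5.0, medium="FaSSIF",
                                              label="amlodipine-FDC", dose=5.0),
    "amlodipine-FeSSIF-single": DissolutionTruth(87.9, 25.0, medium="FeSSIF",
                                                 label="amlodipine-single", dose=5.0),
    "amlodipine-FeSSIF-FDC": DissolutionTruth(79.9, 45.0, medium="FeSSIF",
                                              label="amlodipine-FDC", dose=5.0),
    "atorvastatin-FaSSIF-single": DissolutionTruth(80.0, 6.0, medium="FaSSIF",
                                                   label="atorvastatin-single", dose=10.0),
    "atorvastatin-FaSSIF-FDC": DissolutionTruth(89.3, 5.5, medium="FaSSIF",
                                                label="atorvastatin-FDC", dose=10.0),
    "atorvastatin-FeSSIF-single": DissolutionTruth(76.9, 41.0, medium="FeSSIF",
                                                   label="atorvastatin-single", dose=10.0),
    "atorvastatin-FeSSIF-FDC": DissolutionTruth(86.2, 40.0, medium="FeSSIF",
                                                label="atorvastatin-FDC", dose=10.0),
}


def dissolution_preset(name: str) -> DissolutionTruth:
    try:
        return DISSOLUTION_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(DISSOLUTION_PRESETS)}"
        ) from None


def release_model_for(drug: str, medium: str, formulation: str) -> ReleaseModel:
    """Release model of a bundled preset, e.g. ('amlodipine','FaSSIF','single')."""
    return dissolution_preset(f"{drug}-{medium}-{formulation}").release_model()


def dose_event_for(
    compound: CompoundProfile, formulation: str = "single",
    dose: Optional[float] = None,
) -> DoseEvent:
    """DoseEvent wired to the bundled in vitro release presets for a drug."""
    default_dose = {"amlodipine": 5.0, "atorvastatin": 10.0}
    return DoseEvent(
        compound=compound,
        dose=dose if dose is not None else default_dose[compound.name],
        formulation=formulation,
        release={
            "FaSSIF": release_model_for(compound.name, "FaSSIF", formulation),
            "FeSSIF": release_model_for(compound.name, "FeSSIF", formulation),
        },
    )


# ---------------------------------------------------------------------------
# Transport


@dataclass(frozen=True)
class TransportTruth:
    """Ground truth of one sink-condition monolayer flux run.

    papp_true cm/s; c0 ug/mL; area cm^2; volumes mL; sampling minutes;
    noise_cv multiplicative CV on the measured receiver concentrations;
    retained_fraction diverts that share of transported drug into the cells
    (reducing receiver appearance; used for mass-balance fixtures).
    """

    papp_true: float
    c0: float = 20.0
    area: float = 1.12
    donor_volume: float = 0.5
    receiver_volume: float = 1.5
    sample_volume: float = 0.2
    sampling_times: tuple[float, ...] = tuple(TRANSPORT_TIMES)
    noise_cv: float = 0.0
    retained_fraction: float = 0.0
    direction: str = "A->B"
    label: str = ""

    def __post_init__(self) -> None:
        if self.papp_true < 0:
            raise ValueError("papp_true must be >= 0")
        if min(self.c0, self.area, self.donor_volume, self.receiver_volume) <= 0:
            raise ValueError("c0, area and volumes must be > 0")
        if not (0 <= self.sample_volume < self.receiver_volume):
            raise ValueError("require 0 <= sample_volume < receiver_volume")
        if not (0 <= self.retained_fraction < 1):
            raise ValueError("retained_fraction must be in [0, 1)")
        t = np.asarray(self.sampling_times, float)
        if np.any(np.diff(t) <= 0) or t[0] <= 0:
            raise ValueError("sampling_times must be strictly increasing, first > 0")


TRANSPORT_PRESETS: dict[str, TransportTruth] = {
    "amlodipine-AB": TransportTruth(8.34e-6, c0=20.0, direction="A->B",
                                    donor_volume=0.5, receiver_volume=1.5,
                                    sample_volume=0.2, label="amlodipine"),
    "amlodipine-BA": TransportTruth(9.51e-6, c0=20.0, direction="B->A",
                                    donor_volume=1.5, receiver_volume=0.5,
                                    sample_volume=0.1, label="amlodipine"),
    "atorvastatin-AB": TransportTruth(2.03e-6, c0=40.0, direction="A->B",
                                      donor_volume=0.5, receiver_volume=1.5,
                                      sample_volume=0.2, label="atorvastatin"),
    "atorvastatin-BA": TransportTruth(10.18e-6, c0=40.0, direction="B->A",
                                      donor_volume=1.5, receiver_volume=0.5,
                                      sample_volume=0.1, label="atorvastatin"),
}


def gen_transport(truth: TransportTruth, seed: int = 0) -> TransportExperiment:
    """Simulate a sink-regime flux run with withdrawal/replacement sampling.

    Transferred mass grows linearly at J = Papp * C0 * A (ug/s); each
    sampling withdraws ``sample_volume`` from the receiver and replaces it
    with fresh medium, diluting subsequent measurements exactly as in the
    bench protocol. A noiseless run round-trips through the permeability
    analysis to ``papp_true`` up to solver-free arithmetic.
    """
    t = np.asarray(truth.sampling_times, float)
    if t[-1] > 120.0 + 1e-9:
        logger.warning("sampling extends beyond the 2 h window (t_max=%.0f min)", t[-1])
    rng = _stream(seed, f"transport:{truth.label}:{truth.direction}")
    flux_ug_min = truth.papp_true * truth.c0 * truth.area * 60.0
    flux_receiver = flux_ug_min * (1.0 - truth.retained_fraction)
    content = 0.0  # ug presently in the receiver
    conc = np.empty_like(t)
    prev_t = 0.0
    for i, ti in enumerate(t):
        content += flux_receiver * (ti - prev_t)
        c = content / truth.receiver_volume
        if truth.noise_cv > 0:
            c *= rng.lognormal(0.0, truth.noise_cv)
        conc[i] = c
        # withdrawal of the *measured* medium, replacement with fresh
        content -= (content / truth.receiver_volume) * truth.sample_volume
        prev_t = ti
    donor_loss = flux_ug_min * t[-1] / truth.donor_volume
    return TransportExperiment(
        direction=truth.direction,  # type: ignore[arg-type]
        c0=truth.c0,
        donor_volume=truth.donor_volume,
        receiver_volume=truth.receiver_volume,
        sample_volume=truth.sample_volume,
        times=t,
        receiver_concentrations=conc,
        area=truth.area,
        donor_conc_t0=truth.c0,
        donor_conc_end=max(truth.c0 - donor_loss, 0.0),
        label=truth.label,
    )


# ---------------------------------------------------------------------------
# Populations and plasma


@dataclass(frozen=True)
class PopulationCV:
    """Log-normal coefficients of variation of the population multipliers."""

    cv_cl: float = 0.3
    cv_vss: float = 0.3
    cv_gut_cyp: float = 0.4
    cv_liver_cyp: float = 0.4

    def __post_init__(self) -> None:
        for name in ("cv_cl", "cv_vss", "cv_gut_cyp", "cv_liver_cyp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _lognormal_mean1(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Log-normal draws with arithmetic mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=n)


def gen_population(
    n: int,
    cv_set: Optional[PopulationCV | dict] = None,
    seed: int = 0,
    body_weight: float = 70.0,
) -> list[SubjectParameters]:
    """Draw a virtual population of exchangeable multiplier sets."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if cv_set is None:
        cv_set = PopulationCV()
    elif isinstance(cv_set, dict):
        cv_set = PopulationCV(**cv_set)
    rng = _stream(seed, "population")
    cl = _lognormal_mean1(rng, cv_set.cv_cl, n)
    vss = _lognormal_mean1(rng, cv_set.cv_vss, n)
    gut = _lognormal_mean1(rng, cv_set.cv_gut_cyp, n)
    liver = _lognormal_mean1(rng, cv_set.cv_liver_cyp, n)
    return [
        SubjectParameters(
            subject_id=f"S{i + 1:04d}",
            body_weight=body_weight,
            cl_multiplier=float(cl[i]),
            vss_multiplier=float(vss[i]),
            gut_cyp_multiplier=float(gut[i]),
            liver_cyp_multiplier=float(liver[i]),
            seed=seed,
        )
        for i in range(n)
    ]


@dataclass(frozen=True)
class PlasmaTruth:
    """Ground truth for synthetic single-dose oral plasma tables."""

    compound: CompoundProfile
    dose_mg: float
    n_subjects: int = 12
    cv_cl: float = 0.3
    cv_vss: float = 0.3
    residual_cv: float = 0.1
    prandial_state: str = "fasted"
    formulation: str = "single"
    duration: float = 24.0
    sampling_times: tuple[float, ...] = (
        0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in ("cv_cl", "cv_vss", "residual_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_plasma(truth: PlasmaTruth) -> pd.DataFrame:
    """Per-subject observed plasma tables from the forward trial simulation.

    Between-subject variability enters through log-normal CL and Vss
    multipliers; assay error is multiplicative log-normal with the given
    residual CV. Columns: subject, time_h, conc_ng_ml, plus the per-subject
    true multipliers for round-trip checks.
    """
    rng = _stream(truth.seed, "plasma-residual")
    pop_rng = _stream(truth.seed, "plasma-population")
    cl = _lognormal_mean1(pop_rng, truth.cv_cl, truth.n_subjects)
    vss = _lognormal_mean1(pop_rng, truth.cv_vss, truth.n_subjects)
    dose_event = dose_event_for(truth.compound, truth.formulation, truth.dose_mg)
    frames = []
    for i in range(truth.n_subjects):
        subject = SubjectParameters(
            subject_id=f"S{i + 1:04d}",
            cl_multiplier=float(cl[i]),
            vss_multiplier=float(vss[i]),
        )
        design = TrialDesign(
            dose_event=dose_event,
            prandial_state=truth.prandial_state,  # type: ignore[arg-type]
            n_subjects=1,
            duration=truth.duration,
            sampling_times=np.asarray(truth.sampling_times, float),
        )
        sim = simulate_subject(design, subject)
        conc = sim.concentrations.copy()
        if truth.residual_cv > 0:
            conc *= rng.lognormal(0.0, truth.residual_cv, size=conc.shape)
        frames.append(pd.DataFrame({
            "subject": subject.subject_id,
            "time_h": sim.times,
            "conc_ng_ml": conc,
            "true_cl_multiplier": cl[i],
            "true_vss_multiplier": vss[i],
        }))
    return pd.concat(frames, ignore_index=True)


def write_truth_yaml(truth, path: str) -> None:
    """Sidecar YAML of the ground-truth parameters of any generator."""
    d = {}
    for k, v in vars(truth).items():
        if isinstance(v, CompoundProfile):
            d[k] = v.name
        elif isinstance(v, tuple):
            d[k] = [float(x) for x in v]
        elif isinstance(v, (int, float, str)):
            d[k] = v
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
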
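"""Virtual clinical trials: minimal PBPK disposition, populations, PK stats.

The systemic model couples the gut absorption model's portal input to a
well-stirred liver compartment draining into a single central compartment
(minimal PBPK). Hepatic elimination uses the unbound intrinsic clearance
back-calculated from the compound's observed oral clearance, so the model
reproduces ``CLpo = CL_h / (fa*fg*fh)`` by construction; the central volume
is Vss * body weight. Virtual populations draw log-normal, mean-1
multipliers on clearance, Vss, and gut/liver CYP3A4 abundance.

PK summaries follow bioequivalence-report conventions: geometric mean (and
geometric SD) for Cmax, median (range) for AUC and tmax; groups are
compared with an unpaired two-tailed t-test (Welch by default) plus a
geometric-mean-ratio diagnostic with 90% CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.integrate import solve_ivp

from .compound import CompoundProfile, SystemPhysiology
from .gut_absorption import (
    DoseEvent,
    GutModel,
    GutPhysiology,
    SolverOptions,
    build_physiology,
)

__all__ = [
    "SubjectParameters",
    "TrialDesign",
    "PkSummary",
    "TrialResult",
    "SubjectResult",
    "EstimationProblem",
    "ObservedDataset",
    "EstimationResult",
    "simulate_subject",
    "pk_parameters",
    "summarize_pk",
    "run_trial",
    "compare_groups",
    "estimate_parameters",
]

REFERENCE_SUBJECT_ID = "typical"


@dataclass(frozen=True)
class SubjectParameters:
    """Exchangeable per-subject multipliers (log-normal, mean 1)."""

    subject_id: str = REFERENCE_SUBJECT_ID
    body_weight: float = 70.0            # kg
    cl_multiplier: float = 1.0
    vss_multiplier: float = 1.0
    gut_cyp_multiplier: float = 1.0
    liver_cyp_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cl_multiplier", "vss_multiplier",
                     "gut_cyp_multiplier", "liver_cyp_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.body_weight <= 0:
            raise ValueError("body_weight must be > 0")


def _default_sampling() -> np.ndarray:
    return np.round(np.arange(0.0, 24.0 + 1e-9, 0.1), 6)


@dataclass
class TrialDesign:
    """One simulated trial arm: formulation x prandial state x population."""

    dose_event: DoseEvent
    prandial_state: Literal["fasted", "fed"]
    n_subjects: int = 10
    duration: float = 24.0               # h
    sampling_times: np.ndarray = field(default_factory=_default_sampling)
    seed: int = 0
    population_cv: Optional[dict] = None  # forwarded to gen_population
    physiology: Optional[GutPhysiology] = None
    system: SystemPhysiology = field(default_factory=SystemPhysiology)
    solver: SolverOptions = field(default_factory=SolverOptions)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)

    @property
    def compound(self) -> CompoundProfile:
        return self.dose_event.compound

    @property
    def dose(self) -> float:
        return self.dose_event.dose

    def resolved_physiology(self) -> GutPhysiology:
        return self.physiology or build_physiology(self.prandial_state)


@dataclass(frozen=True)
class PkSummary:
    cmax_geomean: float       # ng/mL
    cmax_gsd: float           # geometric SD (dimensionless, >= 1)
    auc_median: float         # ng/mL*h
    auc_range: tuple[float, float]
    tmax_median: float        # h
    tmax_range: tuple[float, float]


@dataclass
class SubjectResult:
    subject: SubjectParameters
    times: np.ndarray          # h
    concentrations: np.ndarray  # ng/mL plasma
    fa: float
    fg: float
    cmax: float
    tmax: float
    auc: float


@dataclass
class TrialResult:
    design: TrialDesign
    subjects: list[SubjectResult]
    summary: PkSummary

    @property
    def cmax(self) -> np.ndarray:
        return np.array([s.cmax for s in self.subjects])

    @property
    def auc(self) -> np.ndarray:
        return np.array([s.auc for s in self.subjects])

    @property
    def tmax(self) -> np.ndarray:
        return np.array([s.tmax for s in self.subjects])

    @property
    def fa(self) -> np.ndarray:
        return np.array([s.fa for s in self.subjects])

    @property
    def fg(self) -> np.ndarray:
        return np.array([s.fg for s in self.subjects])

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            rows.append(pd.DataFrame({
                "subject": s.subject.subject_id,
                "time_h": s.times,
                "conc_ng_ml": s.concentrations,
            }))
        return pd.concat(rows, ignore_index=True)

    def parameters_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"subject": s.subject.subject_id, "cmax": s.cmax, "tmax": s.tmax,
             "auc": s.auc, "fa": s.fa, "fg": s.fg,
             "cl_multiplier": s.subject.cl_multiplier,
             "vss_multiplier": s.subject.vss_multiplier}
            for s in self.subjects
        ])


def simulate_subject(
    design: TrialDesign,
    subject: Optional[SubjectParameters] = None,
    absorption: Literal["gut", "bolus"] = "gut",
) -> SubjectResult:
    """Simulate one subject's plasma concentration profile (ng/mL).

    ``absorption="gut"`` runs the full mechanistic model: gut states feed a
    well-stirred liver, which drains into the central compartment.
    ``absorption="bolus"`` is a verification configuration: the dose is
    placed in the central compartment at t=0 with no first pass (fa=fg=fh=1
    for input) and eliminated with the compound's oral blood clearance, so
    the profile has the one-compartment closed form C(t) = D/V * exp(-k t).
    """
    subject = subject or SubjectParameters()
    compound = design.compound
    system = design.system
    bp = compound.bp_ratio
    clpo_blood = compound.clpo_l_per_h / bp
    # fu_b * CLu_int (blood) from the retrograde identity, with population scaling
    x_int = (
        clpo_blood * compound.retrograde_fa * compound.retrograde_fg
        * subject.cl_multiplier * subject.liver_cyp_multiplier
    )
    v_central = compound.vss * subject.body_weight * subject.vss_multiplier / bp
    v_liver = system.liver_volume
    q_h = system.hepatic_blood_flow
    if system.renal_fraction > 0:
        cl_h = q_h * x_int / (q_h + x_int)
        cl_renal = cl_h * system.renal_fraction / (1.0 - system.renal_fraction)
    else:
        cl_renal = 0.0

    t_eval = design.sampling_times
    dose = design.dose

    if absorption == "bolus":
        def rhs(t, y):
            return [-x_int * y[0] / v_central - cl_renal * y[0] / v_central]

        sol = solve_ivp(
            rhs, (0.0, design.duration), [dose], method=design.solver.method,
            t_eval=t_eval, rtol=design.solver.rtol, atol=design.solver.atol,
        )
        if not sol.success:
            raise RuntimeError(f"systemic solver failed: {sol.message}")
        conc_blood = sol.y[0] / v_central              # mg/L
        conc = conc_blood / bp * 1000.0                # ng/mL plasma
        cmax, tmax, auc = pk_parameters(sol.t, conc)
        return SubjectResult(subject, sol.t, conc, 1.0, 1.0, cmax, tmax, auc)

    physiology = design.resolved_physiology()
    options = replace(
        design.solver,
        t_end=design.duration,
        gut_cyp_multiplier=design.solver.gut_cyp_multiplier * subject.gut_cyp_multiplier,
    )
    gm = GutModel(compound, design.dose_event, physiology, system, options)
    n_gut = gm.N_STATES
    i_liver, i_central = n_gut, n_gut + 1

    def rhs(t, y):
        dy = np.empty(n_gut + 2)
        dy[:n_gut] = gm.rhs(t, y[:n_gut])
        c_liver = y[i_liver] / v_liver
        c_central = y[i_central] / v_central
        portal = gm.portal_rate(y[:n_gut])
        dy[i_liver] = portal + q_h * c_central - (q_h + x_int) * c_liver
        dy[i_central] = q_h * c_liver - q_h * c_central - cl_renal * c_central
        return dy

    y0 = np.zeros(n_gut + 2)
    y0[:n_gut] = gm.init_state()
    sol = solve_ivp(
        rhs, (0.0, design.duration), y0, method=design.solver.method,
        t_eval=t_eval, rtol=design.solver.rtol, atol=design.solver.atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"subject {subject.subject_id}: solver failed at t={sol.t[-1]:.2f} h: "
            f"{sol.message}"
        )
    conc = sol.y[i_central] / v_central / bp * 1000.0  # ng/mL plasma
    conc = np.maximum(conc, 0.0)
    y_end = sol.y[:n_gut, -1]
    absorbed = float(np.sum(y_end[28:36]))
    fa = absorbed / dose if dose > 0 else 0.0
    fg = float(y_end[26]) / absorbed if absorbed > 0 else 1.0
    cmax, tmax, auc = pk_parameters(sol.t, conc)
    return SubjectResult(subject, sol.t, conc, fa, fg, cmax, tmax, auc)


def pk_parameters(times: Sequence[float], conc: Sequence[float]):
    """Noncompartmental (Cmax, tmax, AUC) from a sampled profile.

    Cmax is the maximum observed concentration, tmax the time of its first
    occurrence, AUC the linear trapezoid over the sampling grid. An all-zero
    profile yields (0, nan, 0).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    cmax = float(c.max())
    if cmax <= 0.0:
        return 0.0, float("nan"), 0.0
    tmax = float(t[int(np.argmax(c))])
    auc = float(np.trapezoid(c, t))
    return cmax, tmax, auc


def summarize_pk(
    cmax: Sequence[float], auc: Sequence[float], tmax: Sequence[float]
) -> PkSummary:
    """Geometric mean (GSD) for Cmax; median (range) for AUC and tmax."""
    cmax = np.asarray(cmax, dtype=float)
    auc = np.asarray(auc, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    pos = cmax > 0
    if not pos.all():
        import warnings

        warnings.warn(f"excluding {int((~pos).sum())} non-positive Cmax values",
                      stacklevel=2)
    logs = np.log(cmax[pos])
    gsd = float(np.exp(np.std(logs, ddof=1))) if pos.sum() > 1 else 1.0
    return PkSummary(
        cmax_geomean=float(np.exp(np.mean(logs))),
        cmax_gsd=gsd,
        auc_median=float(np.median(auc)),
        auc_range=(float(auc.min()), float(auc.max())),
        tmax_median=float(np.nanmedian(tmax)),
        tmax_range=(float(np.nanmin(tmax)), float(np.nanmax(tmax))),
    )


def run_trial(design: TrialDesign) -> TrialResult:
    """Simulate a virtual population through one trial arm.

    The population is drawn by ``synthetic_data.gen_population`` from the
    design seed, so a fixed seed reproduces the trial bit-for-bit.
    """
    from . import synthetic_data  # deferred: synthetic_data imports this module

    population = synthetic_data.gen_population(
        design.n_subjects, design.population_cv, design.seed
    )
    subjects = []
    for sp in population:
        try:
            subjects.append(simulate_subject(design, sp))
        except RuntimeError as err:
            raise RuntimeError(f"trial aborted at subject {sp.subject_id}: {err}")
    summary = summarize_pk(
        [s.cmax for s in subjects], [s.auc for s in subjects],
        [s.tmax for s in subjects],
    )
    return TrialResult(design=design, subjects=subjects, summary=summary)


def compare_groups(
    result_a: TrialResult | Sequence[float],
    result_b: TrialResult | Sequence[float],
    parameter: str = "auc",
    welch: bool = True,
) -> dict:
    """Unpaired two-tailed t-test on a PK parameter across two trial arms.

    Also reports the geometric-mean ratio (a/b) with its 90% CI as the
    bioequivalence-style diagnostic. With zero variance in both groups an
    exact-equality report replaces the t-test.
    """
    def _values(r):
        if isinstance(r, TrialResult):
            return np.asarray(getattr(r, parameter), dtype=float)
        return np.asarray(r, dtype=float)

    a, b = _values(result_a), _values(result_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    report: dict = {"parameter": parameter, "n_a": len(a), "n_b": len(b),
                    "mean_a": float(a.mean()), "mean_b": float(b.mean())}
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
        report.update({"t": None, "p": None,
                       "equal": bool(np.isclose(a.mean(), b.mean()))})
        return report
    tt = stats.ttest_ind(a, b, equal_var=not welch)
    report.update({"t": float(tt.statistic), "p": float(tt.pvalue),
                   "welch": welch})
    if (a > 0).all() and (b > 0).all():
        la, lb = np.log(a), np.log(b)
        diff = la.mean() - lb.mean()
        se = math.sqrt(la.var(ddof=1) / len(a) + lb.var(ddof=1) / len(b))
        df = len(a) + len(b) - 2
        tcrit = stats.t.ppf(0.95, df)
        report["gmr"] = float(np.exp(diff))
        report["gmr_ci90"] = (float(np.exp(diff - tcrit * se)),
                              float(np.exp(diff + tcrit * se)))
    return report


# ---------------------------------------------------------------------------
# Design serialization


def design_to_dict(design: TrialDesign) -> dict:
    from .compound import compound_to_dict

    de = design.dose_event
    return {
        "compound": compound_to_dict(de.compound),
        "dose": float(de.dose),
        "formulation": de.formulation,
        "release": {m: model.to_dict() for m, model in de.release.items()},
        "medium_map": dict(de.medium_map),
        "prandial_state": design.prandial_state,
        "n_subjects": int(design.n_subjects),
        "duration": float(design.duration),
        "sampling_times": [float(t) for t in design.sampling_times],
        "seed": int(design.seed),
        "population_cv": design.population_cv,
    }


def design_from_dict(d: dict) -> TrialDesign:
    from .compound import compound_from_dict
    from .dissolution import ReleaseModel

    dose_event = DoseEvent(
        compound=compound_from_dict(d["compound"]),
        dose=d["dose"],
        formulation=d["formulation"],
        release={m: ReleaseModel(**spec) for m, spec in d["release"].items()},
        medium_map=dict(d.get("medium_map",
                              {"fasted": "FaSSIF", "fed": "FeSSIF"})),
    )
    return TrialDesign(
        dose_event=dose_event,
        prandial_state=d["prandial_state"],
        n_subjects=d.get("n_subjects", 10),
        duration=d.get("duration", 24.0),
        sampling_times=np.asarray(d["sampling_times"], float)
        if "sampling_times" in d else _default_sampling(),
        seed=d.get("seed", 0),
        population_cv=d.get("population_cv"),
    )


def save_design(design: TrialDesign, path: str) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(design_to_dict(design), fh, sort_keys=False)


def load_design(path: str) -> TrialDesign:
    import yaml

    with open(path) as fh:
        return design_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Parameter estimation


@dataclass
class ObservedDataset:
    """One observed plasma dataset used for parameter estimation."""

    times: np.ndarray          # h
    concentrations: np.ndarray  # ng/mL (pooled or mean over subjects)
    dose_event: DoseEvent
    prandial_state: Literal["fasted", "fed"] = "fasted"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must align")


_FREE_PARAMETERS = ("peff", "vss", "raf_pgp")


@dataclass
class EstimationProblem:
    """Bounded weighted least squares of simulated vs observed concentrations."""

    datasets: list[ObservedDataset]
    free_parameters: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    weighting: Literal["uniform", "1/y", "1/y2"] = "uniform"
    n_starts: int = 5
    seed: int = 0
    system: SystemPhysiology = field(default_factory=SystemPhysiology)
    solver: SolverOptions = field(
        default_factory=lambda: SolverOptions(rtol=1e-6, atol=1e-9)
    )
    xtol: float = 1e-8
    ftol: float = 1e-10
    maxfev: int = 4000

    def __post_init__(self) -> None:
        if not self.datasets:
            raise ValueError("at least one observed dataset is required")
        for p in self.free_parameters:
            if p not in _FREE_PARAMETERS:
                raise ValueError(f"unknown free parameter {p!r}")
            lo, hi = self.bounds[p]
            if not (0 < lo < hi < math.inf):
                raise ValueError(f"bounds for {p} must be finite and positive")


@dataclass
class EstimationResult:
    values: dict[str, float]
    objective: float
    starts: pd.DataFrame
    n_evaluations: int


def _weights(obs: np.ndarray, scheme: str) -> np.ndarray:
    floor = max(float(np.max(obs)) * 1e-3, 1e-12)
    safe = np.maximum(obs, floor)
    if scheme == "uniform":
        return np.ones_like(obs)
    if scheme == "1/y":
        return 1.0 / safe
    if scheme == "1/y2":
        return 1.0 / safe**2
    raise ValueError(f"unknown weighting {scheme!r}")


def estimate_parameters(problem: EstimationProblem) -> EstimationResult:
    """Multi-start bounded local search over the free parameters.

    Each start runs a derivative-free Powell search within bounds; the
    per-start table records initial point, final point and objective. The
    typical (multiplier-1) subject is simulated against each dataset.
    """
    names = list(problem.free_parameters)
    lo = np.array([problem.bounds[p][0] for p in names])
    hi = np.array([problem.bounds[p][1] for p in names])
    n_eval = 0

    def objective(theta: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        total = 0.0
        for ds in problem.datasets:
            compound = ds.dose_event.compound
            updates = dict(zip(names, theta))
            compound = compound.with_(**updates)
            dose_event = replace(ds.dose_event, compound=compound)
            design = TrialDesign(
                dose_event=dose_event,
                prandial_state=ds.prandial_state,
                n_subjects=1,
                duration=float(ds.times.max()),
                sampling_times=ds.times,
                system=problem.system,
                solver=problem.solver,
            )
            try:
                sim = simulate_subject(design)
            except RuntimeError:
                return 1e12
            w = _weights(ds.concentrations, problem.weighting)
            total += float(np.sum(w * (sim.concentrations - ds.concentrations) ** 2))
        return total

    rng = np.random.default_rng(problem.seed)
    starts = [0.5 * (lo + hi)]
    for _ in range(problem.n_starts - 1):
        starts.append(lo + rng.random(len(names)) * (hi - lo))

    rows = []
    best_x, best_f = None, np.inf
    for k, x0 in enumerate(starts):
        f0 = objective(np.asarray(x0))
        res = optimize.minimize(
            objective, x0, method="Powell",
            bounds=list(zip(lo, hi)),
            options={"xtol": problem.xtol, "ftol": problem.ftol,
                     "maxfev": problem.maxfev},
        )
        # a truncated line search may end worse than the start point
        xk, fk = (res.x, float(res.fun)) if res.fun <= f0 else (np.asarray(x0), f0)
        rows.append({"start": k, **{f"x0_{p}": x0[i] for i, p in enumerate(names)},
                     **{p: xk[i] for i, p in enumerate(names)},
                     "objective": fk, "success": bool(res.success)})
        if fk < best_f:
            best_x, best_f = xk, fk
    if best_x is None or not np.isfinite(best_f):
        raise RuntimeError("all optimization starts failed")
    return EstimationResult(
        values={p: float(best_x[i]) for i, p in enumerate(names)},
        objective=best_f,
        starts=pd.DataFrame(rows),
        n_evaluations=n_eval,
    )
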
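"""Recover (Peff, Vss) from synthetic plasma data by bounded least squares.

Generates a noise-free single-dose amlodipine plasma profile with known
ground truth, then fits human effective permeability and volume of
distribution by simulating candidate parameter sets through the full
absorption + disposition model (Powell search within bounds, center start).
"""

from oralbe.compound import load_compound
from oralbe.gut_absorption import SolverOptions
from oralbe.studies import pooled_mean_profile
from oralbe.synthetic_data import PlasmaTruth, dose_event_for, gen_plasma
from oralbe.trial_engine import EstimationProblem, ObservedDataset, estimate_parameters

amlodipine = load_compound("amlodipine")
truth = PlasmaTruth(compound=amlodipine, dose_mg=5.0, n_subjects=1,
                    cv_cl=0.0, cv_vss=0.0, residual_cv=0.0, seed=3)
times, conc = pooled_mean_profile(gen_plasma(truth))

problem = EstimationProblem(
    datasets=[ObservedDataset(times=times, concentrations=conc,
                              dose_event=dose_event_for(amlodipine, "single"))],
    free_parameters=("peff", "vss"),
    bounds={"peff": (3e-5, 5e-4), "vss": (4.0, 30.0)},
    n_starts=2, seed=0, solver=SolverOptions(rtol=1e-6, atol=1e-9),
    xtol=1e-5, maxfev=400,
)
fit = estimate_parameters(problem)

print(f"true  Peff = {amlodipine.peff:.3e} cm/s, Vss = {amlodipine.vss:.2f} L/kg")
print(f"fitted Peff = {fit.values['peff']:.3e} cm/s, "
      f"Vss = {fit.values['vss']:.2f} L/kg")
print(f"objective (weighted SSE) = {fit.objective:.3e} after "
      f"{fit.n_evaluations} model evaluations")
print("\nWith noise-free data the fit returns the generating parameters;")
print("with assay noise the estimates scatter around them (see docs/methods.md).")
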
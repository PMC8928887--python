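"""Can a well-sampled web be recovered from an under-sampled observation?

Links are deleted at random from a ground-truth web (emulating incomplete
sampling), the ADBM is fitted by ABC to the degraded web, and the posterior
webs are scored against the undegraded truth. The estimated connectance
typically exceeds the degraded observed connectance: the model "fills back"
missing links because it can only predict contiguous diets.
"""

from adbm import ADBMParams, SyntheticScenario, recovery_experiment

scenario = SyntheticScenario(
    S=20,
    log10_mass_bounds=(-6, 2),
    true_params=ADBMParams(a=1e-3, ai=0.5, aj=0.5, b=0.1),
    removal_prob=0.2,
    seed=1001,
)
report = recovery_experiment(scenario, n_accept=100, n_reference=1500)

print(f"true connectance:            {report.truth_connectance:.4f}")
print(f"degraded (observed):         {report.degraded_connectance:.4f}")
print(f"posterior mean connectance:  {report.posterior_mean_connectance:.4f}")
print(f"selected tol:                {report.chosen_tol}")
print(f"mean TSS vs undegraded truth: {report.mean_tss_vs_truth:.4f}")
print(f"true parameter inside 95% CI: {report.param_covered}")
print()
print(
    "The posterior-mean connectance exceeds the degraded observation --\n"
    "the fitting procedure compensates for deleted links rather than\n"
    "reproducing the under-sampled web verbatim."
)
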
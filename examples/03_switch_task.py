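"""Switch-task habituation: single vs. multiple agreeing speakers.

An infant hears seven tokens of "buk" for a novel object, either as
seven repetitions from one speaker or one token from each of seven
speakers. Because speakers are consistent (one intention per object),
repetitions from a lone speaker add no evidence, while independent
agreement compounds: the posterior on the habituated label rises from
2/3 to ~0.9999. Greater certainty about the label predicts longer
looking on switch trials.
"""

from epilex import GibbsSettings, run_simulation2

for condition in ("single", "multiple"):
    exact = run_simulation2(condition, tokens=7, method="exact", k_prior=0.5)
    print(f"{condition} speaker condition (exact enumeration):")
    for label, p in exact.posterior.items():
        print(f"  C = {label:<4s} {p:.6f}")

gibbs = run_simulation2(
    "multiple", tokens=7, method="gibbs",
    settings=GibbsSettings(samples=20_000, burn_in=2_000, seed=0),
)
print("multiple speaker condition (Gibbs, 20,000 samples after burn-in):")
for label, p in gibbs.posterior.items():
    print(f"  C = {label:<4s} {p:.6f}")
print(f"  effective sample size (modal label): "
      f"{gibbs.diagnostics['ess_modal_label']['obj']:.0f}")
print()
print(
    "One speaker repeating 'buk' leaves P(buk) at 2/3 no matter how often\n"
    "they repeat it; seven independent speakers agreeing push it to ~0.9999.\n"
    "The Gibbs estimate tracks the exact value to within sampling error."
)
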
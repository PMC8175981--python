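"""How informative is one labeling event about the speaker's knowledgeability?

A 16-month-old already knows the object's label, so hearing it labeled
tells them about the *speaker*. We compute the KL divergence (bits)
between the posterior and prior belief over the speaker's
knowledgeability for correct and incorrect labels from two groups:
adult humans (prior knowledgeability 0.80) and inanimate audio speakers
(0.15), with 3 candidate labels.
"""

from epilex import run_simulation1

report = run_simulation1(theta_adult=0.80, theta_audio=0.15, n_labels=3)

print("Informativeness of one labeling event (bits of KL divergence):")
for condition, value in report.rows():
    print(f"  {condition:<26s} {value:.4f}")

print()
print(
    "An incorrect label from an adult is by far the most informative event\n"
    "(~2.32 bits): a trusted informant has just revealed itself to be\n"
    "unknowledgeable. Correct and incorrect labels from the low-trust audio\n"
    "group are roughly equally (un)informative — the predicted ordering of\n"
    "infant looking times."
)
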
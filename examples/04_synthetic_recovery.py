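"""Sample corpora from the generative model and recover the true label.

Speakers are drawn with Bernoulli(theta) knowledgeability; knowledgeable
ones always label correctly, the rest commit to one uniform-random label.
With mostly knowledgeable speakers the MAP label under exact joint
inference (with matched per-speaker priors) recovers the truth almost
always; a single surely-unknowledgeable speaker carries no information
and leaves the posterior at the uniform prior.
"""

from epilex import CorpusDesign, GroupSpec, LabelSpace, recovery_experiment, sample_corpus

space = LabelSpace(("wug", "dax", "fep"))
groups = {"caregivers": GroupSpec("caregivers", 0.9)}

design = CorpusDesign(
    label_space=space,
    true_categories={"toy": "wug"},
    speakers=tuple((f"s{i}", "caregivers") for i in range(10)),
    groups=groups,
    tokens_per_speaker_object=1,
    seed=2024,
)

corpus = sample_corpus(design)
print(f"one sampled corpus: m={corpus.m} speakers, "
      f"tokens={[e.token for e in corpus.events]}")

report = recovery_experiment(design, replicates=200)
print(f"recovery over {report.replicates} replicate corpora "
      f"(theta=0.9, 10 speakers, 3 labels):")
print(f"  MAP accuracy:            {report.map_accuracy:.3f}")
print(f"  mean posterior on truth: {report.mean_posterior_on_truth:.3f}")

lone = CorpusDesign(
    label_space=space,
    true_categories={"toy": "wug"},
    speakers=(("s0", "noise"),),
    groups={"noise": GroupSpec("noise", 0.0)},
    seed=7,
)
uninformative = recovery_experiment(lone, replicates=50)
print(f"lone theta=0 speaker: mean posterior on truth = "
      f"{uninformative.mean_posterior_on_truth:.4f} (the 1/3 prior, exactly)")
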
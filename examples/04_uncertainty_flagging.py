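"""Turn posteriors into per-epoch uncertainty and review flags.

Shannon entropy of the five-class posterior ranges from 0 bits (the model
is sure) to log2(5) = 2.32 bits (it knows nothing).  An epoch whose entropy
strictly exceeds 1 bit - the entropy of two equally likely stages - is
flagged for targeted expert review.
"""

import sleepuq as s

print("entropy of [0,0,0,0.5,0.5]:", s.shannon_entropy([0, 0, 0, 0.5, 0.5]), "bits")
print("entropy of the uniform posterior:", round(s.shannon_entropy([0.2] * 5), 2), "bits")

train_hyp, train_feats = s.simulate_and_featurize(s.SyntheticStudyConfig(n_epochs=480, seed=10))
test_hyp, test_feats = s.simulate_and_featurize(s.SyntheticStudyConfig(n_epochs=480, seed=11))
model = s.fit_hmm(train_feats, train_hyp)
posteriors = model.predict_posteriors(test_feats)

trace = s.uncertainty_trace(posteriors, "shannon")
flags = s.flag_uncertain(trace, threshold=1.0)
count, fraction = s.review_burden(flags)
print(f"flagged {count}/{len(flags)} epochs ({100 * fraction:.1f}% of the night)")

estimate = s.estimate_hypnogram(posteriors)
correct = estimate.stages == test_hyp.stages
print(f"mean entropy, correct epochs:   {trace.values[correct].mean():.2f} bits")
print(f"mean entropy, incorrect epochs: {trace.values[~correct].mean():.2f} bits")

# The incorrect epochs carry markedly more entropy: the model's own
# uncertainty predicts where it is wrong, before any truth is consulted.
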
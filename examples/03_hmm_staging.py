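"""Stage a held-out night with the KDE-emission HMM and score it.

The HMM is trained on one labelled night (bigram transitions, per-stage
kernel density emissions) and decoded on a second night with the
forward-backward algorithm, which yields exact per-epoch posteriors
P(stage | whole night).  Agreement with ground truth is summarised by
Cohen's Kappa, the chance-corrected epoch-match rate.
"""

import sleepuq as s

train_hyp, train_feats = s.simulate_and_featurize(
    s.SyntheticStudyConfig(n_epochs=480, seed=10)
)
test_hyp, test_feats = s.simulate_and_featurize(
    s.SyntheticStudyConfig(n_epochs=480, seed=11)
)

model = s.fit_hmm(train_feats, train_hyp)
posteriors = model.predict_posteriors(test_feats)
estimate = s.estimate_hypnogram(posteriors)

accuracy = (estimate.stages == test_hyp.stages).mean()
report = s.cohens_kappa(estimate, test_hyp)
print(f"held-out accuracy: {accuracy:.3f} (chance = 0.2)")
print(f"Cohen's Kappa: {report.kappa:.3f} "
      f"(observed {report.observed_agreement:.3f}, "
      f"expected-by-chance {report.expected_agreement:.3f})")

# Kappa discounts the agreement two random scorers with these stage
# frequencies would reach; values above ~0.6 are 'substantial' agreement.
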
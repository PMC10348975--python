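"""Evaluate an estimated trace: feature contributions and eyes-scoring accuracy.

Runs the full pipeline on a four-block schedule, then reports Spearman
feature contributions, inter-cluster distances and the thresholded accuracy
sweep against the (noise-free) eyes scoring.
"""

import eegcl

schedule = eegcl.StateSchedule.alternating(300.0, 4)
config = eegcl.SynthConfig(n_channels=6, seed=1)
rec, labels = eegcl.generate_recording(schedule, config)
eyes = eegcl.generate_eyes_scoring(schedule, config)

rec = eegcl.bandpass_filter(rec)
fm = eegcl.extract_features(rec, eegcl.segment(rec))
trace, fcm_res, gmm_res = eegcl.estimate_consciousness(fm, seed=1)

contrib = eegcl.spearman_contributions(
    fm,
    {
        "FCM": fcm_res.conscious_trace(fm.timestamps),
        "GMM": gmm_res.conscious_trace(fm.timestamps),
        "Ensemble": trace,
    },
)
print("Spearman correlation of each feature with the ensemble trace:")
print(contrib[contrib.method == "Ensemble"]
      .set_index("feature")[["rho", "p_value"]].round(4))

d_fcm = eegcl.intercluster_distance(*fcm_res.centroids)
print(f"\ninter-cluster (centroid) distance, FCM: {d_fcm:.3f}")
print("larger distances indicate better-separated conscious/unconscious")
print("clusters and hence more trustworthy trace values")

acc = eegcl.accuracy_vs_eyes(trace, eyes)
print("\naccuracy against eyes scoring by binarisation threshold:")
print(acc.to_string(index=False))
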
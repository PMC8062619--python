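"""Generate the synthetic panel and a study-shaped count matrix.

The default panel carries 770 base genes plus 18 spiked immune genes (788
measured) along with the positive-control ladder A..F and negative controls.
The simulated cohort mirrors the trial: 19 patients, 14 matched pre/post
pairs, 7 complete responders, planted fold-change effects.
"""

import aktx

manifest = aktx.generate_panel()
print(f"measured genes: {len(manifest.measured_genes)}")
print(f"housekeeping genes: {len(manifest.housekeeping_genes)}")
ladder = [(l, manifest.positive_control(l).nominal_concentration) for l in "ABCDEF"]
print("positive-control ladder:", ladder)

counts, annotations, truth = aktx.simulate_counts(manifest, aktx.SimulationConfig(seed=1))
print(f"\ncount matrix: {counts.shape[0]} probes x {counts.shape[1]} samples")
n_pre = sum(a.timepoint == "pre" for a in annotations)
print(f"pre-treatment samples: {n_pre}, post: {len(annotations) - n_pre}")
print(f"complete responders: {len(truth.cr_patients)} of 19 patients")
print(f"planted response genes: {len(truth.response_effects)}, "
      f"treatment genes: {len(truth.treatment_effects)}")
print("\nfirst corner of the matrix (raw digital counts):")
print(counts.iloc[:4, :3])
# Each entry is a negative-binomial draw around library_factor x baseline,
# doubled/halved per planted log2 fold change for the sample's group.
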
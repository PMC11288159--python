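"""Quantify modification-induced signal shifts with the Mann-Whitney test.

Simulates one k-mer dataset under a strong 5moU-like effect (2-sigma current
shift at the central U, 1-sigma at neighbours, dwell lengthening) and tests
all 20 features.  Low p-values at neighbouring positions illustrate that the
modification perturbs the signal beyond the modified base itself.
"""

from nanoml5mou import ModEffect, compare_features, results_to_frame, simulate_kmer_dataset

dataset = simulate_kmer_dataset("AGTCC", n_per_class=300, effect=ModEffect.strong(), seed=11)
results = compare_features(dataset)
frame = results_to_frame(results)

print(f"k-mer {dataset.kmer}: {dataset.n_pos} modified vs {dataset.n_neg} unmodified windows")
print("\nmost significant feature per window position (positions 1-5, centre = 3):")
top = frame[frame["top_of_position"]].sort_values("feature_name")
print(
    top[["feature_name", "u_stat", "p_value", "median0", "median1"]]
    .to_string(index=False, float_format=lambda v: f"{v:.3g}")
)
print(
    "\nU counts modified-above-unmodified pairs; p < 0.05 marks a significant"
    "\nmodified-vs-unmodified shift. Central-position (…_3) features separate"
    "\nmost strongly, neighbours are attenuated but still significant."
)
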
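"""Validate the prep-and-cluster machinery on data with known ground truth.

Generates descriptor matrices from a Gaussian mixture with planted cluster
labels and planted near-collinear columns, pushes them through
standardize → VIF-prune → PCA → silhouette-selected k-medoids, and reports how
often the true number of clusters is recovered.
"""

from spirospace.synthetic import CollinearSpec, SyntheticSpec, recovery_experiment

spec = SyntheticSpec(
    n_clusters=3,
    sizes=(20, 20, 20),
    n_descriptors=6,
    separation=10.0,  # pairwise center distance, in units of within-cluster sd
    collinear=(
        CollinearSpec("c00", (0, 1), (1.0, 1.0), 1e-3),
        CollinearSpec("c01", (2,), (1.5,), 1e-3),
    ),
)
result = recovery_experiment(spec, k_range=(2, 6), n_reps=50, seed=7)

print(f"replicates: 50, planted k = {spec.n_clusters}, separation = {spec.separation}x sd")
print(f"true-k recovery rate:      {result.recovery_rate:.2f}")
print(f"mean adjusted Rand index:  {result.mean_agreement:.3f}")
print()
print("A recovery rate near 1 shows the silhouette criterion finds the planted k;")
print("ARI near 1 shows the k-medoids partition matches the planted labels almost")
print("exactly. The two planted collinear columns are removed by the VIF rule")
print("before clustering, so they do not distort the distances.")
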
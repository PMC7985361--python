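"""Autonomous k-means labeling versus ground truth.

Clusters a synthetic dataset's band-flux features (k=2) for each feature
set, maps the anonymous clusters to healthy/tumor semantics via the
high-wavenumber-collapse rule, and scores the labeling against the
generator's ground truth with accuracy / sensitivity / specificity.
"""

from ramanbayes import (
    GeneratorConfig,
    build_feature_matrix,
    compare_partitions,
    fit_kmeans,
    map_cluster_labels,
    preprocess_all,
)
from ramanbayes.metrics import stats_from_counts
from ramanbayes.synth import generate_dataset

sset, manifest = generate_dataset(GeneratorConfig(seed=12), 25, 25, 0, seed=12)
pre = preprocess_all(sset)
truth = manifest["true_class"].tolist()

print(f"{'set':>5} {'acc %':>8} {'sens %':>8} {'spec %':>8}   cluster sizes")
for tag in ("FPHW", "FP", "HW"):
    fm = build_feature_matrix(pre, feature_set=tag)
    model = map_cluster_labels(fit_kmeans(fm, seed=0))
    labels = model.labels()
    stats = stats_from_counts(compare_partitions(labels, truth))
    sizes = [labels.count("healthy"), labels.count("tumor")]
    print(
        f"{tag:>5} {stats.accuracy_display:>8} {stats.sensitivity_display:>8} "
        f"{stats.specificity_display:>8}   healthy={sizes[0]} tumor={sizes[1]}"
    )

print(
    "\nPositive class is tumor. With well-separated synthetic templates the"
    "\nunsupervised partition recovers the ground truth without histology."
)
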
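"""Evolve a supervised 2-D projection and compare it with PCA.

The synthetic feature family hides the class signal on a single
low-variance axis beneath high-variance nuisance axes, so the variance-
maximizing PCA projection is blind to it while the silhouette-driven
evolutionary search recovers it.
"""

from evoslide import EAConfig, evolve, silhouette, transform
from evoslide.projections import pca_projection
from evoslide.synthetic import SyntheticFeatureSpec, gen_feature_set

spec = SyntheticFeatureSpec(
    n_per_class=200, dim=20, signal_axes=(0,), separation_delta=6.0,
    signal_sd=0.5, nuisance_sd=5.0, seed=0,
)
features, labels = gen_feature_set(spec)

config = EAConfig(P=5, G=300, mu=0.8, rho=0.4, sigma=0.1, seed=0)
W, trace = evolve(features.values, labels, config, d_out=2)

ea_sil = silhouette(transform(features.values, W), labels)
pca = pca_projection(features.values, 2)
pca_sil = silhouette(transform(features.values, pca), labels)

print(f"initial best fitness : {trace.best[0]:+.4f}")
print(f"final best fitness   : {trace.best[-1]:+.4f}")
print(f"EA 2-D silhouette    : {ea_sil:+.4f}")
print(f"PCA 2-D silhouette   : {pca_sil:+.4f}")
print()
print("A silhouette near +1 means the two classes form tight, well-separated")
print("clusters after projection; near 0 means the projection carries no")
print("class information. The evolved projection separates the classes while")
print("PCA, following the nuisance variance, does not.")
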
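"""Constrained-mixture zoning of a three-tracer dataset.

Fits all ten covariance parameterizations (EII ... VVV) over a range of
cluster counts to a small synthetic three-cluster dataset, prints the BIC
surface, and shows the plateau-based choice of the number of zones.
"""

import numpy as np

from isozone import bic, classify, em_fit, fit_family, select_model_plateau

rng = np.random.default_rng(2)
X = np.vstack([
    rng.normal((6.0, -11.0, -27.0), (0.6, 0.9, 0.4), (150, 3)),    # background
    rng.normal((9.0, -5.0, -24.8), (0.8, 1.0, 0.5), (120, 3)),     # enriched halo
    rng.normal((13.0, -0.5, -26.0), (0.7, 0.8, 0.5), (80, 3)),     # canopy core
])

surface = fit_family(X, k_range=range(1, 8))
print("BIC surface (rows k, columns covariance code):")
print(surface.values.round(1).to_string())

code, k = select_model_plateau(surface, tau=0.01)
fit = surface.fits[(code, k)]
print(f"\nchosen: {code} with k = {k} (BIC {bic(fit):.1f})")
print("component means (n_conc g/kg, d15N permil, d13C permil):")
for j, m in enumerate(fit.means, start=1):
    print(f"  zone {j}: {m.round(2)}")
labels = classify(fit)
print("zone sizes:", np.bincount(labels)[np.unique(labels)])
print("\nThe chosen k sits at the start of the BIC plateau: more components")
print("stop improving the penalized likelihood once each generative cluster")
print("is covered by one Gaussian.")
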
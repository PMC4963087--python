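"""Full three-plot study: simulate, interpolate, zone, harmonize.

Runs the complete pipeline on the default synthetic study (two invaded
plots, one control) at a coarse 2 m resolution so the example finishes in
about a minute, then prints the per-plot zone counts, the final cross-plot
clusters, and the invader-influence diagnostics.
"""

import dataclasses
import tempfile

import numpy as np

from isozone import pipeline as pl
from isozone import synth

workdir = tempfile.mkdtemp(prefix="isozone_example_")
scenarios = [dataclasses.replace(s, resolution=2.0)
             for s in synth.validation_scenarios(seed=1)]
config = pl.simulate_to_files(workdir, seed=1, scenarios=scenarios)
config.profile["k_max"] = 8

result = pl.run_pipeline(config)

print("per-plot zoning:")
for pid, info in result.manifest["plots"].items():
    tag = "invaded" if info["invaded"] else "control"
    print(f"  plot {pid} ({tag}): {info['n_zones']} zones, "
          f"covariance model {info['mixture_code']}")
print(f"final harmonized clusters: k = {result.manifest['final_k']}")

mapping = result.harmonization.mapping
high = mapping["final"].max()
high_plots = sorted(mapping.loc[mapping["final"] == high, "plot"].unique())
print(f"highest-N final cluster {high} occurs in plots: {high_plots}")

for pid, summ in result.summaries.items():
    if result.distances[pid] is None:
        continue
    m = mapping[mapping["plot"] == pid]
    finals = dict(zip(m["zone"], m["final"]))
    md = {finals[z]: d for z, d in zip(summ["zone"], summ["median_dist"])}
    print(f"  plot {pid}: median distance to canopy by final cluster: "
          + ", ".join(f"{c}: {md[c]:.1f} m" for c in sorted(md)))
print("\nThe highest-N cluster should appear only in invaded plots and sit")
print("closest to the canopy: that cluster IS the invader's zone of influence.")
print(f"artifacts in {workdir}")
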
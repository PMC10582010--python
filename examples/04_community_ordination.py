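"""Ordinate a community table and regress its first axis on the indices.

Bray-Curtis distances -> non-metric MDS (PCA-rotated, axis 1 mirrored to
ascend with recovery) -> OLS of axis 1 on the five acoustic indices.
This is the statistical core of the recovery-tracking analysis.
"""

from sonoscape import indices as idx
from sonoscape import pipeline as pl
from sonoscape import simulate as sim
from sonoscape import stats

cfg = pl.RunConfig()
cfg.simulator.n_plots = 12
cfg.simulator.schedule_days = 1
cfg.simulator.schedule_interval_s = 14_400.0  # 6 files per plot
cfg.detector.enabled = False

report = pl.run_pipeline(cfg)
g = report["dataset"].gradients
ordination = report["truth_ordination"]
fit = report["regressions"]["community_axis"]

print(f"NMDS stress: {ordination.stress:.4f}")
print("axis 1 vs gradient Pearson: "
      f"{stats.pearson(ordination.scores['axis1'], g):.3f}")
print(f"\nfive-index model of the community axis "
      f"(adj R^2 = {fit.adj_r2:.2f}):")
print(fit.table().round(3).to_string())
print()
print("A high axis-gradient correlation says community composition orders")
print("the plots along recovery; the adjusted R^2 says how much of that")
print("axis the acoustic indices explain without any species labels.")
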
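"""The complete regression-kriging pipeline on a synthetic landscape.

Simulates a 100x100-cell (30 m) landscape with 300 inventory plots,
fits the random-forest and radial-kernel SVR trend models, kriges their
training residuals, composes the regression-kriging surfaces, and
prints held-out accuracy plus the relative-improvement (RI) index.
"""

from agbkrige import RunConfig, SimulationConfig, run_pipeline

report = run_pipeline(RunConfig(seed=42, simulation=SimulationConfig(seed=42)))

print(f"{'model':7s} {'R2':>6s} {'RMSE':>7s} {'MAE':>7s} {'bias':>7s}")
for label in ("rf", "rfrk", "svm", "svmrk"):
    ev = report["models"][label]["evaluation"]
    print(f"{label:7s} {ev['r_squared']:6.3f} {ev['rmse']:7.2f} "
          f"{ev['mae']:7.2f} {ev['bias']:+7.2f}")

print(f"\nRI rf -> rfrk:   {report['ri']['rf_to_rfrk_pct']:.2f}%")
print(f"RI svm -> svmrk: {report['ri']['svm_to_svmrk_pct']:.2f}%")
for kind in ("rf", "svm"):
    v = report["variograms"][kind]
    print(f"{kind} residual variogram: {v['family']}, nugget {v['nugget']:.1f}, "
          f"partial sill {v['partial_sill']:.1f} (Mg/ha)^2, "
          f"range {v['range']:.0f} m")

# Kriging the residuals adds back the spatially autocorrelated part of
# the biomass signal that the covariates cannot explain, so both
# regression-kriging models beat their base learner on held-out plots
# (positive RI), mirroring how the method behaves on real inventories.
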
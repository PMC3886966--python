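"""Closed-loop kinetic fitting: generate one stepwise-degradation dataset and
re-estimate each group's parameters by Monte Carlo + conjugate gradient.

The generator's four groups share their shape constants but differ in the
maximal synthesis rate v_p (reduced in offspring of obese dams) and the
non-specific decay rate delta_p (rising stepwise lean-control < lean-HFD <
obese-control < obese-HFD).  The printout compares fitted and true values.
"""

import pparclock as pc

forcing = pc.default_bmal1_forcing()
ds, truth = pc.synth_ppar_groups(forcing, noise_cv=0.05, seed=42)
bounds = pc.recovery_bounds(truth)

print(f"{'group':<16} {'v_p fit':>8} {'v_p true':>9} {'d_p fit':>8} {'d_p true':>9}  rss")
for i, (m, d) in enumerate(pc.GROUPS):
    cfg = pc.FitConfig(n_monte_carlo=10_000, bounds=bounds, seed=100 + i)
    res = pc.fit_group(ds, "PPARA", m, d, forcing, cfg)
    row = truth[(truth.maternal == m) & (truth.diet == d)].iloc[0]
    print(f"{m}-{d:<9} {res.params.v_p:8.3f} {row.v_p:9.3f} "
          f"{res.params.delta_p:8.3f} {row.delta_p:9.3f}  {res.rss:.2e}")

print("\nWith 6 cross-sectional means and 8 parameters the fit is only")
print("weakly identified: v_p/delta_p estimates carry ~15% typical error")
print("even inside informative search boxes (see docs/methods.md).")
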
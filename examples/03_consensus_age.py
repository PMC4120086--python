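"""Consensus WGD age: KDE mode with a 90% ranked-bootstrap interval.

The mode of the kernel density estimate is used instead of the mean
because peak-based samples carry a younger-biased contaminant that shifts
moments but barely moves the density peak.
"""

from wgdwave import SimulationConfig, bootstrap_mode_ci, simulate_homeolog_ages

config = SimulationConfig(seed=1, n_anchor_pairs=400, n_peak_pairs=1200)

for source in ("anchor", "peak_based"):
    sample = simulate_homeolog_ages(config, source, seed=11, species="demo")
    est = bootstrap_mode_ci(sample, n_bootstrap=1000, seed=2)
    print(
        f"{source:>10}: n={est.n:4d}  mode {est.mode:6.2f} mya  "
        f"90% CI [{est.ci_low:.2f}, {est.ci_high:.2f}]  "
        f"mean {sample.ages.mean():6.2f} mya"
    )
print(
    f"true WGD age: {config.true_wgd_age} mya — both modes land within a few "
    "my of it, while the peak-based mean is dragged ~10 my young by the "
    "contaminant"
)
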
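"""Ask whether a population's action code generalizes across formats.

Two populations: one with format-general (mirror-like) action coding, one
whose intention and observation codes are unrelated.  For each, compute the
split-half cross-format RSA structure statistic with its permutation p, and
the cross-format decoding generalization map.
"""

from crossformat import (
    archetype_population,
    bin_rates,
    cross_format_decode,
    make_design,
    rsa_permutation_test,
    simulate_spikes,
)

design, trials = make_design("main", reps_per_condition=8, seed=1)

for name, counts in (("shared/mirror-like", {"shared_action3": 16}),
                     ("idiosyncratic", {"idiosyncratic": 16})):
    specs = archetype_population(counts, seed=2, effect_size=16.0, observation_gain=1.0)
    spikes, _ = simulate_spikes(design, trials, specs, seed=6)
    rates = bin_rates(spikes, design)

    pt = rsa_permutation_test(rates, trials, design, grouping="action", comparison="cross",
                              n_splits=50, n_perm=199, seed=4)
    gm = cross_format_decode(rates, trials, design, "action", train_format="intention",
                             n_perm=4999, window_bins=2, seed=5)
    print(f"{name:20s} RSA structure = {pt['observed']:+.3f} (p = {pt['p']:.4f}); "
          f"cross-format peak accuracy = {gm.matrix.max():.2f}, "
          f"significant train x test cells = {gm.n_significant}/{gm.matrix.size}")
# The shared population shows positive diagonal structure at the minimum
# attainable p and many Bonferroni-significant generalization cells; the
# idiosyncratic population shows neither, even though both are strongly tuned
# within each format.
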
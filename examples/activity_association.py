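"""Does weak membrane partitioning predict weak modulator potency?

Joins the screening panel with EC50/IC50 records and computes the two
association statistics: a Spearman rank correlation between dG_par and
log10 potency concentration, and a rank-sum comparison of potency between
molecules above and below the -10 kJ/mol partitioning threshold.
"""

import mempart as mp

panel, activity = mp.generate_screening_panel(seed=0)
join = mp.merge_activity(panel, activity)

rank = mp.rank_correlation(join, seed=0)
split = mp.threshold_split(join, cutoff=-10.0)

print(f"joined records: {rank.n} (assays pooled)")
print(f"Spearman rho(dG_par, log10 EC50/IC50) = {rank.rho:.2f}, "
      f"permutation p = {rank.p_value:.4f} ({rank.n_permutations} shuffles)")
print(f"threshold split at {split.cutoff:.0f} kJ/mol "
      f"({split.n_above} weak vs {split.n_below} strong partitioners):")
print(f"  median log10 concentration: {split.median_above:.2f} (weak) vs "
      f"{split.median_below:.2f} (strong)")
print(f"  rank-sum U = {split.statistic:.0f}, p = {split.p_value:.4f} "
      f"({split.method})")
print()
print("A positive rho means molecules that partition weakly into the bilayer")
print("need higher concentrations to act, i.e. they are less potent.")
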
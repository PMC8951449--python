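"""Split-half consistency and sliding-window sensitivity.

Each group is split into two sex/age-matched halves and the group-mean
network edge patterns of the halves are correlated; dFC variability is
also recomputed at window sizes 30/60/100 TR and compared with the
50-TR reference.
"""

import cstcnet as c

cohort = c.generate_roi_cohort(c.SimulationConfig(n_per_group=28, seed=9))
phen = cohort.phenotype

static, dyn_sd, signals = [], [], []
for sig in cohort.signals:
    x = sig[10:]
    signals.append(x)
    static.append(c.static_network(x))
    dyn_sd.append(c.dfc_variability(c.dynamic_network(x)))

split = c.split_half(phen, seed=0)
print("split balance (per group, p-values should be > 0.05):")
print(split.balance.to_string(index=False))

ids_a = set(split.half_ids("A"))
print("\nhalf-vs-half pattern correlations (190 unique edges):")
for group in ("HC", "GE", "FE"):
    rows = phen.index[phen.group == group]
    a = [i for i in rows if phen.loc[i, "id"] in ids_a]
    b = [i for i in rows if phen.loc[i, "id"] not in ids_a]
    for kind, mats in (("static", static), ("dynamic", dyn_sd)):
        r, p = c.pattern_correlation(
            c.mean_matrix([mats[i] for i in a]), c.mean_matrix([mats[i] for i in b])
        )
        print(f"  {group} {kind:7s}: r = {r:.3f} (p = {p:.2g})")

hc = phen.index[phen.group == "HC"].tolist()
print("\nwindow-size sweep on the healthy group (reference 50 TR):")
print(c.window_sweep([signals[i] for i in hc]).to_string(index=False))

# High pattern correlations mean both halves see the same network
# topology.  Healthy controls carry no planted dynamics, so their dFC
# variability pattern is nearly flat and its half-vs-half correlation is
# expected to hover near zero; in the patient groups the planted gated
# couplings give the pattern reproducible structure.  Stable sweep
# correlations mean the variability findings do not hinge on the 50-TR
# window choice.
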
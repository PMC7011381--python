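"""Fit the Sloan neutral community model to a simulated neutral community.

Generates 100 local communities assembled purely by immigration and drift
(migration rate m = 0.3), fits the occurrence-frequency curve, and reports
the recovered migration rate, goodness of fit and the share of OTUs inside
the 95% neutral band.
"""

import recoverymics as r
from recoverymics.neutral_model import fit_ncm

pool = r.make_source_pool(300, "lognormal", {"sigma": 1.5}, seed=1)
cfg = r.SimulationConfig(
    n_samples=100, N_local=1000, m=0.3, depth=2000, mode="stationary", seed=42
)
table = r.simulate_neutral_community(pool, cfg)

fit = fit_ncm(table, d=1, ci_level=0.95)
frac = fit.fractions

print(f"true migration rate      m  = {cfg.m}")
print(f"fitted migration rate    m^ = {fit.m:.3f}")
print(f"goodness of fit          R2 = {fit.r2:.3f}")
print(f"community size (reads)   N  = {fit.N:.0f}")
print(
    f"classification: {frac['neutral']:.1f}% neutral, "
    f"{frac['above']:.1f}% above, {frac['below']:.1f}% below"
)
print()
print(
    "A high R2 and a large neutral share mean occurrence frequencies are\n"
    "explained by source abundance + drift alone; OTUs above the band occur\n"
    "more often than neutrality predicts (candidate host selection), those\n"
    "below less often (dispersal limitation or exclusion)."
)
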
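"""Sugar content (TSS, %Brix): do bears pick sweeter berries?

Per-species linear mixed models with a bear-id random intercept, reduced by
backward selection, plus the Welch t test between the species means.
"""

import numpy as np

from berryforage import RunConfig, assemble_dataset, make_scenario
from berryforage.pipeline import run_sugar_analysis

scn = make_scenario(seed=5)
rng = np.random.default_rng(5)
table = assemble_dataset(scn.foraging_plots, scn.random_plots, rng)
res = run_sugar_analysis(table, RunConfig(selection_nodes=5))

for sp in ("bilberry", "lingonberry"):
    fit = res.fits[sp]
    n = fit.n_obs
    kept = "plottype" in fit.spec.terms
    print(f"{sp}: n={n} plots with ripe berries; plot-type effect "
          f"{'RETAINED' if kept else 'dropped'}")
    if kept:
        b = fit.beta[fit.names.index("plottype")]
        se = fit.se[fit.names.index("plottype")]
        print(f"  bear-used berries are {b:+.2f} +/- {se:.2f} %Brix sweeter")

t, p = res.t_test
print(f"\nbilberry vs lingonberry mean TSS: t = {t:.1f}, p = {p:.2g}")
print("  -> lingonberries carry clearly more sugar per unit juice; a"
      " plot-type effect only for lingonberry means bears were choosy about"
      " lingonberry sweetness but not bilberry sweetness.")
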
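"""Tumor-model quantification: cells/mg via counting beads and
Dunnett-starred shifts vs healthy control.

Runs a small joint experiment (control + intravenous LLC1 injection model,
5 mice each) and prints the populations whose absolute density changed.
The intravenous preset elevates VSMCs, NKT cells, Tregs and introduces
LLC1 tumor cells; everything else should stay unstarred.
"""

import lungflow as lf
from lungflow.pipeline import run_experiment

presets = lf.condition_presets()
counts, comparisons, ctx = run_experiment(
    [presets["control"], presets["intravenous"]], seed=1,
    n_mice=5, n_events=15_000, n_fmo=15_000,
)

print("population            control (cells/mg)   i.v. model     Dunnett p")
for c in comparisons:
    stars = c.stars["intravenous"]
    flag = f" {stars}" if stars else ""
    print(f"{c.population:22s} {c.means['control']:10.0f} "
          f"+- {c.sems['control']:5.0f}   {c.means['intravenous']:8.0f} "
          f"+- {c.sems['intravenous']:5.0f}  "
          f"p={c.pvalues['intravenous']:.4f}{flag}")

print("\nexpected elevated:", sorted(presets["intravenous"].elevated()))
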
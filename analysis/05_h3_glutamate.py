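"""Glutamate-dynamics experiment: scale the presynaptic release rate (w_f)
and astrocytic uptake/receptor-recovery rate (w_g) over {1, 1/2, 1/4}^2,
fit the identity-scale mixed model with diagonal random effects, and export
the fixed-effect response surface for contour plotting.

Desk scale: 2 repetitions.  Writes results/responses_h3.csv,
results/table_h3.csv and results/surface_h3_<response>.csv.
"""

import itertools
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gliasim.experiments import ExperimentPlan, build_network_suite, run_h3_glutamate
from gliasim.lme import fits_to_table, hypothesis_fits, response_surface

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    plan = ExperimentPlan(base_seed=1, n_reps=2, duration_s=300.0)
    suite = build_network_suite(plan)
    table = run_h3_glutamate(suite, plan)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "responses_h3.csv", index=False)
    fits = hypothesis_fits(table, "H3")
    fits_to_table(fits).to_csv(OUT / "table_h3.csv", index=False)

    wf = [0.25 + 0.025 * i for i in range(31)]
    grid = pd.DataFrame(
        [(a, b) for a, b in itertools.product(wf, wf)], columns=["w_f", "w_g"]
    )
    for resp, fit in fits.items():
        surf = response_surface(fit, grid)
        surf.to_csv(OUT / f"surface_h3_{resp}.csv", index=False)
    print(fits_to_table(fits).to_string(index=False))
    print("\nmean spike rate by (w_f, w_g):")
    print(table.pivot_table("Z_spike", "w_f", "w_g").to_string(
        float_format=lambda v: f"{v:.1f}"))


if __name__ == "__main__":
    main()
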
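"""Synaptic-weight experiment: sweep the excitatory and inhibitory weight
bounds (Ymax+ in {0.7, 0.8, 0.9}, Ymax- in {0.1, 0.5, 0.6, 0.7}), fit the
identity-scale mixed model with a network random intercept, and export the
fixed-effect response surface.

Desk scale: 2 repetitions.  Writes results/responses_h4.csv,
results/table_h4.csv and results/surface_h4_<response>.csv.
"""

import itertools
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gliasim.experiments import ExperimentPlan, build_network_suite, run_h4_weights
from gliasim.lme import fits_to_table, hypothesis_fits, response_surface

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    plan = ExperimentPlan(base_seed=1, n_reps=2, duration_s=300.0)
    suite = build_network_suite(plan)
    table = run_h4_weights(suite, plan)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "responses_h4.csv", index=False)
    fits = hypothesis_fits(table, "H4")
    fits_to_table(fits).to_csv(OUT / "table_h4.csv", index=False)

    yin = [0.1 + 0.02 * i for i in range(31)]
    yex = [0.7 + 0.02 * i for i in range(11)]
    grid = pd.DataFrame(
        [(a, b) for a, b in itertools.product(yin, yex)],
        columns=["y_in", "y_ex"],
    )
    for resp, fit in fits.items():
        response_surface(fit, grid).to_csv(
            OUT / f"surface_h4_{resp}.csv", index=False)
    print(fits_to_table(fits).to_string(index=False))
    print("\nmean spike rate by (y_in, y_ex):")
    print(table.pivot_table("Z_spike", "y_in", "y_ex").to_string(
        float_format=lambda v: f"{v:.1f}"))


if __name__ == "__main__":
    main()
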
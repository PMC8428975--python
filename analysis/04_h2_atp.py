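"""Astrocytic ATP experiment: sweep the depression magnitude y_Astro over
{0.01, 0.025, 0.05, 0.075, 0.1} and fit the log-scale mixed model with a
random intercept and y_Astro slope per network.

Desk scale: 2 repetitions.  Writes results/responses_h2.csv and
results/table_h2.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from gliasim.experiments import ExperimentPlan, build_network_suite, run_h2_atp
from gliasim.lme import fits_to_table, hypothesis_fits

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    plan = ExperimentPlan(base_seed=1, n_reps=2, duration_s=300.0)
    suite = build_network_suite(plan)
    table = run_h2_atp(suite, plan)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "responses_h2.csv", index=False)
    fits = hypothesis_fits(table, "H2")
    report = fits_to_table(fits)
    report.to_csv(OUT / "table_h2.csv", index=False)
    print(report.to_string(index=False))
    spike = table.groupby("y_astro")["Z_spike"].mean()
    print("\nmean spike rate by y_Astro:")
    print(spike.to_string(float_format=lambda v: f"{v:.1f}"))


if __name__ == "__main__":
    main()
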
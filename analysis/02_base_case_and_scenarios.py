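"""Lifetime costs and life expectancy for all seven strategies under the
base case (CD4 200-500) and the low/high CD4 scenarios.

Writes results/scenario_table.csv and prints the strategy ranking by
societal cost within each scenario.
"""

from pathlib import Path

from cervical_ce import base_case_and_scenarios, kenya_female_2011_synthetic, \
    load_parameters

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = load_parameters()
    lt = kenya_female_2011_synthetic()
    table = base_case_and_scenarios(params, lt)
    table.to_csv(OUT / "scenario_table.csv", index=False)
    print(f"wrote {OUT / 'scenario_table.csv'}")
    for scenario, sub in table.groupby("scenario", sort=False):
        print(f"\n{scenario}: (societal $, clinic $, discounted LE years)")
        for _, row in sub.iterrows():
            print(
                f"  {row.strategy:<9} {row.cost_societal:7.0f} "
                f"{row.cost_clinic:7.0f} {row.le_discounted:6.2f}"
            )
        cheapest = sub.iloc[0]
        print(f"  -> cheapest and most effective: {cheapest.strategy}")


if __name__ == "__main__":
    main()
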
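"""Materialize the background-mortality schedule used by the analyses.

Writes the bundled synthetic Kenya-like female life table (Gompertz-Makeham,
ages 15-100) to results/life_table.csv.  To run the analyses on the actual
WHO Kenya 2011 female table instead, export it per
src/cervical_ce/data/life_table_format.md and point the other scripts at it.
"""

from pathlib import Path

from cervical_ce import kenya_female_2011_synthetic

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    lt = kenya_female_2011_synthetic()
    df = lt.to_frame()
    df.to_csv(OUT / "life_table.csv", index=False)
    q38, q60, q80 = lt.q(38), lt.q(60), lt.q(80)
    print(f"wrote {OUT / 'life_table.csv'} ({len(df)} ages)")
    print(f"annual q at 38/60/80: {q38:.4f} / {q60:.4f} / {q80:.4f}")


if __name__ == "__main__":
    main()
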
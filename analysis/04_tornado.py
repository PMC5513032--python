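"""One-way (tornado) sensitivity analyses of the two incremental societal
cost comparisons: VIA over preventative cryotherapy, and HPV over VIA.

Writes results/tornado_via_minus_cryo.csv and results/tornado_hpv_minus_via.csv
(entries sorted by bar width), ready for horizontal-bar plotting.
"""

from pathlib import Path

import pandas as pd

from cervical_ce import kenya_female_2011_synthetic, load_parameters, tornado

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    params = load_parameters()
    lt = kenya_female_2011_synthetic()
    for comparison in ("VIA_minus_cryo", "HPV_minus_VIA"):
        base_delta, entries = tornado(comparison, params, lt, "societal")
        df = pd.DataFrame(
            {
                "parameter": [e.parameter_name for e in entries],
                "delta_low": [e.delta_low for e in entries],
                "delta_high": [e.delta_high for e in entries],
                "span": [e.span for e in entries],
            }
        )
        path = OUT / f"tornado_{comparison.lower()}.csv"
        df.to_csv(path, index=False)
        signs = set()
        for e in entries:
            signs.update((e.delta_low > 0, e.delta_high > 0))
        print(f"{comparison}: base incremental cost ${base_delta:.0f}")
        print(f"  widest bars: {', '.join(e.parameter_name for e in entries[:3])}")
        print(
            "  incremental cost sign "
            + ("changes within ranges" if len(signs) > 1 else "is constant")
        )
        print(f"  wrote {path}")


if __name__ == "__main__":
    main()
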
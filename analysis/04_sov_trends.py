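"""Share-of-voice composition, growth, and group comparisons.

Computes per-year SOV for every symptom, category, and the nocturnal
aggregate; the 2016->2018 compounded annual growth rate with an
independent-samples test on the dialogue-level indicators; and the pairwise
category comparisons (motor vs non-motor vs motor complications) per year.
"""

import argparse
from pathlib import Path

from pdlisten import Unit
from pdlisten.annotate import read_annotated
from pdlisten.lexicon import load_symptom_lexicon
from pdlisten.report import build_report, format_p, write_bundle


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--annotated", type=Path, default=Path("results/annotated/annotated.jsonl"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()

    included = read_annotated(args.annotated)
    bundle = build_report(included, load_symptom_lexicon())
    write_bundle(bundle, args.out)

    years = bundle.metadata["years"]
    sov = bundle.sov.set_index(["unit", "year"])["sov"]
    print(f"included dialogues per year: {bundle.metadata['included_per_year']}")
    for label in ("motor", "non_motor", "motor_complication", "nocturnal:any"):
        by_year = ", ".join(f"{y}: {100 * sov[(label, y)]:.1f}%" for y in years)
        trend = bundle.trend.set_index("unit").loc[label]
        cagr = 100 * trend["cagr"]
        print(f"{label:20s} SOV {by_year}  CAGR {cagr:+.1f}% (p {format_p(trend['p_value'])})")
    top = (
        bundle.trend[bundle.trend["kind"] == "symptom"]
        .assign(cagr_pct=lambda f: 100 * f["cagr"])
        .nlargest(3, "cagr_pct")
    )
    grown = ", ".join(f"{r.unit} {r.cagr_pct:+.1f}%" for r in top.itertuples())
    print(f"fastest-growing symptoms: {grown}")
    print(f"wrote SOV, trend and between-group tables to {args.out}/")


if __name__ == "__main__":
    main()
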
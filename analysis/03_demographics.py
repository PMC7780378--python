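"""Demographic summary of the included dialogues (age availability, bins).

Mirrors the study's reporting: counts and percentages for age groups
<50 / 50-60 / 60-70 / >70 over the subset of dialogues carrying an age.
"""

import argparse
from pathlib import Path

from pdlisten import age_statistics, demographics_summary
from pdlisten.annotate import read_annotated


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--annotated", type=Path, default=Path("results/annotated/annotated.jsonl"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()

    included = read_annotated(args.annotated)
    table = demographics_summary(included)
    stats = age_statistics(included)

    args.out.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    out["percent"] = out["percent"].round(1)
    out.to_csv(args.out / "demographics.csv", index=False)

    print(f"age available for {stats['n']} of {len(included)} included dialogues "
          f"({100 * stats['n'] / len(included):.1f}%)")
    print(f"mean age {stats['mean']:.1f} years (sd {stats['sd']:.1f})")
    print(out.to_string(index=False))
    print(f"wrote {args.out / 'demographics.csv'}")


if __name__ == "__main__":
    main()
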
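"""Weighted negative-sentiment burden, any-time vs nocturnal.

For each symptom, the score (p1*1 + ... + p6*6)/100 over dialogues carrying
the symptom and at least one graded sentiment word, computed once over all
mentions and once restricted to nocturnal mentions, plus the per-symptom
day/night contrast for symptoms that are not exclusively nocturnal.
"""

import argparse
from pathlib import Path

from pdlisten.annotate import read_annotated
from pdlisten.lexicon import load_symptom_lexicon
from pdlisten.report import build_report


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--annotated", type=Path, default=Path("results/annotated/annotated.jsonl"))
    parser.add_argument("--out", type=Path, default=Path("results/tables"))
    args = parser.parse_args()

    included = read_annotated(args.annotated)
    bundle = build_report(included, load_symptom_lexicon())

    args.out.mkdir(parents=True, exist_ok=True)
    for name in ("sentiment_any_time", "sentiment_nocturnal", "day_night"):
        frame = bundle.tables()[name].copy()
        for col in frame.columns:
            if frame[col].dtype.kind == "f":
                frame[col] = frame[col].round(1)
        frame.to_csv(args.out / f"{name}.csv", index=False)

    any_time = bundle.sentiment_any_time.sort_values("score", ascending=False)
    print("highest any-time negative-sentiment scores:")
    for row in any_time.head(5).itertuples():
        print(f"  {row.symptom:24s} {row.score:.1f} (n={row.n_eligible})")
    contrast = bundle.day_night
    higher = (contrast["difference"] > 0).sum()
    print(f"nocturnal score exceeds the any-time score for {higher} of "
          f"{len(contrast)} comparable symptoms")
    print(f"wrote sentiment tables to {args.out}/")


if __name__ == "__main__":
    main()
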
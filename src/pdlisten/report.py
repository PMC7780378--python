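"""End-to-end pipeline runs and the assembled output tables.

``run_pipeline`` goes configuration -> corpus -> normalization/annotation ->
inclusion filter -> SOV / trend / sentiment / demographics tables, with
per-stage counts logged and every table written as CSV alongside a single
machine-readable run-metadata file.  Percentages are carried at full
precision internally and rounded only when written (one decimal; p-values
below 0.01 displayed as "<0.01", matching common reporting practice).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel

from . import __version__
from . import lexicon as lex
from .annotate import (
    AnnotatedDialogue,
    Windows,
    annotate_corpus,
    filter_inclusion,
    load_sentiment_lexicon,
    load_symptom_lexicon,
)
from .metrics import (
    Unit,
    build_sov_table,
    compare_day_night,
    compute_sentiment_score,
    compute_sov,
    sov_trend,
)
from .stats import between_group_test
from .synthetic_corpus import GeneratorConfig, generate_corpus, read_corpus

logger = logging.getLogger(__name__)

DEFAULT_AGE_EDGES = (50, 60, 70)


def demographics_summary(
    corpus: Iterable, bin_edges: Sequence[int] = DEFAULT_AGE_EDGES
) -> pd.DataFrame:
    """Age-group counts and percentages over dialogues with a known age.

    Bins are left-closed between consecutive edges, with open bins below the
    first and above the last edge; the total row equals their sum.
    """
    edges = sorted(bin_edges)
    ages = []
    for item in corpus:
        dialogue = getattr(item, "dialogue", item)
        if dialogue.age is not None:
            ages.append(dialogue.age)
    labels = (
        [f"<{edges[0]}"]
        + [f"{a}-{b}" for a, b in zip(edges, edges[1:])]
        + [f">{edges[-1]}"]
    )
    counts = dict.fromkeys(labels, 0)
    for age in ages:
        if age < edges[0]:
            counts[labels[0]] += 1
        elif age >= edges[-1]:
            counts[labels[-1]] += 1
        else:
            for lo, hi, label in zip(edges, edges[1:], labels[1:-1]):
                if lo <= age < hi:
                    counts[label] += 1
                    break
    total = len(ages)
    rows = [
        {"age_group": label, "count": n, "percent": (100.0 * n / total) if total else 0.0}
        for label, n in counts.items()
    ]
    rows.append({"age_group": "Total", "count": total, "percent": 100.0 if total else 0.0})
    return pd.DataFrame(rows)


def age_statistics(corpus: Iterable) -> dict:
    """n / mean / sd of the available ages."""
    ages = []
    for item in corpus:
        dialogue = getattr(item, "dialogue", item)
        if dialogue.age is not None:
            ages.append(float(dialogue.age))
    if not ages:
        return {"n": 0, "mean": None, "sd": None}
    s = pd.Series(ages)
    return {"n": int(s.size), "mean": float(s.mean()), "sd": float(s.std(ddof=1))}


class PipelineConfig(BaseModel):
    """Configuration of a full run: either a generator scenario or a corpus
    file, plus lexicon paths (package defaults when omitted)."""

    generator: GeneratorConfig | None = None
    corpus_path: str | None = None
    symptom_lexicon: str | None = None
    sentiment_lexicon: str | None = None
    out_dir: str = "results"
    age_bin_edges: list[int] = list(DEFAULT_AGE_EDGES)
    windows: dict = {}

    def model_post_init(self, _ctx) -> None:
        if self.generator is None and self.corpus_path is None:
            raise ValueError("config needs either generator settings or a corpus_path")


@dataclass
class ReportBundle:
    demographics: pd.DataFrame
    sov: pd.DataFrame
    trend: pd.DataFrame
    between_groups: pd.DataFrame
    sentiment_any_time: pd.DataFrame
    sentiment_nocturnal: pd.DataFrame
    day_night: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "demographics": self.demographics,
            "sov": self.sov,
            "trend": self.trend,
            "between_groups": self.between_groups,
            "sentiment_any_time": self.sentiment_any_time,
            "sentiment_nocturnal": self.sentiment_nocturnal,
            "day_night": self.day_night,
        }


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    with Path(path).open() as fh:
        return PipelineConfig.model_validate(yaml.safe_load(fh))


def format_p(p: float) -> str:
    return "<0.01" if p < 0.01 else f"{p:.2f}"


def default_units(symptom_lexicon) -> list[Unit]:
    symptoms = sorted({e.canonical_symptom for e in symptom_lexicon})
    units = [Unit.category(c) for c in sorted(lex.CATEGORIES)]
    units += [Unit.symptom(s) for s in symptoms]
    units += [Unit.nocturnal_any()]
    units += [Unit.nocturnal(s) for s in symptoms]
    return units


def build_report(
    included: Sequence[AnnotatedDialogue],
    symptom_lexicon,
    metadata: dict | None = None,
    age_bin_edges: Sequence[int] = DEFAULT_AGE_EDGES,
) -> ReportBundle:
    """Assemble every output table from an included (post-filter) corpus."""
    years = sorted({a.dialogue.year for a in included})
    year_start, year_end = years[0], years[-1]
    symptoms = sorted({e.canonical_symptom for e in symptom_lexicon})
    noct_only = lex.nocturnal_only_map(symptom_lexicon)
    units = default_units(symptom_lexicon)

    sov = build_sov_table(included, units, years)

    trend_rows = []
    n_tests = 0
    if len(years) >= 2:
        for unit in units:
            start = compute_sov(included, unit, year_start)
            if start.numerator == 0:
                logger.info("trend: %s has zero SOV in %d, CAGR undefined", unit.label, year_start)
            result = sov_trend(included, unit, year_start, year_end)
            n_tests += 1
            trend_rows.append(
                {
                    "unit": unit.label,
                    "kind": unit.kind,
                    "year_start": year_start,
                    "year_end": year_end,
                    "sov_start": result.sov_start,
                    "sov_end": result.sov_end,
                    "cagr": result.cagr,
                    "p_value": result.p_value,
                }
            )
    trend = pd.DataFrame(
        trend_rows,
        columns=[
            "unit", "kind", "year_start", "year_end",
            "sov_start", "sov_end", "cagr", "p_value",
        ],
    )

    pairs = [
        ("motor", "non_motor"),
        ("non_motor", "motor_complication"),
        ("motor", "motor_complication"),
    ]
    between_rows = []
    for year in years:
        for cat_a, cat_b in pairs:
            row_a = compute_sov(included, Unit.category(cat_a), year)
            row_b = compute_sov(included, Unit.category(cat_b), year)
            test = between_group_test(row_a, row_b)
            n_tests += 1
            between_rows.append(
                {
                    "year": year,
                    "n": row_a.denominator,
                    "group_a": cat_a,
                    "group_b": cat_b,
                    "sov_a": row_a.sov,
                    "sov_b": row_b.sov,
                    "statistic": test.statistic,
                    "p_value": test.p_value,
                }
            )
    between = pd.DataFrame(between_rows)

    def sentiment_frame(nocturnal: bool) -> pd.DataFrame:
        rows = []
        for symptom in symptoms:
            r = compute_sentiment_score(included, symptom, nocturnal_only_mentions=nocturnal)
            if r.score is None:
                continue
            record = {"symptom": symptom, "n_eligible": r.n_eligible, "score": r.score}
            record.update({f"p{g}": r.percentages[g] for g in sorted(r.percentages)})
            rows.append(record)
        return pd.DataFrame(rows)

    any_rows = [compute_sentiment_score(included, s, False) for s in symptoms]
    noct_rows = [compute_sentiment_score(included, s, True) for s in symptoms]
    day_night = compare_day_night(any_rows, noct_rows, noct_only)

    meta = dict(metadata or {})
    meta.update(
        {
            "version": __version__,
            "years": years,
            "included_dialogues": len(included),
            "included_per_year": {
                int(y): int(sum(1 for a in included if a.dialogue.year == y)) for y in years
            },
            "n_significance_tests": n_tests,
            "multiple_testing_correction": "none",
        }
    )
    return ReportBundle(
        demographics=demographics_summary(included, age_bin_edges),
        sov=sov,
        trend=trend,
        between_groups=between,
        sentiment_any_time=sentiment_frame(False),
        sentiment_nocturnal=sentiment_frame(True),
        day_night=day_night,
        metadata=meta,
    )


def _rounded(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for column in out.columns:
        if out[column].dtype.kind != "f":
            continue
        if column in ("sov", "sov_start", "sov_end", "cagr", "sov_a", "sov_b"):
            out[column] = (out[column] * 100).round(1)
        elif column == "p_value":
            out[column] = out[column].map(format_p)
        else:
            out[column] = out[column].round(1)
    return out


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every table as CSV (percent scale, one decimal) plus
    ``run_metadata.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in bundle.tables().items():
        _rounded(frame).to_csv(out / f"{name}.csv", index=False)
    with (out / "run_metadata.json").open("w") as fh:
        json.dump(bundle.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")


def config_hash(config: BaseModel) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
    write: bool = True,
) -> ReportBundle:
    """Execute the full pipeline described by a configuration file.

    ``seed`` overrides the generator seed; runs are fully reproducible from
    configuration plus seed (identical CSV bytes).
    """
    if not isinstance(config, PipelineConfig):
        config = load_pipeline_config(config)
    symptom_lexicon = load_symptom_lexicon(config.symptom_lexicon)
    sentiment_lexicon = load_sentiment_lexicon(config.sentiment_lexicon)
    windows = Windows(**config.windows)

    if config.generator is not None:
        generator = config.generator
        if seed is not None:
            generator = generator.model_copy(update={"seed": seed})
        corpus = generate_corpus(generator, symptom_lexicon, sentiment_lexicon)
        dialogues = corpus.dialogues
        used_seed = generator.seed
    else:
        dialogues = read_corpus(config.corpus_path)
        used_seed = None
    logger.info("raw dialogues: %d", len(dialogues))

    annotated = annotate_corpus(
        dialogues, symptom_lexicon, sentiment_lexicon, windows=windows
    )
    included = filter_inclusion(annotated)
    logger.info("included dialogues: %d (of %d)", len(included), len(annotated))
    if not included:
        raise RuntimeError(
            f"no dialogues passed the inclusion filter (raw={len(dialogues)}, "
            f"annotated={len(annotated)})"
        )

    bundle = build_report(
        included,
        symptom_lexicon,
        metadata={
            "config_hash": config_hash(config),
            "seed": used_seed,
            "raw_dialogues": len(dialogues),
        },
        age_bin_edges=config.age_bin_edges,
    )
    if write:
        write_bundle(bundle, out_dir or config.out_dir)
    return bundle
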
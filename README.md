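# pdlisten

Social-listening analytics for Parkinson's disease (PD) symptom dialogues.

Patient–doctor and patient–patient conversations on consulting platforms
and bulletin boards are a rich, low-burden signal of which PD symptoms
patients care about — including nocturnal symptoms (night-time rigidity,
insomnia, REM-sleep behaviour disorder, ...) that clinicians rarely observe
directly. `pdlisten` implements the full analysis pipeline for such corpora
as a reusable, tested package:

* **synthetic corpora with ground truth** — real dialogue corpora of this
  kind are not redistributable, so the package ships a generator that
  emulates their statistical structure (per-year dialogue counts,
  per-symptom mention prevalences, nocturnal context markers, graded
  sentiment co-occurrence, typos, double negations, partial demographics)
  and returns the exact annotations alongside, so every downstream stage is
  testable by parameter recovery;
* **normalization** — noisy-channel typo correction over an add-k-smoothed
  bigram language model, and paired-cancellation resolution of double
  negations;
* **annotation** — deterministic lexicon/rule tagging of symptom mentions
  (motor / non-motor / motor-complication taxonomy, greedy longest match),
  nocturnal context detection, negation flagging, graded sentiment tagging,
  and the inclusion rule (keep dialogues with ≥ 1 non-negated symptom);
* **metrics & statistics** — share of voice, compounded annual growth,
  weighted negative-sentiment scores, and Welch t-tests on dialogue-level
  indicators.

## The statistics

**Share of voice.** For a unit *u* (a symptom, a category, or the nocturnal
aggregate) in year *y* with `n_y` included dialogues of which `x_{u,y}`
carry at least one qualifying non-negated mention,

    SOV(u, y) = x_{u,y} / n_y .

A dialogue counts at most once per unit; a category's SOV is the
dialogue-level union over its member symptoms, not their sum.

**Growth.** Two-point compounded annual growth rate over `n` years:

    CAGR = (SOV_end / SOV_start)^(1/n) − 1 .

**Negative-sentiment score.** Sentiment words carry severity grades
1 (suspicion), 2 (anxiety), 3 (fear), 4 (agony), 5 (anger), 6 (sorrow).
Over the `n_e` dialogues that mention the symptom and carry at least one
sentiment word, with `p_k` the *percentage* carrying grade `k`
(multi-label, so Σp_k may exceed 100),

    score = (p_1·1 + p_2·2 + p_3·3 + p_4·4 + p_5·5 + p_6·6) / 100 ,

ranging over [1, 21].

**Tests.** SOV contrasts (across years; motor vs non-motor vs motor
complications within a year) are Welch t-tests on the 0/1 dialogue
indicators — equivalent to the unpooled two-proportion z at these sample
sizes.

## Worked example

The numbered scripts under `analysis/` run the study-scale scenario
(15,119 dialogues over 2016–2018, seeded, fully reproducible):

```sh
python analysis/01_simulate_corpus.py --seed 42
python analysis/02_annotate_corpus.py
python analysis/03_demographics.py
python analysis/04_sov_trends.py
python analysis/05_sentiment.py
```

which prints, among other things:

```
generated 15119 dialogues: 2016: 7524, 2017: 5198, 2018: 2397
injected 1490 typos and 332 double negations
...
annotated 15119 dialogues; 15114 included (100.0%)
15088 dialogues (99.8%) recover the generator ground truth exactly despite injected noise
...
motor                SOV 2016: 78.3%, 2017: 76.3%, 2018: 78.2%  CAGR -0.1% (p 0.89)
non_motor            SOV 2016: 63.0%, 2017: 65.5%, 2018: 68.5%  CAGR +4.2% (p <0.01)
motor_complication   SOV 2016: 3.2%, 2017: 6.0%, 2018: 10.3%  CAGR +78.7% (p <0.01)
nocturnal:any        SOV 2016: 40.1%, 2017: 40.4%, 2018: 45.6%  CAGR +6.5% (p <0.01)
...
nocturnal score exceeds the any-time score for 27 of 29 comparable symptoms
```

The category SOVs recover the configured generator rates (motor 79/76/79%,
non-motor 62/66/69%, complications 3/6/9%, nocturnal 39/41/45%) to within
binomial sampling error after the full normalize → annotate → filter
pipeline; the day/night contrast shows the configured effect that nocturnal
mentions co-occur with heavier negative sentiment. Tables land in
`results/tables/` as CSV.

The same pipeline is scriptable via the CLI (`pdlisten generate | annotate |
metrics | report | run-all`, see `pdlisten --help` and `configs/demo.yaml`)
or the library API:

```python
from pdlisten import study_config, generate_corpus, annotate_corpus, \
    filter_inclusion, compute_sov, Unit

corpus = generate_corpus(study_config(years=[2018], seed=7))
included = filter_inclusion(annotate_corpus(corpus.dialogues))
print(compute_sov(included, Unit.nocturnal_any(), 2018).sov)  # ~0.45
```

## Layout

```
src/pdlisten/        library: synthetic_corpus, normalize, annotate,
                     metrics, stats, report, cli (+ packaged lexicons)
analysis/            numbered narrative drivers for the study-scale run
configs/             example pipeline configurations
tests/               pytest suite (unit, property, acceptance)
scripts/acceptance.py
docs/methods.md      modelling and design notes
```
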
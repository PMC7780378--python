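# Methods

## What the pipeline models

The unit of analysis is a *dialogue*: one conversation record with a year,
a platform label, an ordered token sequence, and optionally a patient age.
All statistics are dialogue-level proportions — a dialogue either mentions
a unit (symptom, subcategory, category, nocturnal variant) or it does not,
regardless of how often. Dialogues enter the analysis only if they carry at
least one non-negated symptom mention (the inclusion rule).

Text is modelled as an abstract token sequence rather than raw natural
language. The quantities of interest are defined entirely over lexicon
terms (symptom keywords, graded sentiment words, night markers, negators),
so tokenization/segmentation is orthogonal to the analysis; for real text a
segmenter can be applied upstream and the pipeline consumed unchanged.

## Lexicons

The symptom lexicon maps token sequences (single- or multi-token terms,
with synonyms) to a canonical symptom, a category (motor / non-motor /
motor complication), a subcategory (tremor, rigidity, bradykinesia,
postural instability, sleep & sensory, cognitive & psychiatric, autonomic,
dyskinesia, motor fluctuation), and a `nocturnal_only` flag. Sleep-cycle
disturbances (insomnia, RBD, poor/fragmented sleep, nocturia, excessive
daytime sleepiness) are marked `nocturnal_only`: they exist only as
nocturnal symptoms, so every mention is nocturnal without requiring a
context marker. Sentiment words carry severity grades with a fixed
grade–label correspondence (suspicion=1, anxiety=2, fear=3, agony=4,
anger=5, sorrow=6); the loader rejects any row violating it, duplicate
terms, and categories outside the closed set, reporting line numbers.

## Normalization

**Typo correction** is a noisy-channel speller. A token is treated as a
typo when it is neither a lexicon word nor a corpus word with frequency at
least `min_count` (default 5) — so one-off corruptions, which the corpus
model has seen once, still look out-of-vocabulary. Candidate repairs are
in-vocabulary words within edit distance `max_edit` (default 1, computed
with edlib), scored by the smoothed bigram likelihood of the surrounding
window, `P(cand | left) * P(right | cand)`, under an add-k bigram model
(k = 1 by default; small vocabularies make add-one harmless) trained on the
corpus being corrected. Ties break lexicographically, so correction is
deterministic. Tokens with no candidate pass through; since every
replacement is in-vocabulary, the operation is idempotent.

**Double negation** is resolved by paired cancellation: scanning left to
right, a negation token whose next negation lies within `window` tokens
(default 3) is cancelled together with its partner, reading the pair as an
affirmation; the scan is non-overlapping. A negation without a partner is
kept, and the tagger later marks a mention *negated* when a surviving
negation token occurs within 2 tokens before its span. Negated mentions are
flagged rather than deleted (audit trail) and excluded from every count.

## Annotation

Symptom tagging is greedy longest-match, left-to-right, case-insensitive,
over multi-token terms; spans are half-open, in bounds and non-overlapping
(property-tested against an exhaustive all-substrings oracle). A mention is
*nocturnal* when a night/early-morning marker token occurs within
`nocturnal window` tokens of its span (default 5; unstated in source
material of this kind, hence configurable) or the symptom is
`nocturnal_only`. Sentiment tagging returns the *set* of grades present —
multi-label by design, because observed symptom scores above 6 are only
possible when grade percentages can sum past 100.

This deterministic tagger stands behind a minimal contract (tokens in,
mentions out) precisely so that a learned named-entity model could replace
it without touching the metrics or statistics.

## Synthetic corpus generator

The generator's defaults encode the emulated study conditions:

* per-year included dialogue counts 7524 / 5198 / 2397 (2016–2018);
* per-symptom, per-year mention prevalences equal to the published
  share-of-voice values; symptoms with no published row (dyskinesia, motor
  fluctuation, immobility, restless legs, overall difficulty breathing,
  apathy, fragmented sleep, nocturia) receive fixed small prevalences
  (0.01–0.06, chosen once as clinically plausible for consultation
  dialogues);
* demographics attached with probability 2895/15119 ≈ 0.19, ages drawn from
  N(63, 13.4²) truncated at 18 and rounded to whole years;
* token noise: each lexicon token corrupted with probability
  `typo_rate` (default 0.02) by a single random edit constrained to be at
  least two edits from every other vocabulary word — corruptions are
  unambiguous by construction, which is what makes correction accuracy
  well-defined; each mention wrapped in a double negation with probability
  `double_negation_rate` (default 0.01);
* graded sentiment words co-occur with symptom mentions per independent
  per-grade Bernoullis (a global default mixture plus per-symptom
  overrides; psychiatric symptoms heavier, tremor lighter), and nocturnal
  mentions add draws from a heavier high-grade boost mixture — the
  generative counterpart of the observation that night-time symptoms evoke
  stronger negative sentiment.

**Aggregate calibration.** Category-level rates (motor 79%, non-motor 69%,
complications 9% in 2018) are unions over *correlated* per-symptom
indicators in real data; independent Bernoullis at the published
per-symptom rates would give a motor union near 83%. When
`category_prevalence` is configured, category presence is therefore drawn
first — motor from the bottom of a shared latent uniform and non-motor from
the top, motor complications independently — making the configured category
rates exact and, whenever the motor and non-motor rates sum to ≥ 1,
guaranteeing every dialogue at least one symptom (so the included count
equals the configured raw count). Member symptoms of a present category are
then drawn conditioned on non-emptiness, preserving relative composition;
within-category marginals are consequently scaled by the calibration and
are not individually recoverable in this mode. Similarly,
`nocturnal_aggregate` draws a per-dialogue nocturnal indicator: nocturnal
dialogues are guaranteed one nocturnal mention, non-nocturnal dialogues
carry none (and no nocturnal-only symptoms). The plain independent mode
remains the default and is the one whose per-symptom rates converge to the
configured prevalences within binomial error.

Randomness is one counter-based stream per dialogue (corpus seed, year,
index), so any dialogue can be regenerated independently of order and
identical configurations produce byte-identical corpora.

**Ground truth** is defined as the exact annotation of the clean
(pre-noise) token sequence — nocturnal flags are recomputed with the same
context detector used downstream, so a dialogue whose night marker falls
inside a neighbouring mention's window is truthed the way a perfect tagger
would read it. On noise-free corpora the annotate stage reproduces the
ground truth verbatim (tested); with noise, recovery is measured against
the recorded corruption ledger.

**What the generator does not emulate:** real Mandarin text and its
segmentation ambiguity; dialogue threading and doctor/patient turns;
correlation between symptom burden and age; the empirical (non-normal)
shape of the age distribution within bins; platform-specific vocabulary.
Passing recovery tests therefore demonstrates that the pipeline's
arithmetic and rules are correct under the study's statistical structure,
not that the tagger would match a trained model's accuracy on real text.

## Numerical and design choices

* CAGR is the standard two-point compounded rate; with published values it
  is computed over n = 2 years (2016→2018). A zero starting value raises an
  explicit undefined-growth error rather than returning an infinity.
* Sentiment scores are undefined (absent), not zero, when no dialogue is
  eligible; with any eligible dialogue the score lies in [1, 21].
* The day/night sentiment contrast covers only symptoms that are not
  exclusively nocturnal and attaches no significance claim.
* "t-tests" on proportions are Welch t on the 0/1 indicators: unpooled
  variances, Welch–Satterthwaite df, two-sided p. Both samples constant and
  equal gives statistic 0, p 1 (degenerate-variance rule). Between-group
  comparisons within a year treat the two indicator vectors as independent
  samples, mirroring the emulated study's design even though the indicators
  share dialogues; a paired test would be the natural alternative. No
  multiple-testing correction is applied (none was applied in the emulated
  design); the report metadata records the number of tests performed.
* Percentages and proportions are carried at full precision and rounded
  only when tables are written (one decimal; p-values below 0.01 shown as
  "<0.01").
* Problem sizes: the packaged analysis scripts run the full 15,119-dialogue
  scenario (a few seconds); tests and the acceptance script use one-year
  corpora of 400–2,397 dialogues and 500–1,000 Monte-Carlo replicates for
  test calibration, sizes at which binomial error bands are tight enough to
  be informative.

## Known limitations

* The generator's calibrated mode fixes category and nocturnal aggregates
  exactly but only approximates within-category composition; per-symptom
  recovery guarantees apply to the plain mode.
* The bigram corrector assumes corruptions are rare relative to their clean
  forms; at extreme typo rates (≫ 0.1) repeated identical corruptions can
  cross the frequency threshold and be treated as vocabulary.
* Negation handling is window-based, not syntactic; long-range negation
  scope is out of reach by construction.
* The published growth figures for aggregate rows equal percentage-point
  SOV differences rather than two-point CAGRs, and a handful of low-SOV
  symptom rows are reproducible only from unrounded inputs; the acceptance
  tests document both facts.
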
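# Methods

## Model

`radtriage` treats report prioritization as two-class text
classification with high-priority as the positive class. A report's
features are the unique tokens surviving the preprocessing pipeline —
presence/absence only, no counts, following the Bayesian spam-filter
lineage this design descends from. Under the naive independence
assumption the posterior that a report is high-priority is

    P(H | f₁…f_k) = P_p L_H / (P_p L_H + (1 − P_p) L_L),
    L_H = Π_i P(f_i | H),   L_L = Π_i P(f_i | L)

with P_p the prior probability of a high-priority report. Conditionals
are smoothed per-class document frequencies,
`P(f|H) = (d_H(f) + α)/(n_H + 2α)`, clamped into
`[clamp_low, clamp_high]`. A report is labeled high when the posterior
reaches the threshold P_th (inclusive: a posterior exactly at P_th is
high, reading the threshold as the *minimal* probability at which a
report counts as important).

Numerical notes:

- Likelihood products are accumulated as sums of logs and the posterior
  is formed from the log-odds with a branch on sign, so bags of any
  size can neither underflow nor lose precision near 0 or 1. Tests
  verify agreement with a direct product evaluation to 1e-12 on small
  problems and 1e-9 on 20-feature bags.
- The empty bag yields the empty product (L_H = L_L = 1), so a fully
  negated normal report scores exactly the prior. This is intended
  behavior, not an edge case: the preprocessing pipeline is designed to
  drive normal reports toward empty or phrase-only bags.
- Features absent from the training vocabulary are skipped. Because the
  two class tables share one vocabulary, skipping is equivalent to
  assigning any common neutral constant, and it keeps a model's scores
  stable when applied to text with novel vocabulary.
- Degenerate priors 0 and 1 return 0 and 1 exactly rather than
  evaluating log(0).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `prior_pp` | 0.5 | prior probability a report is high-priority; raising it biases toward flagging (fewer false negatives, more false positives) |
| `threshold_pth` | 0.8 | minimal posterior flagged as high-priority; typically > 0.5 |
| `smoothing_alpha` | 1.0 | Laplace pseudo-count in the document-frequency estimate |
| `clamp_low`, `clamp_high` | 0.01, 0.99 | bounds on stored conditionals; prevent a single rare feature from annihilating the product |

Because the posterior distribution is strongly bimodal on separable
corpora, results are insensitive to the exact operating point; the
defaults favor minimizing false negatives, the clinically costly error.

## Preprocessing pipeline

Order is fixed and load-bearing:
lowercase → merge common phrases → remove negated scopes → tokenize →
drop stop words → deduplicate.

- **Phrase merging before negation removal.** Stock normal phrases
  ("no acute cardiopulmonary process", "within normal limits") are
  collapsed to single whitespace-free tokens first; many carry their
  own negation and would otherwise be destroyed by the scope remover.
  The shipped list is the package's versioned default and is
  configurable; matching is case-insensitive, whitespace-normalized,
  longest-match-first.
- **Negation scope.** A trigger deletes itself and all following tokens
  up to (exclusive) the first sentence terminator (`.` `;` `:`), a
  scope-breaking conjunction (*but*, *however*, *although*), or end of
  text. Whole-scope removal within the sentence is the simplest rule
  consistent with the worked examples ("no acute lung disease" → empty;
  "chest is without evidence of pneumonia" → "chest is"); an optional
  `max_scope_len` caps the scope. Default triggers: *no*, *not*,
  *without*, *denies*, plus the multi-word *negative for*, *free of*,
  *rather than*, *ruled out* (matched before single-word triggers).
  Bare *negative* and *free* are deliberately not triggers: "negative
  according to the nci model…" is benign narrative whose content must
  survive — treating *negative* as a trigger would hide exactly the
  false-positive mode worth studying.
- **Tokens** are maximal alphanumeric runs, minimum length 2, pure
  digits dropped (keeps residual numerics and stray single letters out
  of the vocabulary). Stop words are a fixed packaged list of ~120
  English function words; removal mainly de-clutters the vocabulary.
  No stemming, lemmatization or n-grams beyond the phrase list.

The PHI scrubber (dates, phone numbers, digit runs ≥ 5, a configurable
name/facility lexicon; matches replaced by a space, applied to a
fixpoint so it is idempotent) is a simplified stand-in adequate for
synthetic text — it is **not** a certified de-identifier and must not
be relied on for real PHI.

Section extraction accepts IMPRESSION / CONCLUSION / IMPRESSIONS /
FINDINGS AND IMPRESSION headers (configurable, priority-ordered,
case-insensitive, at start of line, optional colon) and ends the
section at the next all-caps `HEADER:` line. Reports with no recognized
header are processed whole-body.

## Synthetic corpus generator

Real report corpora are PHI-protected, so training and evaluation run
on generated corpora that emulate the statistical structure of a
primary-care radiology stream:

- 354 reports with 92 high-priority (26% prevalence) and the modality
  mix 35 mammograms / 36 CTs / 71 plain films / 70 ultrasounds /
  142 MRIs by default; a balanced 100-report (50/50) corpus for
  training. Counts are apportioned deterministically
  (largest-remainder), then shuffled by the seeded generator.
- Low-priority impressions contain 1–2 stock normal phrases plus, at
  `negation_rate` (default 0.8), negated-finding sentences that vanish
  during preprocessing — so normal bags are empty or phrase-only.
- High-priority impressions contain 1–3 positive finding phrases
  (nodules, masses, infiltrates, actionable recommendations).
- At `confuser_rate` (default 0.05) a low-priority report instead
  carries a benign risk statement ("…lifetime risk of developing breast
  cancer is 3.6%"). Templates vary their statistical boilerplate but
  share the salient disease terms, so a trained model usually sees the
  benign wording as out-of-vocabulary while the disease terms score
  high — making confusers the dominant false-positive source, the
  error mode a practitioner should expect from this classifier family.
  Default rates produce false-positive counts of order 10–20 per 354.
- Reports carry planted PHI-like strings (dates, record numbers,
  facility names drawn from the scrubber's lexicon) and, at rate 0.03,
  omit the IMPRESSION header to exercise the whole-body fallback.
  Skeleton dialects (section labels, boilerplate wording) vary between
  reports, as they would across referring hospitals; this also keeps
  the fallback path from injecting a block of perfectly correlated
  boilerplate tokens into every headerless report.

What the generator does **not** emulate: realistic clinical language
(vocabulary is a few hundred words, not the hundreds of unique words
per real report), radiologist style variation, dictation/OCR noise,
label ambiguity between physicians, or findings whose priority depends
on context rather than vocabulary. Passing tests therefore demonstrate
that the pipeline and classifier behave correctly on a separable
corpus of this structure — not that these accuracy figures transfer to
clinical text.

## Evaluation

Precision = TP/(TP+FP), recall = TP/(TP+FN), F-measure = harmonic mean
of the two (computed from unrounded values), accuracy = (TP+TN)/total,
FN rate = FN/total; all reported as percentages, rounded to two
decimals only at presentation. Zero-denominator metrics surface as
explicit `undefined`, never as 0 or 100, so threshold sweeps cannot be
silently corrupted. Operating-point grids score each report once (the
per-class log-likelihoods are prior-independent) and then apply every
(prior, threshold) pair, guaranteeing consistency with the one-shot
classify path. Cohen's kappa for inter-rater agreement is included;
the package's implementation is cross-checked against scikit-learn in
the test suite.

## Problem sizes

The shipped tests and the acceptance script use the study-shaped sizes
throughout — 100-report training corpora, 354-report evaluation
corpora, posterior-oracle enumeration over vocabularies of ≤ 4 features
and ≤ 8 training documents, and 50-point prior/threshold grids — which
the package's own choice of corpus scale makes fast enough to run
end-to-end in seconds.

## Known limitations

- Negation handling is trigger-and-scope only; it has no notion of
  pseudo-negation ("no change in the known mass" removes the finding)
  or of negation expressed beyond the trigger list.
- The phrase list is a small fixed default; real deployments would
  curate site-specific lists.
- Presence/absence features discard within-report term frequency.
- The classifier is batch-trained; it does not learn online from
  physician feedback.
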
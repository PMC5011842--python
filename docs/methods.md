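# Methods

`stagemine` classifies short, dated free-text communication log notes —
written by an implementation broker about sites adopting an evidence-based
program — into the discrete stages of the adoption process, and summarizes
each site's timing through those stages. This note documents the model, its
parameters, the numerical choices, and what the synthetic study used in the
tests does and does not establish.

## Data model

Two corpora enter the analysis. The *stage descriptions* are the definition
sentences of the staging instrument, one set `A_i` per stage `i = 1..S`.
The *log corpus* holds per-site, date-ordered notes; a small fraction
carries an expert stage label, the rest are unlabeled. Stages at or beyond
a configurable cutoff (default 4) are pooled into a single "4 or later"
category for classification, matching the heavily imbalanced occupancy of
late stages in multi-site trials where most sites stall early.

Dates are calendar dates (ISO 8601); same-day notes within a site are legal
and keep their input order (real logs frequently contain several entries
per day, so strict temporal ordering is not enforced).

## Deidentification

Scrubbing runs on the raw, case-preserving text before any tokenization.
Listed person names, phone numbers, and email addresses become stable
numbered placeholders (`person001`, ...), one per distinct matched string.
Name matching uses a case heuristic: a listed name is replaced only when it
appears with an initial capital; lowercase occurrences are assumed to be
ordinary words (the name "Bill" versus an invoice "bill"). We apply the
rule uniformly, including at sentence starts, preferring a false
replacement of a capitalized homograph over leaking a name. Scrubbing is
idempotent, and because the tokenizer later drops any token containing a
digit, placeholders can never become classifier features.

## Features

Tokens are maximal alphanumeric runs; purely alphabetic tokens are
lowercased and reduced with the classic Porter suffix-stripping algorithm
(implemented in-package and tested against the algorithm's published worked
examples). No stopword removal is applied by default — keyword selection
already restricts the feature space — but a stopword list can be supplied.
Features are unigram stems only; a bigram flag exists in the design space
but is deliberately left out of the default method.

Per stage, keywords are selected greedily under a max-relevance /
min-redundancy criterion. The relevance of candidate stem `w` to stage `i`
is the cosine between the vector of `w`'s per-document counts over `A_i`
and the vector of per-document total word counts; the redundancy of `w`
against an already selected keyword is the cosine of their count vectors.
Step `k` selects the candidate maximizing
`relevance(w) − (1/(k−1)) · Σ_p sim(w, w_p)`; at `k = 1` the redundancy
term is defined as 0 (the standard convention for the first pick). Ties
break to the lexicographically smallest stem so selection is deterministic.
The total keyword budget (default `K = 20`, the operating point at which
accuracy peaks before low-ranked keywords begin to blur the classes) is
split evenly across stages; a pooled budget is available through
configuration. A keyword selected by exactly one stage is a *labeled
keyword* with that stage as its label; keywords claimed by several stages
stay unlabeled, since stage describers and note writers need not use terms
the same way.

Each note (and, by default, each description sentence, appended as a
labeled row) becomes a row of the L×K matrix `X`: counts of each keyword
among the note's stems, divided by the note's total keyword count, so every
row with at least one hit sums to exactly 1. The denominator is the
*keyword* total, not the word total — only that normalization makes rows
exactly row-stochastic. Notes hitting no keyword stay as all-zero rows and
are flagged; an optional uniform-row imputation exists but is off by
default, and zero rows end up with uniform stage probabilities after the
final normalization, which is the honest statement of ignorance about them.

## Semi-supervised tri-factorization

The classifier solves

    min_{F,H,G ≥ 0}  ‖X − F H Gᵀ‖²_F
                     + α · tr((F − F₀)ᵀ C₀ (F − F₀))
                     + β · tr((G − G₀)ᵀ C₁ (G − G₀))

with `F` (L×S) the note→stage weights, `G` (K×S) the keyword→stage weights,
and `H` (S×S) a stage-correlation mixing matrix. `F₀`/`G₀` hold the one-hot
partial labels and `C₀`/`C₁` are their diagonal indicator masks. `α = β =
1` by default: the expert labels are trusted, and smaller values are the
right knob when labels are noisy. Orthogonality of `F` and `G` is *not*
enforced.

Minimization uses multiplicative updates applied `F → H → G`, each using
the most recent factors. The default denominators are the
auxiliary-function (Lee–Seung-type) forms

    F ← F ⊙ (X G Hᵀ + α C₀ F₀) / (F (H GᵀG Hᵀ) + α C₀ F)
    H ← H ⊙ (Fᵀ X G)           / (FᵀF H GᵀG)
    G ← G ⊙ (Xᵀ F H + β C₁ G₀) / (G (Hᵀ FᵀF H) + β C₁ G)

for which each update minimizes a quadratic upper bound of the objective,
so the objective is non-increasing at every iteration — a property the test
suite verifies over 50 seeded random problems together with the KKT
stationarity residual `max |(∂J/∂F) ⊙ F|` at convergence. An alternative
`update_rule="projection"` provides the orthogonality-derived denominators
(`F FᵀX G Hᵀ + α C₀ F`, and analogously for `G`); since orthogonality is
not enforced here, that variant carries no descent guarantee — we measured
objective increases in roughly a third of its iterations on random problems
— and it exists for comparison only, not as the default.

Numerical choices:

- Initialization: entries uniform in (0.1, 1.1) for `F` and `G` (strictly
  positive — zeros are absorbing under multiplicative updates), `H` as
  identity + 0.1, and labeled rows of `F` warm-started as a 50/50 blend of
  `F₀` and random mass. All randomness flows from a single integer seed.
- Denominators are stabilized by an additive `ε = 1e−12`.
- Stopping: relative objective change below `tol` (default `1e−6`) or
  `max_iter` (default 500). The objective trace is recorded every
  iteration using the algebraic expansion
  `‖X − FHGᵀ‖² = ‖X‖² − 2⟨XᵀFH, G⟩ + ⟨HᵀFᵀFH, GᵀG⟩`, which shares the two
  large matrix products with the updates; the iteration loop is compiled
  with numba when available (a pure-numpy loop is the fallback), and a test
  pins the compiled loop to the reference `update_step` to 1e−9.
- Entries that decay toward zero are floored at `1e−100` inside the
  compiled loop: mathematically they are zero at working precision, and the
  floor keeps late iterations out of subnormal arithmetic, which is an
  order of magnitude slower.
- Rows of `F` and `G` are normalized to probability vectors once, *after*
  convergence. The updates do not preserve row-stochasticity, and
  renormalizing inside the loop would break the descent guarantee. All-zero
  rows become uniform `1/S`. The KKT residual is evaluated on the
  un-normalized factors, where the stationarity condition actually holds.

## Temporal summaries

Stage probabilities are pooled into categories by summation and the argmax
(lowest index on ties) is the note's stage call. Per site:

- **Stage intervals.** A stage's interval opens at the first note of a run
  of at least `min_run` consecutive notes with `p_stage ≥ threshold`
  (defaults 0.5 and 2) and closes at the run's last note; disjoint runs
  model re-entry. This sustained-threshold rule was chosen over a formal
  change-point model because the observed signature of a stage is a
  sustained rise then fall of its probability; an optional moving-average
  smoother is available. Interval endpoints are the dates of the
  qualifying notes themselves.
- **Attainment flags.** A site is flagged for stage `s` if any of its notes
  is called at or beyond `s`; among a designated subset of sites (e.g.
  those whose ground truth never reached `s`) the flag rate is an
  over-projection (false-flag) rate, reported as a percentage.
- **Transitions.** Maximum-likelihood Markov transition matrices over
  consecutive note categories (notes are the observed process; calendar
  gaps between them are ignored). Rows without observations stay zero and
  are flagged; Laplace smoothing is available but off by default.

## Synthetic study

The generator emulates the structure of a 40-site implementation trial at
roughly one-tenth scale: 4 stage categories, ~460 notes, stage-specific
vocabularies of 20 synthetic stems, notes of ~15 words with a 5 %
background-noise word rate, 10 % expert-labeled notes, 6 description
sentences of 8 words per stage, stage durations around 90 days, and 31/40
of sites stalling at stage 3. Words are pronounceable consonant–vowel
stems constructed to be Porter fixed points, so ground truth does not
depend on stemmer behavior. Adjacent stages share `overlap_fraction` of
their vocabularies; description sentences draw from the full stage
vocabulary with core (unshared) words up-weighted 4:1, so the definitions
emphasize distinctive milestones yet grow more confusable as overlap
rises — with purely core-word definitions, overlap would leave selected
keywords perfectly stage-specific and accuracy essentially flat, which is
not how real, partially overlapping stage definitions behave. Per-category
note counts can be pinned to an exact target shape for table reproduction.

What passing the synthetic tests shows: the full pipeline recovers known
stage structure (note accuracy ≥ 0.95, interval boundaries within ±1 note
for ≥ 90 % of episodes at disjoint vocabularies; accuracy ≥ 0.7 at 30 %
overlap) and every component is deterministic under a fixed seed. What it
does not show: performance on natural English — real notes have grammar,
typos, polysemy, and broker-specific style the bag-of-stems generator does
not model — nor robustness to mislabeled expert codes or to stage
definitions that diverge in register from the notes.

## Known limitations

- Notes are classified independently; no information is shared across a
  site's consecutive notes at classification time.
- The multiplicative updates converge linearly and slow near stationary
  points; tight tolerances (1e−10) can take 10⁵–10⁶ iterations on small
  problems, which the compiled loop makes affordable.
- Zero-keyword notes are uninformative by construction; their uniform
  probabilities can split interval runs if they cluster.
- The interval rule reports note-dated boundaries; with sparse logging the
  true calendar boundary may precede the first qualifying note by days.
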
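# Methods

This note documents the models, conventions and design choices behind
`egolens`: what each computation assumes, which parameters matter, what
the synthetic cohort does and does not emulate, and where the design was
genuinely open.

## Data model

One participant (ego) is a bundle of: up to two personal-network waves
(`pre`, `post`), a prompt schedule, momentary responses, interaction
events, and a roster — the union of all alters ever seen, each tagged
with its provenance (`wave1`, `esm`, `wave2`). Alters carry a social
role (family, friend, romantic partner, fellow student/colleague,
acquaintance, other), gender, a decade age bracket, ordinal ratings and
four dichotomous relationship items (emotional support, practical
support, "can be myself", "discuss personal issues"). Age is stored as
brackets rather than years: feedback narratives need "a friend in her
20s", not a birthdate, and coarse ages reduce re-identification risk.

Rating scales live in a single registry: closeness, interaction quality
and affect share a 0–10 scale; contact frequency is a 7-point ordinal
(0–6). Quality scores are conventionally integers (people rate "7 out
of 10"); affect is stored to one decimal.

Two conventions matter downstream:

* **Non-compliance is a record, not an absence.** An unanswered prompt
  is a `MomentaryResponse` with `response_time=None`, keeping the
  compliance denominator explicit.
* **Interactions shorter than 5 minutes are not logged** — the
  event-contingent rule; the validator enforces `duration_min >= 5`.

Validation reports violations (severity, code, subject) instead of
raising, so a partially broken export can still be inspected. Name
matching when registering a partner typed during ESM is exact after
case-folding and whitespace collapsing — no fuzzy matching, because a
silent wrong merge is worse than a duplicate a user can merge by hand.

## Schedules

The default design is 28 days × (2 semi-fixed + 4 semi-random) prompts.
"Semi-random" is operationalised as block randomisation — the daytime
window (default 10:00–20:00) is split into `n_random` equal blocks with
one uniform draw each — plus a 30-minute minimum gap between any two
same-day prompts. The gap is enforced by bounded rejection re-sampling
within the block (which approximately preserves the uniform marginal)
with a deterministic push-apart fallback, and infeasible configurations
(`n_random × gap >` window length) are refused. Morning/evening window
defaults (08:00–10:00, 20:00–22:00) are configuration, not claims about
any particular study. Weeks for compliance are aligned to study day 1
(days 1–7, 8–14, …). Event-contingent logs are participant-initiated
and therefore never enter the compliance denominator; they are counted
separately.

## Reconciliation

The post wave is seeded from the pre wave (all ratings carried) plus
every ESM-encountered partner (ratings blank), so alter ids are stable
across waves by construction. Reconciliation is then set algebra on
ids: in both waves → stable; pre only → removed; post only → added
(split by whether the alter was first seen in the ESM roster). An
ESM partner absent from the post wave is classed removed with a
warning — the case is not covered by the seeding flow's narrative, and
flagging beats guessing. Renames are rating edits, never turnover.
Rating deltas are reported for ordinal items rated in both waves and
only when nonzero; dichotomous items are reported as flipped/unflipped.
Tie turnover between waves is computed but labelled exploratory.

## Metrics

* **Counts.** A multi-partner event increments every listed partner and
  each partner's role once per partner. This is deliberate (the
  per-partner panels require it) and documented wherever sums are
  shown; only one-on-one events keep role sums equal to event counts.
* **Confidence intervals.** Two-sided 95% t-intervals
  (`mean ± t(0.975, n−1)·s/√n`); the normal approximation is available
  by config. With n < 2 no interval is reported rather than a
  degenerate one. Groups are ordered by descending n, then key, for
  stable display.
* **Perception vs. behaviour.** The discrepancy flag defaults to
  "closeness at or above the 2/3 quantile of the wave's closeness
  ratings and zero interactions". The threshold and the interaction
  cut-off are parameters; the table echoes all inputs because the rule
  is a conversation starter, not a verdict.
* **Structure.** Connected components and isolates of the undirected
  tie graph (via networkx), components ordered by size.
* **Word frequencies.** Unicode word tokens, lowercased, no stemming;
  numbers and underscores excluded by the token pattern. Shipped
  stop-word lists for English and Dutch plus an exclusion list of
  'talking' verbs (every diary entry is about talking; those words
  carry no content). Explicit lists override the defaults.
* **Timeline.** Prompt-level and event-level affect are merged into one
  series, each point tagged with its source, since both are genuine
  momentary assessments; consumers can split them. The partner filter
  applies to interaction points only — mood is a property of the ego,
  not of a partner.

Anonymisation (seeded pseudonym permutation, optional text redaction
and uniform date shift) touches only labels by default, so every metric
is invariant under it; this is tested bit-for-bit.

## Synthetic cohort

The simulator generates the structure the feedback is designed to
reveal, from one seeded generator (fully deterministic per config):

* **Network**: default 42 alters (valid range 10–80), roles drawn from
  a default mix of 46% friends, 24% family, 15% fellow students, 13%
  acquaintances, 2% other, at most one romantic partner; closeness
  centred per role (family ≈ 7, friends ≈ 6, acquaintances ≈ 2).
  Ties are role-clustered: within-role density 0.80 for family, 0.35
  for friends, lower elsewhere; 0.04 between roles. This yields the
  familiar picture of a tight family cluster plus isolates.
* **Interaction quality**: each alter i has an integer latent mean
  μᵢ = clip(round(1.5 + 0.7·closenessᵢ + N(0, 0.8)), 0, 10); event
  scores are N(μ, σ) (σ default 1.5, per-event μ the mean over the
  event's partners), clamped to [0, 10] and rounded to integers. With
  σ = 0 observed scores equal μᵢ exactly, which anchors the recovery
  diagnostics.
* **Partner selection**: categorical with weight ∝ exp(closeness/τ),
  τ = 2 by default — a heavy-tailed per-partner count profile where a
  couple of close friends dominate. Group events (probability 0.2)
  add 1–3 co-partners from the primary partner's tie-graph component:
  people who know each other co-occur.
* **Affect**: AR(1) around baseline b = 7 with φ = 0.5, innovation sd
  1.0, plus coupling γ·(q̄ − 5) where q̄ is the mean quality of
  interactions since the previous prompt (γ default 0.3; the term is
  dropped when there were none). With φ = γ = 0 the series is white
  noise around b; with γ = 0 affect is uncorrelated with same-window
  quality; with γ > 0 prompts preceded by high-quality interactions
  show elevated mood — exactly the pattern the timeline is meant to
  surface.
* **Scenarios**: `breakup` (partner's effective closeness drops at
  mid-study; re-rated as friend post), `growth` (k partners first met
  during ESM, each introduced by a forced first interaction on a random
  study day), `growth_post` (members added only at the post
  assessment), `removals` (m members dropped post, drawn from
  peripheral roles).
* **Diary text**: short sentences from a topic vocabulary whose head
  (food, plans, going) dominates, so term-frequency output looks like
  real diaries.
* Compliance is Bernoulli per prompt (default 0.85); the latent mood
  process advances through unanswered prompts.

What the simulator does **not** emulate: answer styles and scale-use
heterogeneity, time-of-day and weekday rhythms, reactivity to being
measured, missingness that depends on mood, and any demographic realism
beyond role/age/gender marginals. Passing tests therefore demonstrate
that the pipeline computes what it claims on data with the assumed
structure — not that the feedback is clinically valid for real
participants.

## Numerical and testing choices

* Quality means and CIs are plain floating point; no rounding is
  applied except for display (4 decimals in the report payload).
* The CI-coverage diagnostic pools 50 small high-rate simulations
  (10 alters, 28 days, ~14 interactions/day, near-uniform partner
  weights) so ~500 alters accrue ≥ 30 events each; t-interval coverage
  of integer latent means stays within a few points of 95% despite
  rounding and clamping because latent means sit well inside the scale.
* Reconciliation is verified against plain set algebra on every
  structurally distinct membership pattern up to 12 alters (all
  count-compositions over the 7 possible (pre, post, esm) membership
  combinations) plus 200 random larger fixtures; component detection is
  verified against a union-find oracle.
* Bundle writes are byte-deterministic (sorted JSON keys, fixed column
  order, `\n` newlines), giving `read(write(x)) == x` and stable
  re-exports; schema versions other than the current one are refused,
  never guessed.
* The HTML report embeds the payload as JSON and draws views with
  self-contained vanilla JS/SVG; rendering is a pure function of the
  payload (identical payload → identical bytes) and displays only
  payload fields. The simple timeline mode drops role-colour and
  group-shape encodings in favour of a bare mood line with uniform
  interaction dots; per-section free-text annotations support a
  commented hand-over of the report.

## Known limitations

* The feedback is descriptive by design: no regression or multilevel
  modelling of the affect–interaction association is provided, and none
  is planned — the report supports a conversation, not inference.
* Only single-ego data; sociocentric designs, directed or weighted ties
  are out of scope.
* One wave degrades the report gracefully, but network-change questions
  are then genuinely unanswerable and reported as such.
* Importers for proprietary ESM platforms are not included; the bundle
  schema is this artifact's own.
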
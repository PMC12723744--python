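# Methods

This note documents the procedures `clonecoord` implements, the parameters
that matter, the numerical choices made where the design was open, and what
the synthetic-data generator does and does not emulate.

## Data model

A campaign ("instance") is a directory of UTF-8, RFC-4180 CSV tables — one
per record type (oligos, dsdna, assemblies, transformations, minipreps,
sequencing, registry, experiments, plus an optional alerts log) — and a
`settings.yaml`. Records reference each other by id; `validate_instance`
checks id well-formedness, per-prefix serial uniqueness, closed-set enum
membership, day-resolution ISO dates, and referential integrity, and
returns one issue per violation naming table, row, field, and rule.

Design choices:

- **Loose loading, strict validation.** Malformed enum or date cells load
  as their raw strings so that validation can *report* them; a crashing
  loader cannot. Downstream computations assume a validated instance.
- **Day resolution.** All dates are calendar dates. Operations are logged
  to the nearest day, so elapsed times are integer days and storage
  durations quantize.
- **Append-only serials.** Serials are never reused; removal is a `voided`
  flag, preserving the audit trail. Derived quantities (statuses, outcome
  classes) are never persisted — they are recomputed on demand so they can
  never go stale.
- **Extra columns** unknown to the schema are preserved verbatim through a
  load/save round trip, which is byte-identical after one canonicalization
  pass.
- **Storage arithmetic.** Slots fill column-major — position within an
  8-tube strip first, then the 12 strips of a plate, then the next plate —
  matching strips labeled by plate and column. The layout (8×12) is
  configurable; serial ↔ (plate, column, position) is a bijection.

## Status engine

A minimal deterministic state table covers the attested transitions; all
statuses derive from logged fields only.

- dsDNA: `ready:purify` → (`ready:gel` if required) → `ready:quantify` →
  `complete`; a gel code whose configured quality class is failing stalls
  the fragment (`stalled:pcr_failed`) at any stage. External fragments need
  only a concentration.
- Assembly: `ready:assemble` when all parts are complete and no date is
  logged; stalls immediately when any part stalls (no retry budget — a new
  attempt is an explicit re-queue); `ready:transform` once assembled;
  `stalled:no_colonies` when the latest plate scored zero;
  `stalled:screening_exhausted` when clones were picked and every one
  stalled on QC; `complete` + `verified` once a linked miniprep's governing
  read reports all parts present.
- Miniprep: gel first (if `require_miniprep_gel`), then sequencing (if
  `sequencing_mandated`); the **largest-serial** read governs: full
  verification completes, a defect interpretation stalls with that
  interpretation as the reason, a partial verification or failed read sends
  the clone back to `ready:sequence`.
- Construct: `complete` iff any linked assembly is verified;
  `needs_intervention` iff nothing is ready or in flight for it; else
  `in_progress`. The three states partition the registry; the value is
  computed, never stored.
- The verified marker is a boolean field, not a character embedded in a
  status string.

**Cross-construct evidence.** For a part, `part_evidence` counts the other
assemblies using it, how many are verified, and how many gave a nonzero
colony-count category — verification of a sibling construct is strong
evidence the shared part is sound even without direct QC, and colony
counts serve as a weaker proxy.

## Dashboard

One summary per task in pipeline order (purify, quantify, gel, assemble,
transform, miniprep, sequence). Highlights are pure functions of counts,
dates, and settings:

- `batch`: ready count **strictly greater** than the per-task
  `batch_threshold` (default 8) — batching is what makes multichannel and
  premix work pay off;
- `priority`: any ready sample traces to a priority-flagged construct;
- `stale`: the task's last logged completion is at least `staleness_days`
  old (default 14 — the rule needed a number and two weeks is a reasonable
  pipeline-balance horizon), or it was never done while work is waiting.
  Staleness counts from the last logged completion, not the last highlight.

Experiment evaluation replaces email with an append-only alert log. Events
are deduplicated on (experiment, kind, construct, hash of all member
states), so re-evaluating an unchanged campaign emits nothing, while any
genuine state change fires exactly once.

## Golden Gate validation

Parts chain through enzyme-generated 4-base overhangs (length configurable;
4 is the common Type IIS default). A design is valid iff (a) each part's 3′
overhang equals the next part's 5′ overhang, cyclically; (b) junction
overhangs are mutually distinct; (c) no junction overhang equals the
reverse complement of another, *itself included* — a palindromic overhang
ligates to its own complement on another molecule. Violations name the
junction pair and rule. The validator is tested against a brute-force
enumerator of all junction pairs and orientations. Enzyme recognition-site
scanning of part sequences is out of scope: the registry stores overhangs
directly.

## Calculators

- **Molarity**: 1 ng/kb/µL of dsDNA = 1.623 nM, equivalent to a mean
  double-stranded base-pair molar mass of ≈616 g/mol.
- **Equimolar pooling**: by default the *combined* pool is brought to the
  target (7.5 ng/kb/µL in 5 µL by default), each part contributing an equal
  molar share; `per_part=True` instead brings each part individually to the
  target. Because every required part volume scales proportionally with the
  final volume, infeasibility depends only on concentrations — the error
  therefore reports the limiting part and the maximum achievable target
  concentration rather than a "minimum feasible volume", which does not
  exist for this geometry.
- **Premix scaling**: each component × n × (1 + overage); the per-reaction
  aliquot is the recipe sum (5 µL for the standard USER 2× premix of
  2.5 µL water, 1 µL 10× Cutsmart, 0.75 µL DpnI, 0.75 µL USER enzyme mix).

## Analytics

**Transformation matching.** An explicitly recorded source transformation
wins. Otherwise, among the miniprep's assembly's transformations dated on
or before the inoculation date, the largest serial wins; none qualifying →
unmatched. Date ties anywhere resolve by serial (serials are the finer
clock, since dates are day-quantized).

**Gel classes.** `single_band_expected_size` and
`supercoiled_plus_relaxed` → likely correct; `band_absent`, `smear`,
`wrong_size`, `multiple_bands` → likely incorrect; `not_run` / missing →
ambiguous. The mapping lives in settings (`gel_quality_flags`).

**Reconciliation.** Per miniprep the largest-serial read governs. Full
verification makes that clone correct and — deliberately — does *not*
upgrade its set-mates' gel-based calls. A defect interpretation (anything
other than some/all-parts verification or a failed read) makes the clone
incorrect; when that defect **refutes** a gel call of likely-correct on the
sequenced clone itself, the gel evidence for the whole set is discredited
and the other members' gel-based likely-correct calls are demoted to
incorrect. A defect read that merely confirms an already-failing gel
refutes nothing and leaves the others alone. A partial verification or
failed read is neutral: the gel-based class stands. The demotion rule is
isolated in one function (`reconcile_sequencing`) because it is the one
genuinely judgment-laden step of the fusion.

**Assembly outcome.** All correct / ≥1-but-not-all correct / all incorrect;
an ambiguous member blocks the all-or-nothing calls (→ `unclassified`)
unless a correct and an incorrect member already pin `some_correct`.
Assemblies without minipreps are excluded by the caller.

**Empirical hit rate.** `100 · max(n_presumed_correct,
n_sequence_verified) / n_minipreps`; undefined when any member's gel is
ambiguous or absent, because the denominator would mix assessed and
unassessed clones. The campaign mean averages the per-assembly rates where
defined.

**Colony-checking probability.** `100·(1 − (1 − h/100)^k)`, displayed to
the nearest integer percent (47% with k = 3 and 4 gives 85 and 92).

**Decile binning.** Cutoffs are the 10%…90% linear-interpolation
percentiles of elapsed days, floored to whole days (data are integer days,
so flooring changes no count) and deduplicated — durations typically fall
into fewer than 10 bins. Bin *i* covers `(cutoff[i−1], cutoff[i]]`; values
above the last cutoff form an overflow bin labeled `<cutoff+1>+`, emitted
only when occupied, so a degenerate all-zero campaign yields the single
bin `0`. Counts are cross-checked against an independent sort-based
percentile/frequency oracle.

**Storage-time table.** Per assembly (optionally filtered by type), elapsed
= most recent transformation date − assembly date (tie on date → larger
serial). Columns are the settings-defined colony categories; the per-bin
percentage is the share of assemblies whose record links to a fully
verified read.

**Sequencing-outcome table.** Every sequencing submission traceable
miniprep → assembly contributes in its matched transformation's colony
category. Rows with fewer than `min_observations` (default 10) are
suppressed; the rest sort by decreasing fraction of observations in
categories with an upper bound ≤ 100 colonies; an `All` row unions the
*displayed* categories.

**Operations timeline.** Up to 5 tasks; cumulative completed-operation
counts over the union of event dates (nondecreasing by construction);
in-progress constructs per date (queued, not yet first-verified);
days-to-completion = first verifying read's submission date − queue date.

## Synthetic campaign generator

The generator walks each registered construct through the pipeline with
one seeded NumPy generator (bit-reproducible). Defaults model a realistic
mid-size campaign: 1–4 parts per construct (mode 2), 10% PCR failure
(failed fragments are logged, noted in the troubleshooting log, and
replaced), 15% of transformations plating empty, per-clone hit rate 0.47
with 4 clones picked per transformation, storage delays massed at 0–2 days
with a tail to 60, quasi-logarithmic colony categories with a boundary at
100, 15% backbone sharing across constructs (which is what makes
cross-construct evidence testable), 5% of gel lanes not run, defect reads
drawn from a mixture dominated by primer-dimer insertion and surviving
template, and up to 3 attempts per construct.

Gel reads are *faithful*: a correct clone always shows a clean pattern, an
incorrect one a failing pattern (apart from the ambiguous fraction). Real
gels misclassify, migrate anomalously, and vary with operator; the
generator also draws clone correctness i.i.d. per clone, whereas real
failure modes (bad part prep, template carryover) correlate clones within
an assembly and colony count with hit rate. Passing tests therefore
demonstrate that the *bookkeeping and estimators* are correct under known
conditions — e.g. that the mean empirical hit rate recovers the true
per-clone rate within 3 percentage points at 500 assemblies × 4 clones —
not that real campaigns will look like these numbers.

`inject_corruption` produces a deep copy with exactly one dangling
reference, duplicate id, out-of-set enum, or malformed date, returning the
location so soundness of `validate_instance` is testable corruption by
corruption.

## Problem sizes and tolerances

Oracle-equivalence tests run on generated campaigns of 40–60 constructs
(a few hundred to ~1600 records), chosen to exercise every code path many
times over while keeping the full suite around ten seconds. Parameter
recovery uses 500 assemblies × 4 minipreps per condition (the 3-point
tolerance is ≈4 standard errors of the mean at that size). Equimolarity is
asserted to 1e-9 relative; mass/volume balances exactly; the molarity
constant to 0.1% of the closed-form mass computation.

## Known limitations

- Statuses are recomputed by full scans; instances beyond ~10⁴ records
  would want indexing, which the file-backed single-writer model does not
  yet provide.
- The state table is minimal: analytical-PCR and per-sample QC overrides
  exist as settings but gate only the transitions described above.
- No automated troubleshooting recommendations; the tracker surfaces
  evidence, the human decides.
- Sequencing interpretation is a single closed category per read; mixed
  evidence within one read (e.g. verified backbone + point mutation) must
  be logged as its dominant category.
- The alert log records events; delivery (mail, chat) is intentionally out
  of scope.
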
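# clonecoord

A file-backed execution manager for DNA-construction campaigns: a typed data
model for every cloning sample and operation, a live status/task engine with
batch- and priority-aware highlighting, a per-construct tracker with
cross-construct evidence, Golden Gate design validation, bench calculators,
and outcome analytics — all driven by plain CSV tables that a lab (or a
script) can edit directly.

## Who it is for

Groups that build many plasmids in parallel — especially teams of part-time
or trainee researchers — lose most of their cloning time not to pipetting
but to coordination: knowing which PCRs are ready to purify, which
assemblies are waiting on a failed fragment, which constructs stalled and
why, and what the accumulated record says about how well the pipeline
works. `clonecoord` organizes a shared campaign *task-by-task* rather than
construct-by-construct, so work keeps flowing even when individual steps
fail, and it squeezes quantitative answers (hit rates, storage-time effects,
failure-mode spectra) out of the data that routine logging already produces.

## The model

**Inventory.** Every physical sample carries an identifier of the form
`<prefix><serial>` — `o` oligo, `d` dsDNA fragment, `a` assembly, `g`
strain stock, `m` miniprep (e.g. `a20`, `d1286`). Serials map bijectively
onto storage slots: 8-tube strips fill position-first, then the 12 columns
of a 96-slot plate, then the next plate, so `d97` is always plate 2,
column 1, position 1. A sample's table row is just `serial +
num_header_rows`, making every lookup O(1).

**Statuses.** Nothing is stored; every status is recomputed from logged
data. A PCR fragment is `ready:purify` until a purification date appears
and `stalled:pcr_failed` the moment its gel lane shows a failure; an
assembly is `ready:assemble` once all parts are available and inherits a
stall from any part; it becomes *verified* when a linked miniprep's
governing (largest-serial) sequencing read reports all parts present.
Constructs partition into `in_progress` / `needs_intervention` /
`complete`, and experiments (construct sets bound to planned tests) emit
deduplicated alert events when they become ready or a member stalls.

**Analytics.** Minipreps are matched to transformations (explicit reference
wins; otherwise the largest-serial transformation dated on or before
inoculation), gel calls are reconciled with sequencing (a defect read that
refutes a clean gel demotes the set's other gel-based "correct" calls), and
each assembly gets an **empirical hit rate**

```
h = 100 · max(n_presumed_correct, n_sequence_verified) / n_minipreps
```

undefined when any gel lane is ambiguous. The chance of obtaining at least
one correct clone when picking *k* colonies is `100·(1 − (1 − h/100)^k)`;
at the long-run average hit rate of 47%, checking 3–4 clones gives an
85–92% chance. Storage-time tables bin assemblies into decile-derived,
day-quantized bins (the overflow bin is labeled `<cutoff+1>+`), and
sequencing-outcome tables rank failure modes by their propensity for
low-colony (≤100) plates.

**Golden Gate validation.** An ordered part set is valid iff the 4-base
overhangs chain head-to-tail into a closed ring, all junction overhangs are
distinct, and none is the reverse complement of another (palindromes
included) — the rule that catches reverse-complementary junction designs
before any DNA is wasted.

## Worked example

Generate a synthetic 30-construct campaign and look at it:

```
$ clonecoord simulate --out demo --seed 42 --n-constructs 30
wrote instance with 30 constructs to demo

$ clonecoord tracker dashboard --instance demo
in_progress         2
needs_intervention  1
complete            27
ready:sequence      20 construct(s)

$ clonecoord analytics hit-rate --instance demo
mean empirical hit rate: 44.0% over 25 assemblies
```

27 of 30 constructs finished; one stalled and needs a human decision. The
mean empirical hit rate (44% over the 25 assemblies where it is defined)
is the campaign-level estimate of per-clone correctness. Storage time vs.
outcome, binned by deciles of days between assembly and transformation:

```
$ clonecoord analytics storage-time --instance demo --type USER
     0  1-9  10-50  51-100  101-500  >500   n  percent_verified
0    2    3      1       2        2     3  13         53.846154
1    0    1      0       2        1     0   4        100.000000
2    3    0      0       0        1     0   4         25.000000
3-6  1    1      0       0        0     0   2         50.000000
7+   1    1      1       0        0     0   3         66.666667
```

Rows are storage-day bins, columns colony-count categories, `n` the
assemblies per bin, and `percent_verified` the share that eventually gave a
sequence-verified clone. A Golden Gate design with reverse-complementary
junctions is flagged before it is queued:

```
$ clonecoord design gg-validate parts.csv
rc_collision [pVN2, pVN3, pVN3, pVN4]: junction overhangs AACG and CGTT are reverse complementary
```

and the bench calculators reproduce the standard numbers — an equimolar
pool of a 1.0 kb part at 15 ng/µL and a 2.4 kb part at 60 ng/µL to
7.5 ng/kb/µL total in 5 µL:

```
$ clonecoord calc mix --part 1.0:15 --part 2.4:60
part 1: 1.250 uL
part 2: 0.750 uL
water: 3.000 uL
per-part concentration: 3.75 ng/kb/uL = 6.086 nM
```

Everything is equally accessible from Python:

```python
import clonecoord as cc

inst = cc.generate_instance(cc.SimParams(n_constructs=30, seed=42))
print(cc.prob_correct_clone(47, 3))   # 85
print(cc.ng_per_kb_to_nM(1.0))        # 1.623
```

## Layout

- `clonecoord.core_model` — records, sample IDs, storage arithmetic, settings, CSV instance load/save/validate
- `clonecoord.status_engine` — per-sample/per-construct status derivation and cross-construct part evidence
- `clonecoord.dashboard` — prioritized task list, highlight rules, experiment evaluation and alert log
- `clonecoord.tracker` — construct histories by assembly attempt, filtered listings, campaign totals
- `clonecoord.design_tools` — Golden Gate rule validation, molarity/mix/premix calculators
- `clonecoord.analytics` — matching, gel/sequencing reconciliation, hit rates, decile and outcome tables, timelines
- `clonecoord.synthetic_fixtures` — seeded synthetic campaign generator and corruption injection

See `docs/methods.md` for the underlying procedures, parameter defaults,
and known limitations.
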
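# Methods

## Coordinate conventions

Sites are stored as their top strand written 5'→3'; bottom-strand features
are mapped into top-strand coordinates so there is a single canonical frame.
Intervals (the R and L integrase-binding boxes) are 1-based inclusive.
Crossover points are **boundaries**, not positions: index *k* denotes the
inter-base gap between top-strand bases *k* and *k*+1, because strand
exchange happens between bases and the inference target is precisely such a
gap. Within the randomized window the same convention is used ordinally:
window boundary *b* ∈ {0..P} means "between window ordinals *b* and *b*+1",
with *b* = 0 and *b* = P meaning the exchange fell entirely outside the
window on one side.

## The bundled site

The default site is a 39-bp attI1-like top strand

```
TGGCCAAA | CCCTAAA | CG | TAAGC | GTTACCAGT | ATGTGGTG
  flank    L box     sp.  spacer   R box       flank
            9–15    16–17  18–22   23–31
```

built from the canonical elements of a class-1 integron *attI* site: the L
box 5'-CCCTAAA-3'; a spacer whose first base C completes the border
5'-AAC-3' triplet whose two adenines (positions 14/15, window ordinals 6/7)
flank the top-strand crossover (ts_crossover boundary 14, window boundary
6); and an R box beginning 5'-GTT-3' so that its bottom strand reads
5'-AA^C-3' — the universal bottom-strand cleavage signature — giving
bs_crossover boundary 23. The randomized window is the 7 L-box positions,
the 2 adjacent spacer positions and the base pair containing the R-box
crossover C (top-strand G at 23): P = 10 positions in 5'→3' window order.

The 8-bp flanks and the amplicon context sequences are synthetic: the true
flanking sequence of the natural site is not bundled, and any real site can
be supplied through the YAML site config. The specific flank sequences were
chosen so that the 8-mer extraction anchors occur exactly once, on one
strand only, in every amplicon class — the site core itself is rich in
inverted repeats (the R and L boxes are near-palindromic partners), which
rules out very short anchors.

## Library model

The library follows the single-position randomization scheme: P
sub-libraries, each fully random at one designated position, mixed with
equal weight 1/P. Each molecule therefore differs from wild type at zero or
one window position, and the per-position marginal is
P(WT) = 1 − (3/4)/P, P(each alternative) = (1/4)/P — for P = 10, 92.5% /
2.5% each, 7.5% non-WT pooled. `exhaustive_library` enumerates the nominal
pool of 4P = 40 (position, base) combinations; since a quarter of the draws
re-create the wild-type base, only 31 sequences are distinct. `draw_library`
samples molecules i.i.d. from the mixture.

## Recombination model

`recombine` implements reciprocal strand exchange as sequence bookkeeping:

* **second strand exchange** at window boundary *b*: the left product is
  donor[..cut] + recipient[cut+1..] with the cut immediately 3' of window
  ordinal *b* (immediately 5' of the window for *b* = 0); the right product
  is the exact reciprocal. When consecutive window ordinals are not adjacent
  on the top strand, intervening invariant bases travel with the 3' moiety
  (they are identical in both parents, so the choice is unobservable).
* **replicative resolution** (bottom- or top-strand transfer followed by
  replication): only the first exchange at the bottom-strand R-box crossover
  occurs, so the cut sits at `bs_crossover` and the randomized window is not
  split — one junction carries the donor window intact, the other the
  recipient's. Replication itself is modelled only at marker level
  (`trace_circle_markers`), because marker-level predictions are the
  testable content; no replication-fork mechanics are simulated.

Reaction outcomes are a pure function of (pathway, orientation), held in
`OUTCOME_TABLE`: intermolecular reactions always fuse replicons into a
cointegrate; between direct repeats both pathways excise; between inverted
repeats the second exchange inverts while replicative resolution linearizes
the replicon and is abortive.

The mismatched-circle simulation defaults to 50/50 bottom/top strand
transfer, reflecting the observed lack of strand bias in symmetric
double-stranded reactions; the bias is configurable (e.g. to emulate the
strongly bottom-strand-biased single-strand reactions). A `doubles_rate`
knob models circles mis-assembled from two copies of the same strand (the
source of rare NarI+/SacII+ and NarI−/SacII− clones in real preps); the
default of 0 models a clean preparation.

The cointegrate-pool simulator partners the library with a **wild-type**
site. In the wet protocol the partner carries an R-box AAC→AAA mutation to
force top-strand exchange; in silico the pathway is chosen explicitly, and
a mutated partner would plant a constant non-WT base at window ordinal 10
of one junction, confounding the profile model for no benefit. An optional
per-position `acceptance` vector models binding selection by rejection
sampling of non-WT donors.

## Read simulation

Reads are full amplicon copies with i.i.d. per-base substitution errors
(uniform over the three alternatives), constant Phred score, single-end;
indel and quality realism are deliberately out of scope because
position-indexed profiling at this amplicon size is insensitive to them.
Defaults — depth 10,000 reads per amplicon class, error 0.001 — are declared
values for a small-amplicon short-read run, not inferred from any dataset.

A configurable fraction of reads is corrupted to emulate abnormal
recombination events and sequencing artifacts. The four corruption modes
(truncation, 5'-anchor mutation, 2-base insertion, ambiguous window base)
are this package's own taxonomy, built as synthetic stand-ins to exercise
the filters; when the simulator is given the extraction anchors, each mode
is aimed so that the corrupted read is guaranteed to fail exactly one
filter rule.

## Filtering and profiling

Amplicon classes (library, left junction, right junction) are recognized by
their terminal anchor pairs — the in-silico analogue of PCR primer pairs —
with at most 1 substitution per anchor; reads matching zero or several
classes are `unassigned`. Window extraction then requires both 8-mer span
anchors within 1 substitution each (substitution-only Hamming scan; an
edit-distance matcher would tolerate the indels the filter exists to
reject), the exact expected spacing, and no ambiguous window bases; failures
are logged as `anchor_fail`, `length_fail` or `ambiguous_base`. Reads are
tested on both strands and canonicalized to the top strand. Frequencies are
reported from raw counts — no pseudocounts — so descriptive output stays
faithful; pseudocounts enter only the likelihood (below).

## Boundary inference

The changepoint likelihood treats per-position non-WT counts as independent
binomials with two rates: the library mutant load *q* on the retained side
and an error floor *e* elsewhere (left junction retains ordinals ≤ *b*;
the right junction is reciprocal). *q* defaults to the mean non-WT rate of
the sequenced library profile; *e* defaults to the configured sequencing
error estimate (10⁻³). A pseudocount of 0.5 per base-count cell (hence +1.5
on the pooled non-WT count, +2 on the total) keeps the likelihood finite at
zero counts. The curve over all P+1 boundaries is returned with the argmax;
exact ties resolve to the smallest *b* and are listed in the call. The
`confidence` field (log-likelihood gap to the runner-up) is this package's
own uncertainty summary — the source experiments report none. The model
ignores the small q·e cross term (a non-WT base re-substituted by error),
which is third-order at these rates.

Known limitation: when the crossover falls inside a mononucleotide run
(e.g. an adenine stretch), adjacent boundaries are genuinely
indistinguishable at the sequence level; the model will report a small
confidence gap but cannot resolve what the chemistry does not encode.

## Stringency

Per position, observed non-WT retention is tested against the neutral
expectation (7.5%) with an exact two-sided binomial test;
skew = (observed − expected)/expected; Benjamini–Hochberg q-values across
the P positions accompany raw p-values, and a per-base breakdown (expected
share: one third of the pooled rate each) is also reported. Stringency is
scored on the retained-moiety composite profile (each ordinal taken from
the junction that kept it). Note that selection at some positions enriches
the remaining pool: neutral positions then show *positive* skew, so "under
selection" should be read as *significant negative* skew, not mere
significance.

## Power analysis

`power_curve` estimates boundary-recovery rates over a depth × error grid
by replicate simulation. For speed these replicates (and the recovery
checks in the test suite) use a count-level simulator that draws the
per-position binomial counts directly — the counts are sufficient
statistics for the inference, so this is distribution-equivalent
(position-marginally) to the full read path, which is itself exercised
end-to-end at depth 10,000 in the tests.

## Assay estimators

Colony-count frequencies come with Wilson score 95% intervals — chosen over
Wald because counts are often small or zero; the interval is clamped to
[0, 1] and to contain the point estimate against floating-point residue at
the edges. Fold changes propagate a CI on the log scale (delta method on
log p̂) when counts are available and report it as undefined otherwise.
Restriction-profile summaries use largest-remainder rounding so the four
class percentages sum to exactly 100 at the reported precision; full
precision is kept internally. Replicate-level significance testing is a
documented thin pass-through to a two-sample Kolmogorov–Smirnov test.

## What the synthetic data do and do not show

The simulator reproduces the *design* of the mapping experiment: mixture
structure of the library, reciprocal segregation, substitution error,
abnormal-read contamination, strand stoichiometry of circle preps. It does
not model PCR amplification bias, paired-end chemistry, quality-score
structure, indel error, host-factor genetics, or binding biochemistry —
so passing tests demonstrate that the estimators are correct under the
declared generative model, not that real libraries are free of such
artifacts. Real primer sequences and filtering criteria of any particular
experiment are user-configurable inputs, not bundled facts.

## Problem sizes used in tests

The test suite runs the recovery sweep at depth 10,000 and error 10⁻³ with
100 replicates for each true boundary 0..10 (count-level simulator), and
one full read-level end-to-end run at 10,000 reads per class with 5%
abnormal reads; these sizes match the declared defaults of the design while
keeping the whole suite fast.
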
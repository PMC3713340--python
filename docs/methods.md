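# Methods

## Scanner definition

The scanner finds every occurrence of the core 4-mers `TGAC` (plus strand)
and `GTCA` (minus strand, i.e. the reverse complement as read on the scanned
window), case-insensitively. A hit is *maximal*: `TGAC` preceded by `T` is
reported once as `TTGAC` (start one base left, same end); `GTCA` followed by
`A` is reported once as `GTCAA` (same start, end one base right). No longer
extensions are considered — the curated elements mix 4- and 5-mer cores and
never longer ones. IUPAC ambiguity codes cannot match because the patterns
are literal.

Maximal hits can never overlap: no non-empty suffix of any pattern in
{`TGAC`, `TTGAC`, `GTCA`, `GTCAA`} equals a prefix of another (checking each
length: suffixes end in `C`/`A`, prefixes begin `T`/`G`; the longer
comparisons fail on the same characters), and the contained-4-mer case is
removed by maximality. The property-test suite fuzzes this invariant.

Pairing forms every ordered pair of distinct cores whose linker —
`right.start − left.end`, both taken on maximal hits — lies in
`[0, max_linker]`. All-pairs reporting is the default because a three-core
probe genuinely contains three dyads; an adjacent-only mode exists for
per-gene summaries. A dyad is identified by its two core coordinates; nested
or chained dyads are not merged. Orientation is a pure function of the two
strands: `(−,+)→HtH, (+,+)→TtH, (+,−)→TtT, (−,−)→HtT`, the label reading the
outermost arrow-ends left to right. Because ends are non-decreasing along
the sorted hit list, "some pair within the cap" is equivalent to "some
*consecutive* pair within the cap"; all-pairs output is nonetheless reported
for downstream use.

`max_linker` defaults to 24 nt, the largest linker in the curated set; it is
a plain parameter, not a fitted constant.

## Distance and window conventions

Windows are written 5′→3′ in gene orientation with the rightmost base
immediately adjacent to the anchor, so the distance of a dyad is
`len(window) − left.start` (1-based, to the element's 5′-most base, i.e.
"begins N nt upstream"). A `distance_to="3p"` variant measures to the
element's last base for sensitivity analyses. Anchors: TSS = 5′ end of the
gene feature, AUG = 5′ end of the first CDS segment in gene orientation.
Coordinates are GFF3 1-based inclusive throughout; the single 0-based
conversion lives in `Genome.fetch`. Windows truncated at a contig edge warn
rather than fail. The default window is 2 kb (the curated search criterion);
the AUX/IAA survey lists distances up to 2524 bp without stating its window,
so the replication preset uses 3 kb — a documented guess, not an assertion.
The curated catalog carries the StBEL5 element at both 820 nt (TSS
convention) and 970 bp (AUG convention); the implied UTR length is nowhere
stated, so neither row is derived from the other.

## Background model

`dyad_probability` computes the exact probability that an i.i.d. random
window contains at least one dyad. The state couples (a) an Aho–Corasick
automaton over {`TTGAC`, `TGAC`, `GTCA`} and (b) a capped counter of bases
since the most recent core's exclusive end, with two sentinels: "no core
yet" and "`GTCA` just ended, its `A`-extension undecided". When a pattern
completes, the linker implied by the counter (minus 5 for a `TTGAC`
completion, minus 4 otherwise) either falls within the cap — transition to
an absorbing hit state — or resets the counter (to the pending sentinel for
`GTCA`). The counter saturates at `max_linker + 6`, beyond which no future
completion can produce an in-cap linker against that reference.

Modelling maximal hits is not a nicety: extending a *right* core to `TTGAC`
moves its start one base left and shortens its linker by one, so a 4-mer-only
model misclassifies sequences whose gap sits exactly one past the cap
(`TGAC` + 25-nt linker ending in `T` + `TGAC` has 4-mer gap 25 but true
linker 24). A dedicated test (`test_linker_cap_boundary_matters`) pins this.
The left-core extension never matters for existence (ends coincide), and the
minus-core extension matters only through the *end* used for the next gap,
which the pending sentinel captures.

The DP is validated three ways: closed forms (window 7 → 0; window 8,
uniform → exactly the four core-core concatenations, 4/4⁸), exhaustive
enumeration of all 4ⁿ sequences for n ≤ 12 via a vectorised independent
enumerator, and scanner-driven Monte Carlo at n ∈ {50, 200, 2000} within 3
binomial SE. Probabilities are propagated directly in double precision; the
survival mass stays far above underflow for any practical window length, so
no log-space branch is needed. `expected_core_sites` is the
linearity-of-expectation count of 4-mer match positions on both strands,
`2·(n−3)·f_A f_C f_G f_T` (both patterns use each base once); maximality is
deliberately ignored there and documented as such.

## Synthetic data

The generator emulates the *study conditions*, not real promoters:
i.i.d. bases at a configurable GC fraction (default 0.36, a typical plant
promoter AT-richness) with rejection resampling of every `TGAC`/`GTCA`
4-mer. Forbidding those two words on the plus string forbids all cores on
both strands, which makes embedded-element truth tables exact. Elements are
spliced by replacement (window length preserved, so planned distances are
exact) at the position implied by their distance; a repair loop then redraws
any background base that creates an incidental junction core or changes a
terminal core's maximality (a background `T` before an element starting
`TGAC`, or `A` after one ending `GTCA`, would shift the reported
coordinates). The loop terminates when the window's maximal-hit set equals
the planned set, so the scanner round trip recovers exactly the truth table.
What this does **not** emulate: dinucleotide/Markov structure, repeats, CpG
or TA skew of real genomes — a pass on synthetic windows validates
coordinate arithmetic and bookkeeping, not discovery performance on real
promoters.

Genome materialisation appends a core-free gene body per window (one contig
per gene), writes GFF3 gene/mRNA/CDS features starting right after the
window, and optionally reverse-complements whole contigs to exercise the
minus-strand extraction path.

The Ct simulator inverts the Livak model: target Ct = per-gene baseline −
log2(expression) + N(0, sd); the reference-gene Ct is condition-independent.
Defaults follow the quantification stage being emulated: 3 replicates,
Gaussian cycle noise 0.3 (a typical replicate SD for SYBR assays), WT as
calibrator. Noiseless simulation inverts to the true fold change exactly.

## Induction analysis

Fold change is `2^(−ΔΔCt)` with ΔCt = target − reference per replicate and
ΔΔCt the difference of condition means. The t-test is two-sample, two-sided
on per-replicate ΔCt — the scale on which noise is approximately Gaussian —
with pooled variance by default (Welch by flag); stars follow
0.05/0.01/0.001. A single replicate yields a fold change but a missing
(NaN) p-value. No multiple-testing correction is applied by default (per-gene
stars are reported); the efficiency-corrected base `(1+E)^−ΔΔCt` is available
but not asserted against any published value, since raw Ct values are not
printed anywhere. The 95% CI on the fold change comes from the t-quantile on
the ΔΔCt scale; simulation shows ~95% coverage (asserted ≥ 93% over 1000
seeded experiments). The linker correlation is Spearman's rank of linear
fold change against linker length, NaN on constant input, requiring ≥ 3
genes; only the sign is scientifically interpretable here because the
generating magnitudes are synthetic.

## Problem sizes and numerical choices

Suite sizes were chosen to keep the default run at about a minute: scanner ↔
naive-oracle equivalence is exhaustive for all sequences of length ≤ 8
(parametrised per length) plus 4000 seeded random sequences of length ≤ 60
with random linker caps; DP ↔ enumeration runs at n ≤ 12; Monte-Carlo
cross-checks use 1200–8000 windows (3 SE bands); qPCR properties use 400 or
1000 seeded simulations. Hypothesis property tests run derandomised.
Parameter-recovery bounds are established by the simulation oracle itself
(direct normal draws of ΔΔCt at the same noise level) rather than hard-coded
constants.

Degenerate inputs: windows shorter than 8 nt yield nothing; empty plan lists
yield background-only sets with empty truth tables; overlapping embedded
elements are an error; `gc_fraction` outside [0,1], non-positive fold
changes, and base frequencies not summing to 1 (within 1e-9) are rejected.

## Known limitations

Literal-core scanning only — no PWM or degenerate-motif support, no
phylogenetic footprinting, and no prediction of binding affinity; the i.i.d.
background has no Markov extension yet; transcript isoforms are not
resolved (TSS = gene-feature 5′ end); the AUX/IAA survey row whose linker
sequence is unprinted carries a synthetic linker (flagged
`linker_synthetic`) and its linker text must not be interpreted; the curated
"double, palindromic motif" count annotation of one GA2ox1 row is ambiguous
and excluded from assertions.
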
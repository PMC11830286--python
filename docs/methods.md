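# Methods

`fragid` models the identification of an unknown co-purifying protein from
the output of sequence-agnostic model building into a cryo-EM density map.
A model builder run without a sequence emits chain fragments — putative
stretches of backbone with per-residue amino-acid calls (and, optionally,
per-position probability profiles). The question the pipeline answers is:
*given only those fragments, which database protein is in the sample, and
how does the answer degrade with map resolution?*

## The synthetic fragment generator

No neural model builder runs here; its output is emulated in sequence
space by `fragid.fragsim`. A degradation level nominally labelled with a
resolution r (Å) maps to:

* mean fragment length `L̄ = scale_k / r`, rounded, minimum 1 — lengths are
  inversely proportional to resolution. Default `scale_k = 150 Å·residues`
  (mean length 60 at 2.5 Å).
* substitution error rate `ε = clamp(error_base + error_slope · (r − r₀),
  0, 0.95)`, defaults `error_base = 0.10`, `error_slope = 0.08 /Å`,
  `r₀ = 2.5 Å`.

Fragments sample a uniform start on the reference and a geometric length
with mean `L̄` (truncated at the reference end, minimum 1) — a
single-parameter, heavy-right-tailed choice that reproduces the mixture of
stubs and long chains real builders emit. Each residue is then substituted
independently with probability ε by a *different* residue drawn from the
background renormalised without the original (no silent "errors"). Each
fragment carries an emission profile with `1 − ε` on the emitted residue
and `ε/19` elsewhere. All randomness derives from one root seed through
`numpy.random.SeedSequence(seed, index)` streams, so enlarging a fragment
set never reshuffles earlier fragments and every result is a pure function
of `(seed, parameters)`.

What the generator does **not** emulate: density-driven breakpoints
(fragment boundaries are random), position-dependent error rates,
insertions/deletions in the traced chain, non-standard residues, and any
change of total coverage with resolution (the expected residue coverage is
held constant, default 3× the reference). Passing tests therefore show
that the downstream statistics behave correctly under a controlled,
heavy-tailed, iid-error fragment model — not that any particular neural
builder has these error characteristics.

The synthetic decoy proteome contains the target under its true
description, one paralog diverged at rate `paralog_divergence` under a
confounder description that deliberately does *not* match the target's key
terms, optionally `n_homologs` mildly diverged copies labelled like the
target (the redundancy knob: real non-redundant databases still return
hundreds of near-identical records for a bacterial enzyme, and top-100
tables are filled by them), and `n_decoys` iid background sequences with
neutral descriptions.

## Consensus from fragments

Fragments of one protein are multiply aligned with a deterministic
center-star heuristic: the fragment maximising the summed pairwise global
score (ties: longest, then smallest id) is the center; all others are
aligned to it pairwise with free end gaps, and gaps merge under "once a
gap, always a gap". This replaces a progressive-tree MSA engine: for
overlapping windows of a single protein it is adequate, dependency-free
and byte-reproducible. Its known weakness is fragments that do not overlap
the center — they are placed arbitrarily and contribute junk columns,
which the downstream local search tolerates.

The consensus emits the most frequent non-gap residue per column
(ties broken alphabetically), dropping columns whose gap fraction exceeds
`max_gap_fraction`. The operation default is 0.5 — a majority-gap column
has no meaningful "most prevalent" residue in a globally overlapping
alignment. For *tiling* fragments, however, the per-column gap fraction is
approximately `1 − depth/n_rows`, which exceeds 0.5 at any realistic
depth; the benchmark therefore keeps every covered column
(`max_gap_fraction = 1.0`). Per-column support (agreeing / non-gap rows)
is reported alongside the call.

## Alignment and search statistics

Global alignment is affine-gap Gotoh DP with the conventions of the
standard global-alignment tool for proteins: BLOSUM62, gap open 10.0 /
extend 0.5, end gaps free by default, and identity/similarity/gap
percentages computed over **all** alignment columns, "similar" meaning
substitution score > 0. Local search is full Smith–Waterman (no heuristic
seeding) with BLOSUM62, open 11 / extend 1. Throughout, a gap of length L
costs `open + L · extend`. The unknown residue `X` scores 0 against
everything and counts as neither identical nor similar. Tracebacks prefer
diagonal, then up, then left, making alignments byte-reproducible; both
engines are verified cell-exactly against an independent brute-force DP.

Significance uses Karlin–Altschul statistics, `E = K · m · n · e^{−λS}`
with the published gapped BLOSUM62/11,1 constants λ = 0.267, K = 0.041;
m is the query length and n the total database residue count. One best
local hit is kept per subject; hits above `max_evalue` are dropped; tables
sort by ascending E (ties: descending bits, then subject id) and truncate
to the top 100. The library default `max_evalue = 10` mirrors the common
search-server default. The *benchmark* instead counts hits at `E ≤ 10⁻³`:
by the definition of E, a threshold of 10 admits ~10 chance decoy entries
per search, which a 60-record synthetic database — unlike a real top-100
table padded with true homologs — cannot absorb.

## Profile HMMs

A profile has one match state per usable alignment column (gap fraction ≤
0.5 by default; the benchmark again keeps all covered columns), insert
states emitting the background, and delete states. Emissions and
transitions are estimated with a single pseudocount weight α (default 1):
`em = (counts + α·background) / (total + α)`, transitions likewise with
α/k per alternative. A chain's per-position probability profile is
accepted directly as a single ungapped observation per column.

Scoring is the forward algorithm over odds ratios (emission / background)
against a local alignment model: uniform entry over match states, a
uniform exit point (`P(exit at j | entry at i) = 1/(L−i)`), and flanking
sequence scored at odds 1. Because summing over entry positions inflates
even an uninformative profile, the reported bit score subtracts a
placement-entropy null — the forward score of the same architecture with
background emissions, a function of the sequence length only. An
uninformative profile (α → ∞) then scores exactly 0 bits for any
sequence. Computation is in scaled linear space; a sequence with no
admissible path reports −∞ and is treated as no-hit.

Significance is empirical: each subject's score is compared with forward
scores of `n_null_shuffles` random permutations of itself (composition-
and length-preserving); `E = n_records × tail frequency`, with a
moment-fit Gumbel extrapolation when the score exceeds every null sample
(capped at 1/n_shuffles before extrapolation applies). The default is 200
shuffles; the benchmark uses 30, trading tail resolution for runtime —
the Gumbel extrapolation then occasionally admits a stray decoy, visible
as sub-point accuracy noise in the sweep.

## The percent-match statistic

All hit descriptions are lowercased and screened for the configured key
terms as plain substrings (five synonyms of dihydrolipoamide
succinyltransferase by default, fully overridable). Family-level terms
such as "2-oxo acid dehydrogenase subunit E2" never count alone. The
score is `100 × matched / used` over the `min(100, available)` lowest-E
entries, rounded to one decimal; an empty table yields a missing score,
serialized as `--` and excluded from the missing-excluded aggregate.
Aggregation reports the mean with a Student-t 95 % CI (degenerate at
n = 1). Relative particle abundances are percentages of total counts to
two decimals.

## The degradation benchmark

Four methods run per (resolution, replicate): consensus → search (one
score), longest-10 chains → search (≤ 10 scores), per-chain profile →
profile search (≤ 10), and one profile from the full fragment MSA (one).
Seeds derive per (resolution index, replicate) from the root seed, so the
whole sweep is reproducible byte-for-byte. Default study conditions: a
234-residue reference, 3× expected coverage, replicates as configured
(10 in the acceptance sweep, which uses resolutions 3/5/7/9 Å-equivalent;
the analysis driver runs the full 3.0–9.0 Å grid at 4 replicates — sizes
chosen to keep a sweep in the minutes range on one CPU).

Two aggregates are reported. The missing-excluded mean mirrors the
original figure's convention but is *conditional on the method returning
something*, and at strict significance thresholds it can rise with
degradation as the most diverged (non-matching) records drop below
significance first. The benchmark's headline metric is therefore
**unconditional accuracy**: a missing identification counts as 0 %. For
the same reason the sweep database contains only unambiguous true records
(target + homologs + decoys); the paralog confounder is measured
separately — with a 15 %-diverged, differently-named paralog present, the
rate at which it surfaces as a method's top hit is reported, not asserted.

## Known limitations

* The degradation axis is a label, not a physical model; no quantitative
  equivalence to any real model builder is claimed.
* The geometric length tail means "extreme" degradation never fully
  extinguishes identification under constant coverage: a set with mean
  fragment length 8 at 60 % substitution error almost always contains a
  20+-residue fragment whose residual ~40 % identity is genuinely
  significant against the target. Complete failure of all methods
  requires deeper degradation than the mean parameters alone suggest —
  an echo, in the synthetic setting, of how robust fragment-based
  identification is at surprisingly poor resolution.
* Center-star misplaces fragments that do not overlap the center; the
  consensus is only trustworthy where coverage anchors it.
* Empirical E-values at few shuffles rely on a Gumbel tail fit; their
  extreme tail is approximate and deliberately not calibrated to any
  external search tool.
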
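# Methods

## Element patterns and coordinates

Binding elements are represented as degenerate DNA patterns over
{A, C, G, T, R, N} ('.' is accepted as N on input; RNA U is mapped to T on
every input path, so RNA- and DNA-alphabet files give identical results).
Every pattern must begin with the −1 upstream cytosine followed by TGT
(+1…+3) and end with the terminal AU/AT: compact patterns carry exactly one
degenerate base between the +4 purine and the terminal AU (U at +7),
extended patterns exactly two (U at +8). Internally windows are 0-based
half-open; all reporting uses the biological convention (−2…+9, no
position 0).

Matching uses compiled regular expressions with grep line semantics: a
read either contains a pattern or it does not, and by default each read
contributes at most one count per pattern. A read matching several
patterns increments each of them — the counts are independent queries, so
ratio denominators and numerators are not exclusive sets. An
occurrence-count mode (`occurrences=True`) and a deduplication mode
(`dedup=True`) exist behind flags but are not defaults: read-level,
non-deduplicated counting is the convention the ratio statistic assumes.
Counting defaults to the final selection round. Only the sense strand is
scanned (single-stranded RNA selection).

The compact:extended ratio for a dataset and +4 base is the plain count
quotient, undefined (an error, printed as ".") when the extended count is
zero. Report tables round ratios to two significant figures and Kd/Krel
values to three and two respectively.

## Position frequency matrix

`build_pfm` aligns each read on its first anchor-pattern match and tallies
bases over the window −2…+9 (11 columns); reads whose window would run
off either end are skipped, and at least one usable read is required.
Column probabilities use a configurable pseudocount (default 0).
Information content per column is IC = 2 + Σ p·log₂p bits (0·log 0 ≡ 0),
i.e. relative to a uniform background, bounded in [0, 2]. This is a
deliberate desk-scale summary — no EM motif discovery, no logo rendering.

## Selection simulation

The generator emulates an in vitro selection experiment: a library of
reads with an i.i.d.-uniform random core (default 20 nt) between constant
flanks (defaults: 5′ "GG", the guanosines with which T7 transcripts
initiate; empty 3′ — the real primer/adapter flanks are not published, and
their identity is irrelevant to core-element statistics). Each selection
round assigns read *i* the retention weight

    w_i = θ_i + b,   θ_i = P / (P + Kd_c(i))

where *P* is the protein concentration (default 100 nM), *c(i)* is the
read's lowest-Kd matching element class (best-match rule: equilibrium
capture is dominated by the tightest site; θ = 0 for non-matching reads),
and *b* is a concentration-independent background retention modeling
carrier-tRNA/plastic capture (additive, not multiplicative, because
non-binders are retained independently of protein occupancy). The next
round is a multinomial resample of `reads_per_round` reads with
probabilities w/Σw — PCR is neutral (no amplification bias term).

Default class affinities are the measured Kds of representative RNAs for
the four +4-resolved classes: compact-G4 10.3 nM, compact-A4 56.8 nM,
extended-G4 12.4 nM, extended-A4 12.0 nM. Defaults of the undetermined
knobs were fixed once: background retention 0.005 (sub-percent
nonspecific carryover, typical of washed bead capture), 5 rounds,
10⁵ reads per round (large enough that class frequencies are estimated to
~10⁻³ while a round simulates in about a second). Under these defaults
the compact-G4 class is expected to grow monotonically and to overtake
the compact-A4 class well before round five, since per-round class growth
is ∝ (θ_c + b) and (θ_G4+b)/(θ_A4+b) ≈ 1.4.

What the generator does *not* model: wash kinetics, PCR bias, sequencing
error, reverse-transcription dropout, or duplicate-read structure from
amplification. Tests passing on these synthetics therefore demonstrate
the correctness of the analysis arithmetic and the qualitative selection
dynamics, not robustness to the noise structure of real sequencing data.

## Binding titrations and fits

Simulated titrations draw Y = Bmax·X/(Kd+X) + ε, ε ~ N(0, noise_sd·Bmax),
truncated at zero, over the standard 15-point protein dilution series
(4000 … 0.49, 0 nM); defaults noise_sd = 0.05 of Bmax and three technical
replicates match the reported experimental design.

Fitting uses least squares on the one-site specific binding model with
both parameters constrained positive via log-space parameterization
(Levenberg–Marquardt, relative tolerance 10⁻⁸). Initialization: Kd₀ = the
concentration whose signal is nearest half-maximum, Bmax₀ = the maximum
signal. No baseline/nonspecific term is included — the model is "one-site
specific binding", and adding a background parameter would change Bmax
but not Kd under the simulated noise. The fit consumes a generic bound
signal column; whether that is raw band intensity or fraction bound is a
preprocessing decision left to the caller (it rescales Bmax only).

Replicates are fit independently (the SEM convention implies independent
fits); the reported Kd is the replicate mean with SEM = sd/√n, n ≥ 2
required. Krel is the ratio of mean Kds against a reference RNA measured
under the same protein condition (ratio of means, matching the published
convention; a per-replicate-ratio mode exists behind a flag). When the
LST-1 partner is present at constant 4 µM, protein concentrations are
multiplied by the 0.9 dilution correction before fitting. The reporter
normalization (luminescence / A660) is included as a one-line utility for
completeness.

Degenerate inputs are rejected rather than guessed at: fewer than five
distinct concentrations, all-zero signals, single replicates for SEM,
zero A660.

## Enrichment

Genes are stratified by element content into compact, extended, either,
and compact-only sets using the same matcher as read counting. The
universe is the supplied gene list itself (configurable), mirroring the
use case where the comparison set is the full target list. Each term is
tested one-sided for over-representation with the upper-tail
hypergeometric probability P(X ≥ k) (enrichment only, never depletion);
terms annotating no universe gene are skipped with a logged warning.
q-values are Benjamini–Hochberg over the tested terms (flat term sets, no
ontology propagation). The gene-fixture generator assigns each gene one
term uniformly and, for planted terms, overwrites a uniform random window
with a concrete element of the requested class (penetrance configurable,
default 1); default UTR length 200 nt, a typical compact 3′UTR scale.

## Determinism and problem sizes

Every generator takes one integer seed and uses an isolated
`numpy.random.Generator`; identical configurations give byte-identical
outputs, and the pipeline manifest records seeds, parameters and the
package version needed to regenerate every file. The test suite exercises
the generators at the sizes the statistics need — 10⁵-read libraries for
frequency bounds and selection dynamics, 100 simulated titration sets for
recovery error, 200 null universes for FDR behaviour — which keeps the
full suite under ~10 s on one CPU.

## Known limitations

* The selection model is a single-site equilibrium caricature: no
  competition between reads for protein, no wash/rebinding kinetics, no
  sequence-dependent amplification.
* Raw read counts from a real selection depend on sequencing depth,
  deduplication convention, and which round was sequenced; the package
  reproduces published *ratios* from published counts exactly, but raw
  counts are only reproducible from the deposited reads plus those
  conventions.
* The enrichment stand-in uses opaque flat terms; results on real
  annotations depend on the ontology release and background choice.
* Ternary-complex equilibria (partner titration) are out of scope; the
  partner is treated as saturating and folded into the 0.9 concentration
  correction.
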
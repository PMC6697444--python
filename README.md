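# pufselect

Analysis tools for the sequence specificity of PUF-family RNA-binding
proteins — in particular *C. elegans* FBF-2 alone and in complex with its
partner LST-1. The package is aimed at RNA biochemists and computational
biologists who want to analyze (or simulate) three kinds of experiment:

1. **In vitro selection (SEQRS/SELEX-style)** — a random RNA library is
   enriched over several rounds of protein binding, and the surviving reads
   are scanned for degenerate binding elements.
2. **Equilibrium binding titrations (EMSA)** — bound-signal curves are fit
   with the one-site specific binding model to estimate dissociation
   constants and relative affinities.
3. **Motif-stratified target-set enrichment** — genes are split by the kind
   of binding element their UTR contains and tested for functional-term
   over-representation.

## The science in brief

PUF binding elements are anchored on a UGU trinucleotide; the first U is
position +1 and the obligatory upstream cytosine is −1. Two element
geometries matter:

* **compact** (8 nt): `CUGURnAU` — terminal U at +7, one degenerate
  central base; bound with one PUM repeat per base.
* **extended** (9 nt): `CUGURnnAU` — terminal U at +8, two degenerate
  central bases flipped away from the binding surface.

The identity of the +4 purine associates with element length. For a
dataset *d* and base *b* ∈ {A, G}, the package's core statistic is the
read-count ratio

    ratio(d, b) = #reads matching compact(+4 = b) / #reads matching extended(+4 = b)

A4 elements are predominantly extended (ratio ≪ 1), G4 elements compact
(ratio > 1). Binding affinity is modeled as the one-site isotherm
*Y = Bmax·X/(Kd+X)*; relative affinity Krel is the ratio of a mean Kd to
the mean Kd of a reference RNA under the same protein condition.
Enrichment uses the upper-tail hypergeometric test with
Benjamini–Hochberg correction.

A full synthetic-data module (`pufselect.simulate`) generates every input
the pipeline consumes: random-core selection libraries, occupancy-driven
selection rounds (retention weight θ + background, θ = P/(P+Kd) for the
tightest matching element class), noisy replicate titrations, and
gene/term fixtures with planted elements.

## Worked example

Run the bundled demo pipeline (20 000 reads, five selection rounds at
100 nM protein with measured class affinities, two simulated EMSA RNAs,
and a planted-term enrichment universe):

```sh
pufselect run --outdir demo
cat demo/ratios.tsv
```

```
dataset   base4   ratio_compact_extended
synthetic A       0.15
synthetic G       0.94
```

After five rounds the A4 ratio (0.15) shows A4 sequences surviving mostly
as extended elements, while the G4 ratio (0.94) is ~6-fold higher — the
compact-favoring pull of G4, driven purely by the class Kds (compact-G4
10.3 nM vs compact-A4 56.8 nM). The EMSA stage recovers the simulated
affinities:

```
rna_label  protein_label  partner_present  n_replicates  kd_mean_nM  kd_sem_nM  krel
PBE        FBF-2          False            3             56.1        5.48       5.3
cFBE       FBF-2          False            3             10.5        0.48       1.0
```

(true Kds 56.8 and 10.3 nM; Krel of PBE vs the cFBE reference ≈ 5.5), and
the enrichment stage ranks the planted term first with q ≈ 5×10⁻⁴⁰.

The same stages are available individually (`pufselect simulate-library`,
`simulate-selection`, `simulate-emsa`, `count`, `ratio`, `pfm`,
`fit-emsa`, `enrich`) and as library functions.

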
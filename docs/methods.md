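# Methods

cubkit quantifies codon usage bias (CUB) in a set of coding sequences
(CDSs) and relates it to its two classical drivers: mutation pressure
(directional base composition drifting all codon positions together) and
translational/natural selection (preference for specific synonymous
codons beyond what composition explains). The package was built around
the analysis of an AT-rich tapeworm CDS set and its two mammalian hosts,
but every component is generic.

## Sequence handling

A CDS must be an exact multiple of three bases. Under the strict policy a
frame violation or an internal stop codon is an error; under the
permissive policy (the pipeline default) trailing bases are trimmed and
internal stops flagged. A terminal stop codon is removed before any
codon-level statistic (`drop_terminal_stop=True`); stop codons are
otherwise excluded from counts by default, as are codons containing
ambiguity symbols (N, R, Y, …), which are never guessed. `n_excluded` on
every count table makes the exclusions visible.

The default genetic code is NCBI translation table 1 (standard). Its
synonymous universe — the 59 sense codons of the 18 amino acids with more
than one codon, i.e. all sense codons except ATG and TGG — is the domain
of RSCU, ENC, CAI and SiD. Other tables (e.g. 9) can be passed anywhere a
`GeneticCode` is accepted.

## Composition

Per sequence we report base percentages over all counted codons, the
third-position fractions A3/C3/G3/T3, positional G+C (GC1, GC2, GC3),
GC12 = (GC1+GC2)/2, overall GC/AT, AT3 = 100−GC3, and GC3s (third-position
G+C over synonymous-set codons only). GC3 over all counted codons is what
compositional tables conventionally print; GC3s is the natural abscissa
of the ENC expected curve. Both are computed; the ENC–GC3 table lets you
choose (`s_source`). Summary rows use arithmetic means and sample (n−1)
standard deviations. Values are kept at full precision internally and
rounded to 2 decimals only in written reports.

## RSCU

RSCU_ij = X_ij·n_i / Σ_j X_ij, so family values sum to the degeneracy
n_i. An amino acid never observed yields *missing* (NaN) values, never 0,
so absence cannot read as under-representation in short genes. Codons are
classified over-represented (RSCU > 1.6) / under-represented (< 0.6) /
intermediate, with strict inequalities at the thresholds. Preferred
codons are per-family RSCU maxima; ties are broken alphabetically and
flagged. Reports print codons in the RNA alphabet; the DNA alphabet is
used internally.

## ENC

Wright's estimator with the depth-corrected homozygosity
F = (nΣp²−1)/(n−1) per amino acid (n ≥ 2), class means over degeneracy
classes {2, 3, 4, 6}, and ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped
at 61. Six-fold families are kept whole (not split 2+4), matching the
CodonW convention. Families with n < 2 or F ≤ 0 are excluded from their
class mean (a uniformly-used family observed exactly once per codon has
F = 0 and carries no signal); if the single 3-fold family (Ile) is
unusable, 1/F̄₃ is interpolated as the mean of 1/F̄₂ and 1/F̄₄ and the
fallback is recorded in the result's notes. A missing 2-, 4- or 6-fold
class is an error. Because of the n−1 correction, ENC depends weakly on
sequencing depth; the scale-invariance of the index is asymptotic and is
tested at family totals ≥ 200.

The expected curve ENC(s) = 2 + s + 29/(s² + (1−s)²) gives the ENC a gene
would show if codon choice depended on third-position composition s
alone. Genes well below the curve are more biased than composition can
explain.

## CAI and e-CAI

Relative adaptiveness w = RSCU/RSCU_max per family is computed from a
host reference table (counts are converted to RSCU first); absent or
zero reference codons are floored at w = 0.01 so one missing codon cannot
zero a gene's score. CAI is the geometric mean of w over a gene's codons
(Met, Trp, stop and ambiguous codons excluded). The expected CAI null
generates random sequences matching the query set's length distribution
and pooled mononucleotide composition (lengths resampled from the query
lengths, bases i.i.d.), scores them, and reports mean, SD,
e-CAI = mean + z(coverage)·SD at coverage 0.95 by default, plus a
Kolmogorov–Smirnov statistic against the fitted normal. Generation is a
method slot: the composition-matched i.i.d. null is the only built-in;
Markov or amino-acid-preserving nulls would give different (typically
higher) e-CAI values.

## SiD

R(A,B) is the cosine between the two 59-dimensional RSCU vectors and
D(A,B) = (1−R)/2 ∈ [0, 0.5] for non-negative input. The source
literature typesets the formulas ambiguously; we implement the standard
cosine (the quantity its own prose describes) and the (1−R)/2
dissimilarity. Codons undefined in either vector are dropped pairwise and
`n_codons_used` is reported. Note that a host that is *more similar* has
higher R but lower D; qualitative statements about "higher SiD" flip
depending on which of the two is meant.

## Neutrality plot and correlations

GC12 is regressed on GC3 by OLS (the conventional reading of a
"regression line"; reduced major axis is available via `method="rma"`),
with Pearson r and its two-sided p. A constant response is reported as
slope 0, r = 0. Spearman correlations use average-rank tie handling and
two-sided p-values; Benjamini–Hochberg adjustment is off by default and
switchable, since such analyses conventionally report raw correlations.

## Correspondence analysis

Standard CA of the non-negative sequence × codon RSCU matrix: divide by
the grand total, standardize residuals by row/column masses, SVD;
principal inertias are squared singular values and coordinates are
principal (mass-scaled). Missing RSCU entries must be filled with 0
upstream (`RSCUTransformer(fill_missing=True)`), and all-zero rows or
columns are dropped with a warning. Axis signs are fixed by making the
largest-magnitude column loading positive, so output is reproducible
across LAPACK backends. Both raw axis shares (λ_k/Σλ) and
first-k-renormalised shares are reported, because published two-axis CA
plots sometimes renormalise the displayed axes over themselves.

## Synthetic data

The generator draws amino acids i.i.d. and codons i.i.d. within families
(no codon-pair structure — sufficient for every index in scope). Three
knobs map onto the biology:

* `gc3` ∈ (0,1): mass given to G/C-ending codons within each family, so
  expected synonymous third-position G+C equals `gc3` exactly;
* within-class third-base preferences (default neutral; the AT-rich
  panel uses T:0.8/A:0.2 and G:0.9/C:0.1), which add bias beyond
  composition and push genes below the ENC expected curve;
* `gc12`: matched by exponentially tilting uniform amino-acid
  frequencies toward residues with G+C-rich first/second codon
  positions (solved by bisection), since those positions are fixed by
  the protein.

Met and Trp are omitted from generated proteins (they carry no
synonymous signal and would couple GC3 to the protein composition); no
stops are emitted, so all output passes strict validation.

`at_rich_panel(n, seed)` emulates the tapeworm study conditions: 94 % of
sequences from an AT-rich model (GC3 ≈ 0.20, GC12 ≈ 0.365, hence
GC ≈ 31 %) and ~6 % from a GC-rich outlier model (GC3 ≈ 0.47,
GC12 ≈ 0.45), with 1-percentage-point Gaussian jitter on targets and 540
codons per CDS — the approximate length, composition and outlier fraction
of the real 90-strain set. `regime_panel` encodes the neutrality
dichotomy: in the mutation regime one per-sequence composition target
(uniform over `gc3_range`, default 0.10–0.50, jitter 2 pp) drives both
GC3 and GC12 (generative slope 1); in the selection regime GC12 is pinned
at 0.36 while GC3 varies (slope 0). Defaults are 100 sequences of 300
codons. The recovered OLS slope in the mutation regime sits slightly
below 1 (≈ 0.92–0.98) because sampling noise in realized GC3 attenuates
the regression — the expected behaviour of an errors-in-x design, within
the tested recovery band.

What the generators do **not** emulate: phylogenetic correlation between
sequences (real strain sets are nearly clonal with a few divergent
members; ours are independent draws), codon-pair and dinucleotide
effects, gene-length/expression correlations, and amino-acid composition
differences between genes. Tests passing on synthetic panels therefore
validate the estimators and the pipeline plumbing, not any biological
claim about real data.

## Packaged reference tables

`load_fixture("table1")` is the published 90-strain compositional table
(15 columns; the source prints its GC3 column twice — it is stored once);
`load_fixture("table2")` the published 59-codon RSCU table for the
parasite and both hosts. These are preserved *as printed*, including
internal inconsistencies of the source: a handful of families do not sum
to their degeneracy beyond rounding (parasite Pro and Gln; human Ala,
Arg, Leu; bovine Gly, Leu, Ser), and the printed means row for the C and
C3 columns does not match the actual column means. The integrity tests
document these exactly rather than silently repairing data. CAI weights
are within-family ratios and are insensitive to the family-sum issue.

## Numerical choices and limitations

* Thresholds 1.6/0.6, weight floor 0.01, e-CAI coverage 0.95 and n ≥ 100,
  ENC cap 61 are defaults, all overridable.
* Ties: preferred-codon ties broken alphabetically and flagged; Spearman
  uses average ranks; CA axis signs fixed as above.
* Degenerate inputs: empty count tables, zero-norm RSCU vectors,
  zero-variance GC3, all-identical CA rows and single-base composition
  for the e-CAI null all raise typed errors or return flagged results —
  see each module's docstrings.
* Dataset-scale quantities that depend on the exact private inputs of
  the original study (its COA axis shares, its neutrality r/p, its e-CAI
  values, text ENC ranges that contradict its own table) are not
  reproduced here and are not asserted anywhere; the pipeline reports
  whatever the supplied data give.
* Problem sizes used in the shipped checks: panels of 90 × 540 codons
  and 100 × 300 codons, nulls of 100–500 random sequences, convergence
  checks at 50 000 codons — small enough to run anywhere in seconds yet
  deep enough that Monte-Carlo bands (binomial/SE arguments given above)
  hold comfortably.
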
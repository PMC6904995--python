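# Methods

## Problem and model

The package classifies each residue of a protein chain as binding or
not binding a given acid-radical-ion ligand, using only sequence-derived
information.  The unit of classification is a window of odd length L
centred on the residue; both chain ends are padded with (L−1)/2 dummy
`X` symbols so every residue owns exactly one window.  A window is
positive iff its centre residue is annotated as binding the ligand
under study; neighbouring residues of a binding site therefore produce
negative windows that partially overlap positive ones, which is the
honest construction for per-residue prediction and the main source of
hard negatives.

Five discrete tracks describe each position: amino acid (20 + `X`),
polarization charge (K/R/P positive, D/E negative, 15 uncharged, + `X`),
a six-class hydropathy grouping ({R,D,E,N,Q,K,H}, {L,I,V,A,M,F},
{S,T,Y,W}, {P}, {G}, {C}, + `X`), secondary structure (H/E/C + `X`) and
solvent exposure (exposed iff RSA > 25%, else buried, + `X`).  Two
deliberate oddities of the charge map — proline counted as positively
charged and histidine as uncharged — are kept exactly as the method
defines them; the hydropathy class labels are treated as opaque group
names.  RSA exactly 0.25 is classed buried: the published definition
uses only strict inequalities, so the boundary had to be assigned by
convention, and the left-closed choice is fixed and documented here.
SS and RSA tracks are consumed as given input (whatever predictor
produced them); the package does not compute them.

## Feature extraction

**Increment of diversity.**  D(X) = N ln N − Σ nᵢ ln nᵢ with
0 ln 0 = 0; ID(X, Y) = D(X+Y) − D(X) − D(Y).  Logarithms are natural
throughout: the base multiplies every ID by a constant, which the
min–max feature scaling removes.  Training sources pool whole-segment
symbol counts (including `X`, so edge windows are well defined) over
all training windows of a class, one source pair per track; this
whole-segment pooling is one of two defensible readings and is stated
here prominently.  Each window contributes (ID versus positive source,
ID versus negative source) per track: the 10-dimensional ID block.

**Position weight scoring matrices.**  Per class and track,
pᵢⱼ = (nᵢⱼ + √Nᵢ/A)/(Nᵢ + √Nᵢ) with A the alphabet size including `X`
(A = 21 for amino acids; the same formula generalizes to the smaller
property alphabets), mᵢⱼ = ln(pᵢⱼ/p₀ⱼ), and conservation
Cᵢ = (100/ln A)(Σⱼ pᵢⱼ ln pᵢⱼ + ln A) ∈ [0, 100], zero exactly at a
uniform position.  The background p₀ is not part of the published
definition; it is taken as the pooled empirical symbol frequency over
all training windows of both classes, with zero entries floored at
1/(10·A·total) and the vector renormalized so log-odds stay finite.  A
per-class background would be the main alternative; pooled was chosen
as the conventional log-odds reference.  One consequence of the floor
is that symbols absent from training get large positive log-odds, so a
window can only reach S = 1 when every symbol it contains was actually
observed — harmless for classification (both classes' matrices share
the background) but worth knowing when reading raw scores.  The score
S = Σ Cᵢ(mᵢ,ⱼᵢ − mᵢ,min) / Σ Cᵢ(mᵢ,max − mᵢ,min) is bounded in [0, 1]
and base-invariant; a matrix whose every position is uniform has a zero
denominator and refuses to score rather than return a silent default.

**Regimes.**  C: per-track symbol frequencies over non-`X` positions
(padding must not look like signal), 20+3+6+3+2 = 34 columns.  P: the
2L log-odds lookups against the positive and negative matrix per track,
10L columns; `X` is a scored symbol here, matching the 21-symbol matrix
definition.  R: the ID pair then the S pair per track, 20 columns.
Features are min–max scaled per column on training rows; test values
may leave [0, 1] and are not clipped.  Scaling matters because raw 2L
log-odds would dominate Euclidean distances over composition-scale
features.

## Classification protocol

Euclidean KNN with odd k (every sensible published optimum is odd, and
odd k cannot tie a binary vote); distance ties break toward the lower
training-row index, making predictions fully deterministic.  Balanced
undersampling draws all positives plus an equal-count random negative
subset; the protocol repeats this 10 times and averages stratified
five-fold CV results.  Within every fold, sources, matrices, background
and scaler are rebuilt from that fold's training portion only; a fitted
extractor is a pure function of its training rows (hash-checked in the
tests).  Fold metrics are reported both pooled over fold confusion
counts and as the mean of per-fold metrics, since "average of five
results" admits both readings.  The optimal k is the per-resample
argmax-MCC k (ties toward smaller k) averaged over resamples and
rounded to the nearest odd integer (half-way means round down); the
optimal window length is the argmax of the resample-mean MCC of the P
regime over {5, 7, 9, 11, 13, 15, 17} (ties toward the smaller L).
Fold assignment is segment-level and stratified by label; segments of
one chain can land in different folds, a leakage risk inherited from
the protocol's definition, documented here, and avoidable via the
chain-level independent test.

The independent test splits chains 80/20 (no chain on both sides),
trains 10 balanced models on the training side, and takes their
majority vote on every window of the imbalanced held-out side; a 5–5
tie counts as negative (conservative).  Metrics with a zero denominator
are reported as 0 and flagged; MCC with a zero denominator factor is 0
by the standard convention.

## Synthetic data

The generator emulates the statistical shape the feature extractors
see in the real benchmarks: chains of 80–200 residues drawn from
Swiss-Prot-like background amino-acid frequencies, 3 binding sites per
chain, and position-specific enrichment over a halo of ±4 positions
around each binding residue (a 9-residue informative span, comparable
to the ~13-residue optimal windows of the real ligands).  Each offset
has one preferred residue, one preferred SS state and an exposure bias;
`motif_strength` (default 0.8) is the mixture weight between the
preferred symbol and a background draw, so strength 0 is an exact null
and strength 1 is deterministic.  What it does **not** emulate: real
ligand-specific chemistry, autocorrelation within SS/RSA tracks,
homology between chains, multiple ligands per chain, or annotation
noise.  Passing tests therefore show that the pipeline recovers planted
compositional/positional signal and is honest under the null — not that
real ions are predictable at any particular accuracy.

## Numerical choices and problem sizes

All randomness flows from one root seed expanded via `SeedSequence`
(per-resample, per-fold, per-split), so every result is reproducible
bit-for-bit.  Distances are squared Euclidean via `cdist`; stable
argsort implements the tie rule.  Probability rows of a PWSM sum to 1
to ≈1e−15 by construction; conservation values are clipped to [0, 100]
to absorb floating-point dust at the bounds.  Tests and the acceptance
script run desk-scale problems — tens to a few hundred synthetic
chains, reduced k grids (odd 1–31 or 1–101) for selection sweeps —
chosen as the smallest sizes at which the protocol's behaviour is
clearly resolved.

## Known limitations

Dataset construction stops at the published filters (resolution < 3 Å,
length > 50, both strict); sequence-identity reduction is consumed as
an externally produced representative list, not computed.  The KNN
reference set is held in memory and distances are computed densely —
fine at benchmark scale, not tuned for proteome scans.  One ligand is
analysed per run; chains binding several ligands need one run per
ligand code.
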
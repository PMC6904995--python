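# ionbind

Sequence-based prediction of acid-radical-ion binding residues (NO₂⁻,
CO₃²⁻, SO₄²⁻, PO₄³⁻ and similar ligands) in protein chains, for
structural bioinformaticians who have per-chain sequences, BioLip-style
binding annotations and predicted secondary-structure / solvent-
accessibility tracks, and want a transparent, fully deterministic
classifier rather than a black box.

## Method

Each residue is classified from an odd-length window of L residues
centred on it (chain ends are padded with a dummy residue `X`).  Every
window is described on five parallel property tracks: the amino acid
itself (21 symbols), polarization charge (K/R/P positive, D/E negative,
the rest uncharged), a six-class hydropathy grouping, predicted
secondary structure (H/E/C) and relative solvent accessibility
dichotomized at 25% into exposed/buried.

Two feature-compression devices turn windows into small vectors:

* **Increment of diversity (ID).**  For count vectors X, Y with totals
  N, M, the diversity is D(X) = N ln N − Σᵢ nᵢ ln nᵢ and the increment
  ID(X, Y) = D(X+Y) − D(X) − D(Y) ≥ 0, vanishing iff X ∝ Y.  Each
  window's per-track composition is scored against the pooled positive
  and negative training compositions, giving 2 values × 5 tracks.

* **Position weight scoring matrix (PWSM).**  Per class and track, the
  position-specific probabilities are smoothed with a √N pseudocount,
  pᵢⱼ = (nᵢⱼ + √Nᵢ/A)/(Nᵢ + √Nᵢ), turned into log-odds
  mᵢⱼ = ln(pᵢⱼ/p₀ⱼ) against a pooled empirical background, and weighted
  by the conservation Cᵢ = (100/ln A)(Σⱼ pᵢⱼ ln pᵢⱼ + ln A).  A window
  scores S = Σᵢ Cᵢ(mᵢ,ⱼᵢ − mᵢ,min) / Σᵢ Cᵢ(mᵢ,max − mᵢ,min) ∈ [0, 1].

Three feature regimes feed a Euclidean K-nearest-neighbours vote with
odd k: composition **C** (34 dims), position **P** (the 2L log-odds
profiles of both matrices per track, 10L dims), and refined **R** (the
ID pair plus the S pair per track, 20 dims regardless of L).  Because
binding residues are rare, every experiment draws a balanced set (all
positives plus an equal random negative sample) 10 times; stratified
five-fold cross-validation metrics (Sn, Sp, Acc, FPR, MCC) are averaged
over the resamples.  The optimal k is the resample-averaged argmax-MCC
k, and the optimal L is the argmax of the P-feature MCC over the grid
{5, 7, 9, 11, 13, 15, 17}.  An 80/20 chain-level split provides an
independent test on an imbalanced held-out side.

## Worked example

`examples/04_cross_validation.py` generates a synthetic benchmark of 60
chains with planted binding motifs, selects k per regime at L = 13 and
runs the resampled CV protocol:

```
feature      k*    Sn%    Sp%   Acc%   FPR%    MCC
C            11   99.2   71.3   85.3   28.7  0.735
P            35   99.7   98.6   99.1    1.4  0.982
R             3   99.9   98.4   99.2    1.6  0.983
```

Composition alone over-predicts (FPR 28.7%); position and refined
features both recover the planted signal almost perfectly, with the
refined regime doing so in 20 dimensions.  The other example scripts
walk through windowing/encoding, the ID measure, PWSM scoring and the
independent test; each prints a line explaining its numbers.

A thin CLI wraps the same functions for shell use:

```sh
ionbind simulate --seed 5 --out data
ionbind make-dataset --fasta data/chains.fasta --annotations data/annotations.tsv \
    --ligand SO4 --ss data/ss.tsv --rsa data/rsa.tsv --out segments
ionbind select   ... # optimal L and k
ionbind evaluate ... # CV or --independent hold-out, JSON + TSV archive
ionbind predict  ... # per-residue predictions with ensemble vote fractions
```

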
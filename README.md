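# colchain

Tools for characterizing **zebrafish type I collagen**, which — unlike the
tetrapod (α1)₂α2 heterotrimer — is built from *three* distinct chains:
α1(I), α2(I) and the teleost-specific α3(I) (genes *col1a1a*, *col1a2*,
*col1a1b*). The package is aimed at skeletal-biology and matrix-proteomics
groups who need to (a) annotate procollagen domains on fish chains by
alignment transfer from human/mouse references, (b) compute comparative
chain statistics (triplet structure, stability motifs, mass, pI, cysteine
and cross-link site conservation), (c) infer trimer stoichiometry from bulk
amino-acid hydrolysates, and (d) quantify α3(I)/α1(I) chain ratios from
spike-in SRM mass spectrometry.

## What it computes

**Domain annotation & identity.** Chains are compared by Needleman–Wunsch
global alignment (BLOSUM62, gap open 10, extend 0.5). Domain boundaries
(signal/N-propeptide, N-telopeptide, triple helix, C-telopeptide,
C-propeptide) are projected through alignment columns, as are individual
sites: cross-link Lys/Hyl residues (helix positions 87 and 930/933,
telopeptide 9^N/16^C), C-propeptide cysteines, and the 15-residue chain
recognition region.

**Chain features.** The collagenous domain is parsed into Gly-X-Y triplets;
GPP triplets (helix-stabilizing) and GG/GGG glycine runs (destabilizing)
are counted; theoretical average mass and Bjellqvist-pKa isoelectric point
are computed for any region.

**Trimer stoichiometry.** For candidate compositions (n₁, n₂, n₃) with
n₁+n₂+n₃ = 3, the theoretical residue-pair ratio is

    r(n) = Σₖ nₖ·Aₖ / Σₖ nₖ·Bₖ

with Aₖ, Bₖ the per-chain residue counts. A marker residue absent from
some chains (Tyr, theoretically absent in α1(I) and α3(I)) excludes
homotrimers at the 2·sd level; the diagnostic Ile/Leu ratio then selects
the nearest candidate, with z-scores, tie reporting, and an explicit
mixture-identifiability analysis (a bulk ratio cannot distinguish α1α2α3
from a balanced mix of (α1)₂α2 and (α3)₂α2).

**SRM quantitation.** Endogenous peptide amounts come from light/heavy
ratios times the spiked amount; the reporter peptide per protein is the one
with the highest detected amount (robust to variable proline
hydroxylation); per-tissue replicate ratios are summarized by the median
and Huber's M-estimate of scale (c = 1.5), and tissues are compared with a
Wilcoxon rank-sum test that is exact (full enumeration) for small samples.

A seeded synthetic-data module generates collagen-like chains, hydrolysate
measurements and SRM tables with known ground truth, so every pipeline is
testable end to end without downloads.

## Worked example

```bash
python analysis/01_simulate_inputs.py
python analysis/03_stoichiometry.py
```

prints, for the published bulk hydrolysate measurements:

```
published hydrolysate Ile/Leu measurements:
  skin    0.565 +- 0.050 -> 1:1:1 (|z| = 0.38)
  bone    0.535 +- 0.065 -> 1:1:1 (|z| = 0.75)
  scales  0.553 +- 0.097 -> 1:1:1 (|z| = 0.32)
```

Each tissue's observed Ile/Leu ratio is closest to the theoretical value of
the 1:1:1 heterotrimer (0.584, vs 0.770 for 2:1:0 and 0.398 for 0:1:2), and
the |z| values show the fit is well within measurement error — the
α1α2α3 heterotrimer is inferred in skin, bone and scales alike. The script
also shows that the Tyr marker alone removes 7 of the 10 unconstrained
candidate compositions, and that the bulk ratio leaves a one-parameter
family of trimer mixtures unresolved.

`python analysis/04_srm_quantitation.py` runs the SRM pipeline on the
simulated three-tissue design and recovers the built-in truth (bone
α3/α1 = 0.6 vs skin/scales = 1.0), e.g. median ratios 0.63 / 0.85 / 1.11
with bone distinguished from scales at α = 0.05 and skin vs scales called
equal.

## Layout

- `src/colchain/` — the library (sequence I/O, alignment, features,
  stoichiometry, SRM statistics, simulators, CLI `colchain`).
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — pytest suite incl. brute-force oracles.
- `docs/methods.md` — models, assumptions, parameter choices, limitations.
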
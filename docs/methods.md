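# Methods

## Sequence comparison and annotation transfer

Chains are aligned with Needleman–Wunsch global alignment, BLOSUM62,
gap open 10 and gap extend 0.5 (EMBOSS-style affine cost: a gap of length
L costs 10 + 0.5·(L−1)), via Biopython's `PairwiseAligner`; when several
alignments are co-optimal the aligner's first traceback is reported, which
is deterministic for fixed inputs and parameters. Published identity
figures for these chains were produced with a mix of alignment tools, so
identities computed here are expected to agree only within about one
percentage point; that tolerance is used wherever a printed identity is
checked. Choice of database record matters too: isoform choice can shift
full-chain identity by ~1%, so the accessions used for any reference set
should be recorded beside the FASTA (`data/reference_chains/README.md`).

Percent identity = 100 × (identical columns) / (columns where at least one
sequence has a residue), with terminal gap overhangs excluded — the
closest global analogue of the identity-over-aligned-span convention.
A `DomainMap` restriction counts only columns overlapping the named domain
of one of the two chains.

Domain boundaries are transferred by mapping each reference boundary to
the *first target residue at or after the boundary column*. This rule
makes transferred domains contiguous and non-overlapping by construction;
a domain whose image is empty raises an error naming the domain, and a
transferred triple helix that does not open on Gly triggers a warning
rather than an error (real N-terminal helix boundaries are fuzzy at the
one-residue level).

Coordinates are 0-based half-open internally and 1-based inclusive in all
reports. Cross-link sites use the field's conventional numbering: helix
coordinates start at 1 on the first Gly of the triple-helical domain
(positions 87, 930, 933), telopeptide coordinates at 1 on the first
telopeptide residue (9^N, 16^C, 5^N).

## Chain features

The collagenous span is parsed into Gly-X-Y triplets. With a domain map
the span is the annotated triple helix; without one it is the longest run
of consecutive in-frame triplets. Residues inside the span that break the
frame are kept as explicit interruption records, and triplets plus
interruptions always reconstruct the span exactly (property-tested).

Stability motifs: GPP is counted on the triplet frame only (a triplet
exactly equal to "GPP"), because the helix-stability argument concerns
triplets, not substrings. GG+GGG are maximal glycine runs of length 2 and
3 inside the helix span. Runs of length ≥ 4 have no canonical reading;
they are decomposed greedily into GGG units (a remainder of 2 counts as
one GG, a remainder of 1 is dropped) and flagged in the output so a user
can apply a different convention.

X/Y identity strips each triplet to its 2nd and 3rd residues,
concatenates, and aligns the reduced strings — removing the obligatory
glycines that otherwise inflate helix identity.

Composition, mass and pI are *theoretical* (pre-modification):
hydroxyproline/hydroxylysine count as Pro/Lys, and no PTM mass is added.
Mass uses average (not monoisotopic) residue masses (Biopython's table;
reported in kDa to 3 significant figures). The isoelectric point uses the
Bjellqvist pKa set (terminal groups plus D, E, C, Y, H, K, R) with
bisection of the net Henderson–Hasselbalch charge on pH ∈ [0, 14]; the
net charge is strictly decreasing in pH so the root is unique, and the
residual charge at the returned pI is below 0.01. Reported to one decimal.

Conservation conventions: at cross-link sites Lys counts as conserved
(hydroxylysine is indistinguishable from Lys at sequence level); Arg or
His at a site is flagged as a basic substitution, and the surrounding ±5
residues are scanned for a compensating Lys, reported by signed offset.
In the recognition-region comparison a gap column counts as a difference.

## Trimer stoichiometry inference

Candidates are integer compositions (n₁, n₂, n₃) summing to 3; the default
constraint fixes a single α2 per trimer (the rule in tetrapods, supported
by the ~2:1 densitometric ratio of the upper to lower α bands), leaving
2:1:0, 1:1:1, 0:1:2. The theoretical residue-pair ratio of a candidate is
the count-weighted ratio of summed residue totals, invariant under
rescaling the per-chain counts.

Marker exclusion: a candidate is excluded when its expected marker count
per trimer differs from the observed count by more than 2·sd
(conventional, configurable). If the marker is absent from every chain
yet observed, a contamination warning is raised and nothing is excluded.

Selection is nearest-candidate in absolute deviation; deviations within
1e-9 are reported as a tie, never silently broken. The winner's
z = deviation/sd is reported, with |z| > 3 flagged as "no candidate fits".
Measured sd values pooled from replicate analyses are treated as standard
deviations (the alternative half-range reading would only loosen the
z-scores, not change selections).

Compositions default to the triple-helix region only: pepsin-solubilized
collagen retains the helix plus short telopeptide stubs, and the helix
dominates the counts. Any other region (or `"full"`) can be passed to
`aa_composition` to probe sensitivity; for the zebrafish-like counts the
candidate separations (~0.19 in Ile/Leu) dwarf the region effect.

Mixture identifiability: for mixture fractions f_t ≥ 0, Σf_t = 1 the
pooled ratio is (Σ f_t·A_t)/(Σ f_t·B_t). Two species give a unique
solution or infeasibility; three give a one-parameter feasible segment,
sampled on a 101-point grid of the first fraction. The balanced mixture
of 2:1:0 and 0:1:2 pools to exactly the 1:1:1 totals — the algebraic
identity behind the statement that a bulk ratio cannot exclude such
mixtures.

`diagnostic_ranking` scores every ordered residue pair by the minimum
pairwise separation of candidate ratios normalized by the mean ratio;
pairs whose denominator counts are equal across candidates and whose
numerator is maximally chain-discriminating (Ile/Leu among them for the
zebrafish-like compositions) tie for the top score.

### Zebrafish-like chain compositions

The simulators need per-chain Ile/Leu/Tyr counts. The published per-chain
ratios (α1: 0.92, α3: 0.36) and the three candidate-trimer ratios
(0.770 / 0.584 / 0.398) jointly determine the relative counts up to scale;
solving and rounding at a realistic Leu abundance of 25 per helix gives
Ile = (23, 12, 9), Leu = (25, 25, 25), Tyr = (0, 2, 0) for (α1, α2, α3),
which reproduces the candidate ratios within ±0.004 and the adjacent-
candidate separation of ≈ 0.19. These counts are the package defaults for
hydrolysate simulation; non-diagnostic residues share a common
collagen-helix backbone since they never enter the ratios.

## SRM quantitation

Peptide amount = (light/heavy) × spiked fmol. A zero or missing heavy
intensity yields a flagged missing value, never a zero — a zero would
silently distort downstream ratios. Per protein, the reporter peptide is
the one with the highest median detected amount; highest-abundance
selection counters hydroxylation bias because a peptide whose unmodified
form is depleted by variable proline hydroxylation reports a lower
apparent amount. Exact median ties resolve lexicographically and are
flagged.

Per-tissue summaries pool biological and technical replicates (the study
design: 3 × 2 per tissue): median, plus Huber's M-estimate of scale with
winsorizing constant 1.5, location fixed at the median, initialized at the
normalized MAD and iterated to relative tolerance 1e-8 (max 100
iterations; statsmodels implementation). Degenerate samples (zero MAD)
return scale 0. The per-tissue CV is 100 × scale/median.

The Wilcoxon rank-sum p-value is exact — full enumeration of all
C(n+m, n) group assignments, two-sided p = min(1, 2·min(P(W≤w), P(W≥w)))
— whenever n+m ≤ 12 without ties (auto mode), else a normal approximation
with midranks, tie correction and continuity correction. The exact branch
is validated against literal permutation enumeration for every sample-size
split with n+m ≤ 10 and against an independent library implementation.

## Synthetic data

Noise models: Gaussian on hydrolysate ratios (the small-error regime of
amino-acid analysis; default sd 0.05, the low end of the 0.05–0.10
replicate spread reported for such measurements, with n = 3 analyses per
tissue), and lognormal on MS intensities (default σ 0.15 per intensity).
Per-peptide detection efficiencies in (0, 1] (default 1.0, 0.7, 0.5,
0.35 across the four peptides) emulate hydroxylation-dependent depletion
of the monitored light form; per-peptide response factors cancel in
light/heavy by construction. Default tissue truths are bone 0.6 and
skin/scales 1.0, reproducing the qualitative published pattern (external
tissues alike, bone distinct).

Every generator is deterministic under a fixed seed, and per-tissue/
replicate substreams are derived from the seed by counter
(`SeedSequence(seed, spawn_key=...)`), so adding a tissue or replicate
never perturbs earlier draws. The chain generator rejection-samples
non-motif triplets away from "GPP" so the GPP motif frequency parameter is
exact, and returns the true domain map beside the sequence.

What the simulators do *not* emulate: correlated run-level effects shared
between peptides, hydrolysis losses and derivatization chemistry of amino-
acid analysis, retention-time or interference artifacts, and real
inter-chain sequence homology (simulated chains are independent draws, so
their identities are far below the ~75–80% of real orthologs). Passing
simulation tests therefore demonstrates correctness of the estimators
under the stated error models, not instrument-level realism.

## Problem sizes and measured behavior

The test suite and the acceptance script size their simulations to run on
a single CPU in minutes: 1 000 hydrolysate simulations for the recovery
rate, 100 SRM simulations for ratio recovery, 500 for power, 300 for null
retention. Measured under the default conditions: stoichiometry recovery
100% (truth 1:1:1, noise sd 0.05); SRM median-ratio recovery error ~3%;
power at a 2-fold tissue difference 92%; null retention ~95% (the
two-sided exact test is conservative at n = 6 + 6).

A sensitivity note on power: with independent lognormal(σ = 0.15) noise on
each of the four intensities entering a replicate ratio, the ratio carries
σ ≈ 0.30, and a 1.67-fold difference (e.g. 0.6 vs 1.0) is detected in only
~70% of runs at n = 6 + 6 — the design reliably resolves 2-fold but not
substantially smaller differences. Printed replicate-level statistics from
the original measurements (specific p-values, a 24% CV) depend on raw
intensities that are not published and are covered here by these
behavioral checks instead.

## Known limitations

- All composition/mass/pI statistics are sequence-level; no PTM modeling.
- Thermal-stability is only qualitatively linked to GPP and GG/GGG counts;
  no T_m prediction is attempted.
- The aligner reports a single optimum; co-optimal alignments near domain
  boundaries can shift transferred boundaries by a residue or two in
  low-complexity regions.
- Stoichiometry inference assumes exactly three chain species and integer
  trimer compositions; fractional bulk compositions are only addressed
  through the mixture analysis.
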
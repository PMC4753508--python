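"""Trimer stoichiometry inference from amino-acid hydrolysate ratios.

Type I collagen is a trimer of three alpha chains.  With three candidate
chains (alpha1, alpha2, alpha3) and the biologically motivated constraint
of a single alpha2 per trimer, the candidate stoichiometries are 2:1:0,
1:1:1 and 0:1:2.  Because the chains differ in theoretical amino-acid
composition, a bulk hydrolysate residue-pair ratio (Ile/Leu is the most
diagnostic pair) selects among candidates, and a marker residue absent
from some chains (Tyr, theoretically absent in alpha1 and alpha3)
excludes homotrimers outright.

A bulk ratio cannot distinguish a single trimer species from mixtures
whose pooled composition coincides with it; :func:`mixture_consistency`
maps out exactly which mixtures remain consistent with a measurement.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import CompositionVector

CHAIN_KEYS = ("alpha1", "alpha2", "alpha3")


@dataclass(frozen=True, order=True)
class TrimerComposition:
    """Integer chain counts (n_alpha1, n_alpha2, n_alpha3) summing to 3."""

    n_alpha1: int
    n_alpha2: int
    n_alpha3: int

    def __post_init__(self) -> None:
        counts = (self.n_alpha1, self.n_alpha2, self.n_alpha3)
        if any(c < 0 for c in counts):
            raise ValueError("negative chain count")
        if sum(counts) != 3:
            raise ValueError(f"chain counts {counts} do not sum to 3")

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_alpha1, self.n_alpha2, self.n_alpha3)

    @property
    def label(self) -> str:
        return ":".join(str(c) for c in self.counts)


@dataclass
class HydrolysateMeasurement:
    """One tissue's observed residue-pair ratio from amino-acid analysis."""

    tissue: str
    ratio_pair: tuple[str, str]
    observed_ratio: float
    sd: float
    marker_counts: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.observed_ratio <= 0:
            raise ValueError("observed ratio must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


def _residue_totals(
    composition: TrimerComposition,
    chain_compositions: Mapping[str, CompositionVector],
    residue: str,
) -> float:
    return sum(
        n * chain_compositions[key].counts.get(residue, 0)
        for n, key in zip(composition.counts, CHAIN_KEYS)
    )


def theoretical_ratio(
    composition: TrimerComposition,
    chain_compositions: Mapping[str, CompositionVector],
    pair: tuple[str, str],
) -> float:
    """Residue-pair ratio of a trimer: summed A counts over summed B counts.

    Invariant under rescaling all chain counts (mole fractions and
    absolute counts give the same ratio).
    """
    res_a, res_b = pair
    num = _residue_totals(composition, chain_compositions, res_a)
    den = _residue_totals(composition, chain_compositions, res_b)
    if den == 0:
        raise ZeroDivisionError(
            f"composition {composition.label} has no {res_b} residues"
        )
    return num / den


def enumerate_candidates(
    n_alpha1: int | None = None,
    n_alpha2: int | None = None,
    n_alpha3: int | None = None,
) -> list[TrimerComposition]:
    """All trimer compositions satisfying the fixed-count constraints.

    Ordered by descending n_alpha1 (then descending n_alpha2) so the
    canonical candidate triple comes out as [2:1:0, 1:1:1, 0:1:2].
    Contradictory constraints yield an empty list with a warning.
    """
    fixed = {"n_alpha1": n_alpha1, "n_alpha2": n_alpha2, "n_alpha3": n_alpha3}
    out = []
    for a1 in range(3, -1, -1):
        for a2 in range(3 - a1, -1, -1):
            a3 = 3 - a1 - a2
            cand = TrimerComposition(a1, a2, a3)
            if all(
                v is None or getattr(cand, k) == v for k, v in fixed.items()
            ):
                out.append(cand)
    if not out:
        warnings.warn(f"contradictory constraints {fixed}: no candidate sums to 3", stacklevel=2)
    return out


@dataclass
class Exclusion:
    composition: TrimerComposition
    reason: str


def marker_residue_test(
    measurement: HydrolysateMeasurement,
    candidates: Sequence[TrimerComposition],
    chain_compositions: Mapping[str, CompositionVector],
    marker: str = "Y",
    threshold: float = 2.0,
) -> list[Exclusion]:
    """Exclude candidates inconsistent with a marker-residue count.

    A candidate is excluded when its expected marker count per trimer
    deviates from the observed count by more than ``threshold`` SDs.
    Tyr, absent from both alpha1 and alpha3, excludes their homotrimers
    whenever ~2 Tyr per trimer are detected (the single alpha2's share).
    """
    if not measurement.marker_counts or marker not in measurement.marker_counts:
        raise ValueError(f"measurement lacks marker counts for {marker!r}")
    observed, sd = measurement.marker_counts[marker]
    all_zero = all(
        chain_compositions[key].counts.get(marker, 0) == 0 for key in CHAIN_KEYS
    )
    if all_zero and observed > 0:
        warnings.warn(
            f"marker {marker!r} absent from every chain but observed at "
            f"{observed:g}: possible contamination; no exclusions applied",
            stacklevel=2,
        )
        return []
    exclusions = []
    for cand in candidates:
        expected = _residue_totals(cand, chain_compositions, marker)
        if abs(observed - expected) > threshold * sd:
            exclusions.append(
                Exclusion(
                    cand,
                    f"expected {marker} count {expected:g} vs observed "
                    f"{observed:g} +- {sd:g} (>{threshold:g} sd)",
                )
            )
    return exclusions


@dataclass
class CandidateFit:
    composition: TrimerComposition
    theoretical: float
    deviation: float
    z_score: float


@dataclass
class InferenceResult:
    tissue: str
    fits: list[CandidateFit]
    selected: list[TrimerComposition]
    exclusions: list[Exclusion] = field(default_factory=list)
    poor_fit: bool = False  # selected candidate's |z| > 3

    @property
    def is_tie(self) -> bool:
        return len(self.selected) > 1

    @property
    def best(self) -> CandidateFit:
        sel = self.selected[0]
        return next(f for f in self.fits if f.composition == sel)


TIE_TOL = 1e-9


def infer_composition(
    measurement: HydrolysateMeasurement,
    candidates: Sequence[TrimerComposition],
    chain_compositions: Mapping[str, CompositionVector] | None = None,
    theoretical_values: Mapping[TrimerComposition, float] | None = None,
    exclusions: Sequence[Exclusion] = (),
) -> InferenceResult:
    """Select the candidate stoichiometry nearest the observed ratio.

    Theoretical ratios come either from chain compositions or from an
    explicit ``theoretical_values`` table.  The selected candidate
    minimizes absolute deviation among non-excluded candidates; ties
    (deviations within 1e-9) are reported as a tie set, never broken.
    The z-score deviation/sd of the winner is a goodness-of-fit flag
    (|z| > 3 marks a poor fit).
    """
    if theoretical_values is None:
        if chain_compositions is None:
            raise ValueError("need chain_compositions or theoretical_values")
        theoretical_values = {
            c: theoretical_ratio(c, chain_compositions, measurement.ratio_pair)
            for c in candidates
        }
    excluded = {e.composition for e in exclusions}
    fits = []
    for cand in candidates:
        theo = theoretical_values[cand]
        dev = abs(measurement.observed_ratio - theo)
        z = dev / measurement.sd if measurement.sd > 0 else (0.0 if dev == 0 else float("inf"))
        fits.append(CandidateFit(cand, theo, dev, z))
    viable = [f for f in fits if f.composition not in excluded]
    if not viable:
        raise ValueError(f"{measurement.tissue}: all candidates excluded")
    best_dev = min(f.deviation for f in viable)
    selected = [f.composition for f in viable if f.deviation <= best_dev + TIE_TOL]
    best_fit = next(f for f in viable if f.composition == selected[0])
    return InferenceResult(
        tissue=measurement.tissue,
        fits=fits,
        selected=selected,
        exclusions=list(exclusions),
        poor_fit=bool(best_fit.z_score > 3),
    )


@dataclass
class MixtureResult:
    feasible: bool
    fractions: list[tuple[float, ...]]
    achievable_range: tuple[float, float]
    note: str = ""


def mixture_consistency(
    observed_ratio: float,
    trimer_types: Sequence[TrimerComposition],
    chain_compositions: Mapping[str, CompositionVector],
    pair: tuple[str, str],
    grid_points: int = 101,
) -> MixtureResult:
    """Which mixtures of trimer species reproduce an observed bulk ratio.

    For mixture fractions f_t >= 0 summing to 1, the pooled ratio is
    (sum f_t A_t)/(sum f_t B_t) with A_t, B_t the per-trimer summed
    residue counts.  Two types give a unique solution (or infeasible);
    three types give a one-parameter feasible segment, sampled on a
    ``grid_points`` grid of the first fraction.  An observed ratio outside
    the convex range of achievable ratios is reported infeasible.
    """
    if len(trimer_types) < 2:
        raise ValueError("need at least two trimer types")
    res_a, res_b = pair
    A = [_residue_totals(t, chain_compositions, res_a) for t in trimer_types]
    B = [_residue_totals(t, chain_compositions, res_b) for t in trimer_types]
    if any(b == 0 for b in B):
        raise ZeroDivisionError("a trimer type has no denominator residues")
    ratios = [a / b for a, b in zip(A, B)]
    lo, hi = min(ratios), max(ratios)
    r = observed_ratio

    if len(trimer_types) == 2:
        # f*(A1 - r*B1) + (1-f)*(A2 - r*B2) = 0
        g1 = A[0] - r * B[0]
        g2 = A[1] - r * B[1]
        if abs(g1 - g2) < 1e-12:
            if abs(g1) < 1e-12:
                return MixtureResult(True, [(f, 1 - f) for f in np.linspace(0, 1, grid_points)], (lo, hi), "all fractions feasible (types indistinguishable at this ratio)")
            return MixtureResult(False, [], (lo, hi), "observed ratio not achievable")
        f = g2 / (g2 - g1)
        if -1e-9 <= f <= 1 + 1e-9:
            f = min(1.0, max(0.0, f))
            return MixtureResult(True, [(f, 1 - f)], (lo, hi))
        return MixtureResult(False, [], (lo, hi), "observed ratio outside the achievable range")

    if len(trimer_types) != 3:
        raise NotImplementedError("mixtures of 2 or 3 trimer types are supported")

    pts: list[tuple[float, ...]] = []
    for f1 in np.linspace(0.0, 1.0, grid_points):
        m = 1.0 - f1
        # solve for f2 in [0, m]: f1*g1 + f2*g2 + (m-f2)*g3 = 0
        g1 = A[0] - r * B[0]
        g2 = A[1] - r * B[1]
        g3 = A[2] - r * B[2]
        denom = g2 - g3
        rhs = -(f1 * g1 + m * g3)
        if abs(denom) < 1e-12:
            if abs(rhs) < 1e-9:
                pts.append((round(f1, 12), m / 2, m / 2))
            continue
        f2 = rhs / denom
        if -1e-9 <= f2 <= m + 1e-9:
            f2 = min(m, max(0.0, f2))
            pts.append((round(f1, 12), f2, m - f2))
    if not pts:
        return MixtureResult(False, [], (lo, hi), "observed ratio outside the achievable range")
    return MixtureResult(True, pts, (lo, hi))


def diagnostic_ranking(
    chain_compositions: Mapping[str, CompositionVector],
    candidates: Sequence[TrimerComposition],
    residues: str = "ACDEFGHIKLMNPQRSTVWY",
) -> list[tuple[tuple[str, str], float, dict[TrimerComposition, float]]]:
    """Rank residue pairs by how well they separate the candidates.

    For every ordered pair (A, B) whose denominator is nonzero for all
    candidates, the score is the minimum pairwise separation of the
    candidates' theoretical ratios, normalized by the mean ratio.  A high
    score means a bulk measurement of that pair discriminates sharply —
    Ile/Leu is the canonical choice for the zebrafish chains.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidates to rank separability")
    results = []
    for res_a, res_b in itertools.permutations(residues, 2):
        try:
            ratios = {
                c: theoretical_ratio(c, chain_compositions, (res_a, res_b))
                for c in candidates
            }
        except ZeroDivisionError:
            continue
        vals = list(ratios.values())
        min_sep = min(
            abs(x - y) for x, y in itertools.combinations(vals, 2)
        )
        mean = float(np.mean(vals))
        score = min_sep / mean if mean > 0 else 0.0
        results.append(((res_a, res_b), score, ratios))
    results.sort(key=lambda item: (-item[1], item[0]))
    return results
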
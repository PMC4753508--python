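"""Spike-in SRM quantitation of alpha3(I)/alpha1(I) chain ratios.

Selected reaction monitoring with stable-isotope-labeled (heavy) spike-in
peptides yields absolute peptide amounts from the light/heavy intensity
ratio.  Because endogenous collagen peptides carry variable proline
hydroxylation, different proteotypic peptides of the same chain report
systematically different amounts (the unmodified target form is depleted
by hydroxylation); the peptide with the highest detected amount per
protein is the least biased and is used as the reporter.  Per-replicate
alpha3/alpha1 ratios are then summarized per tissue by the median and
Huber's robust scale, and tissues are compared pairwise with the Wilcoxon
rank-sum test (exact by enumeration for small samples).

SRM tables are plain pandas DataFrames with columns
``protein, peptide, tissue, bio_rep, tech_rep, light_area, heavy_area,
spike_fmol``.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.robust.scale import Huber, mad

SRM_COLUMNS = [
    "protein",
    "peptide",
    "tissue",
    "bio_rep",
    "tech_rep",
    "light_area",
    "heavy_area",
    "spike_fmol",
]


def read_srm_table(path: str | Path) -> pd.DataFrame:
    """Read and validate an SRM TSV table."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SRM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SRM table missing column(s): {sorted(missing)}")
    if (df["light_area"] < 0).any() or (df["heavy_area"] < 0).any():
        raise ValueError("negative intensities in SRM table")
    if (df["spike_fmol"] <= 0).any():
        raise ValueError("non-positive spike amounts in SRM table")
    return df


def peptide_amount(light: float, heavy: float, spike: float) -> float:
    """Endogenous peptide amount in fmol: (light/heavy) x spiked fmol.

    A zero/invalid heavy intensity means the spiked standard was not
    detected, so the row is not quantifiable: returns NaN, never raises.
    """
    if spike <= 0:
        raise ValueError("spike amount must be positive")
    if heavy <= 0 or not math.isfinite(heavy):
        return float("nan")
    return (light / heavy) * spike


def add_amounts(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with an ``amount_fmol`` column (NaN = not quantifiable)."""
    out = table.copy()
    heavy = out["heavy_area"].to_numpy(dtype=float)
    light = out["light_area"].to_numpy(dtype=float)
    spike = out["spike_fmol"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        amount = np.where(heavy > 0, light / heavy * spike, np.nan)
    out["amount_fmol"] = amount
    return out


def select_reporter_peptide(amounts: pd.DataFrame) -> tuple[str, bool]:
    """Pick one protein's reporter peptide: highest median amount.

    ``amounts`` holds one protein's rows with ``peptide`` and
    ``amount_fmol`` columns.  The median is taken across quantified
    replicates.  Exact median ties resolve to the lexicographically first
    peptide and are flagged.
    """
    medians = (
        amounts.dropna(subset=["amount_fmol"])
        .groupby("peptide")["amount_fmol"]
        .median()
    )
    if medians.empty:
        raise ValueError("no quantifiable peptide for reporter selection")
    best = medians.max()
    winners = sorted(medians.index[medians == best])
    return winners[0], len(winners) > 1


def replicate_ratio(amount_num: float, amount_den: float) -> float:
    """Per-replicate ratio of two reporter amounts; NaN if not computable."""
    if not math.isfinite(amount_num) or not math.isfinite(amount_den) or amount_den <= 0:
        return float("nan")
    return amount_num / amount_den


def replicate_ratios(
    table: pd.DataFrame,
    protein_num: str,
    protein_den: str,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-(tissue, replicate) reporter-amount ratios for two proteins.

    Runs the quantitation pipeline: light/heavy amounts, reporter-peptide
    selection per protein (across all tissues and replicates), then the
    numerator/denominator reporter ratio per replicate.  Replicates where
    the ratio is not computable are dropped with a warning.
    """
    quant = add_amounts(table)
    reporters: dict[str, str] = {}
    for protein in (protein_num, protein_den):
        sub = quant[quant["protein"] == protein]
        if sub.empty:
            raise ValueError(f"protein {protein!r} not in SRM table")
        peptide, tie = select_reporter_peptide(sub)
        if tie:
            warnings.warn(f"reporter tie for {protein!r}; using {peptide!r}", stacklevel=2)
        reporters[protein] = peptide
    num = quant[(quant["protein"] == protein_num) & (quant["peptide"] == reporters[protein_num])]
    den = quant[(quant["protein"] == protein_den) & (quant["peptide"] == reporters[protein_den])]
    keys = ["tissue", "bio_rep", "tech_rep"]
    merged = num.merge(den, on=keys, suffixes=("_num", "_den"))
    ratios = [
        replicate_ratio(a, b)
        for a, b in zip(merged["amount_fmol_num"], merged["amount_fmol_den"])
    ]
    merged = merged.assign(ratio=ratios)
    n_bad = int(merged["ratio"].isna().sum())
    if n_bad:
        warnings.warn(f"dropped {n_bad} replicate(s) with unquantifiable ratio", stacklevel=2)
    out = merged.dropna(subset=["ratio"])[keys + ["ratio"]].reset_index(drop=True)
    return out, reporters


def huber_scale(
    values: Sequence[float],
    c: float = 1.5,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> float:
    """Huber M-estimate of scale with the location fixed at the median.

    Winsorizing constant 1.5, initialized at the normalized MAD,
    iterated to relative tolerance.  Degenerate samples (zero MAD)
    return 0.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if x.size == 1 or mad(x) == 0:
        return 0.0
    _, scale = Huber(c=c, tol=tol, maxiter=maxiter)(x, mu=np.median(x))
    return float(scale)


@dataclass
class TissueSummary:
    """Robust per-tissue summary of replicate alpha3/alpha1 ratios."""

    tissue: str
    n: int
    median_ratio: float
    huber_scale: float

    @property
    def cv(self) -> float:
        """Robust coefficient of variation, percent (Huber scale / median)."""
        if self.median_ratio == 0:
            return float("nan")
        return 100.0 * self.huber_scale / self.median_ratio


def tissue_summary(ratios: Sequence[float], tissue: str = "") -> TissueSummary:
    x = [r for r in ratios if math.isfinite(r)]
    if not x:
        raise ValueError(f"tissue {tissue!r}: no replicate ratios")
    return TissueSummary(
        tissue=tissue,
        n=len(x),
        median_ratio=float(np.median(x)),
        huber_scale=huber_scale(x),
    )


# --------------------------------------------------------------------------
# Wilcoxon rank-sum test


def _rank_sum_stat(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)  # midranks under ties
    return float(ranks[: len(x)].sum()), ranks


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "normal", "auto"] = "auto",
) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact mode enumerates all C(n+m, n) assignments of the pooled sample
    to the two groups and doubles the smaller tail:
    p = min(1, 2 * min(P(W <= w), P(W >= w))).  Auto mode is exact for
    n+m <= 12 without ties, otherwise a normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    w, ranks = _rank_sum_stat(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n + m
    if mode == "exact" or (mode == "auto" and n + m <= 12 and not has_ties):
        total = 0
        n_le = 0
        n_ge = 0
        for subset in itertools.combinations(range(n + m), n):
            ws = ranks[list(subset)].sum()
            total += 1
            if ws <= w + 1e-12:
                n_le += 1
            if ws >= w - 1e-12:
                n_ge += 1
        return min(1.0, 2.0 * min(n_le, n_ge) / total)

    # normal approximation with tie correction and continuity correction
    N = n + m
    mean_w = n * (N + 1) / 2.0
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1)) if N > 1 else 0.0
    var_w = n * m / 12.0 * ((N + 1) - tie_term)
    if var_w <= 0:
        return 1.0
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def spectral_count_ratio(count_num: float, count_den: float) -> float:
    """Label-free ratio of unique-peptide spectral counts; NaN on zero denominator."""
    if count_den <= 0:
        warnings.warn("zero denominator spectral count; ratio undefined", stacklevel=2)
        return float("nan")
    return count_num / count_den


@dataclass
class TissueComparison:
    summaries: dict[str, TissueSummary]
    pairwise: pd.DataFrame  # tissue_a, tissue_b, p_value, different
    overall_cv: float
    alpha: float
    excluded: list[str] = field(default_factory=list)


def compare_tissues(
    ratios: pd.DataFrame,
    alpha: float = 0.05,
    mode: Literal["exact", "normal", "auto"] = "auto",
) -> TissueComparison:
    """All pairwise rank-sum comparisons of per-tissue replicate ratios.

    ``ratios`` needs ``tissue`` and ``ratio`` columns (biological and
    technical replicates pooled).  Tissues with fewer than two replicates
    are excluded with a warning.  ``overall_cv`` is the classic percent
    CV pooled across every replicate of every tissue.
    """
    groups: dict[str, np.ndarray] = {}
    excluded = []
    for tissue, grp in ratios.groupby("tissue", sort=True):
        vals = grp["ratio"].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"tissue {tissue!r}: <2 replicates, excluded", stacklevel=2)
            excluded.append(str(tissue))
            continue
        groups[str(tissue)] = vals
    if len(groups) < 2:
        raise ValueError("need at least two tissues with >=2 replicates")
    summaries = {t: tissue_summary(v, t) for t, v in groups.items()}
    rows = []
    for ta, tb in itertools.combinations(sorted(groups), 2):
        p = wilcoxon_rank_sum(groups[ta], groups[tb], mode=mode)
        rows.append({"tissue_a": ta, "tissue_b": tb, "p_value": p, "different": p < alpha})
    pooled = np.concatenate(list(groups.values()))
    overall_cv = float(100.0 * pooled.std(ddof=1) / pooled.mean())
    return TissueComparison(
        summaries=summaries,
        pairwise=pd.DataFrame(rows),
        overall_cv=overall_cv,
        alpha=alpha,
        excluded=excluded,
    )
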
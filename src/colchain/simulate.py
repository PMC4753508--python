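"""Seeded synthetic data: collagen-like chains, hydrolysates, SRM tables.

Every generator is fully deterministic under a fixed seed.  Random
substreams for tissues and replicates are derived from the seed by
counter (``numpy.random.SeedSequence`` spawn keys), so adding a replicate
or a tissue never perturbs draws made for earlier ones.

Default parameters emulate the study conditions of the zebrafish
measurements the pipeline targets: hydrolysate ratio noise at the low end
of the reported error bars (SD 0.05, reported SDs span 0.05-0.10 over
three analyses), SRM designs with three biological x two technical
replicates and four proteotypic peptides per protein, lognormal intensity
noise (sigma 0.15), and per-peptide detection efficiencies spread over
(0, 1] to mimic variable proline hydroxylation depleting the unmodified
light peptide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Domain, DomainMap, DomainName, ProCollagenChain
from .features import CompositionVector
from .reference import zebrafish_like_compositions
from .stoichiometry import (
    HydrolysateMeasurement,
    TrimerComposition,
    _residue_totals,
)

#: X/Y-position residue weights for the helix (collagen X/Y positions are
#: Pro-rich), and a generic globular bias for propeptide flanks.
HELIX_XY_BIAS = {
    "P": 0.28, "A": 0.12, "E": 0.07, "R": 0.06, "D": 0.05, "S": 0.05,
    "K": 0.05, "Q": 0.04, "L": 0.04, "N": 0.03, "T": 0.03, "V": 0.03,
    "I": 0.03, "F": 0.02, "M": 0.01, "H": 0.01, "Y": 0.01,
}
FLANK_BIAS = {
    "A": 0.08, "C": 0.02, "D": 0.06, "E": 0.07, "F": 0.04, "G": 0.07,
    "H": 0.02, "I": 0.05, "K": 0.06, "L": 0.09, "M": 0.02, "N": 0.04,
    "P": 0.05, "Q": 0.04, "R": 0.05, "S": 0.07, "T": 0.05, "V": 0.07,
    "W": 0.01, "Y": 0.04,
}


def _sampler(bias: Mapping[str, float]):
    letters = sorted(bias)
    weights = np.array([bias[aa] for aa in letters], dtype=float)
    weights /= weights.sum()
    return letters, weights


def generate_chain(
    n_triplets: int = 338,
    motif_freqs: tuple[float, float, float] = (0.10, 0.03, 0.03),
    composition_bias: Mapping[str, float] | None = None,
    flanks: tuple[int, int] = (161, 246),
    telopeptides: tuple[int, int] = (17, 26),
    seed: int = 0,
    chain_id: str | None = None,
) -> tuple[ProCollagenChain, DomainMap]:
    """Sample a collagen-like procollagen chain with a known domain map.

    The helix is ``n_triplets`` G-X-Y triplets: each is GPP with
    probability ``motif_freqs[0]``; otherwise X (resp. Y) is Gly with
    probability ``motif_freqs[1]`` (resp. ``[2]``) — glycines in X/Y
    create the GG/GGG runs the stability statistics count — or else drawn
    from ``composition_bias``.  Flanks emulate the signal+N-propeptide and
    C-propeptide, joined to the helix by short telopeptides.  Returns the
    chain together with its true :class:`DomainMap`.
    """
    if n_triplets < 1:
        raise ValueError("n_triplets must be >= 1")
    gpp, gly_x, gly_y = motif_freqs
    for name, frac in (("gpp", gpp), ("gly_x", gly_x), ("gly_y", gly_y)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} fraction {frac} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    xy_letters, xy_weights = _sampler(composition_bias or HELIX_XY_BIAS)
    flank_letters, flank_weights = _sampler(FLANK_BIAS)

    def draw_xy(gly_frac: float) -> str:
        if rng.random() < gly_frac:
            return "G"
        return xy_letters[rng.choice(len(xy_letters), p=xy_weights)]

    triplets = []
    for _ in range(n_triplets):
        if rng.random() < gpp:
            triplets.append("GPP")
        else:
            # rejection-sample so the GPP motif frequency is exactly `gpp`
            while True:
                x, y = draw_xy(gly_x), draw_xy(gly_y)
                if (x, y) != ("P", "P"):
                    break
            triplets.append("G" + x + y)
    helix = "".join(triplets)

    def draw_flank(n: int) -> str:
        if n == 0:
            return ""
        idx = rng.choice(len(flank_letters), size=n, p=flank_weights)
        return "".join(flank_letters[i] for i in idx)

    n_pro, c_pro = flanks
    n_telo, c_telo = telopeptides
    parts = {
        DomainName.signal_n_propeptide: draw_flank(n_pro),
        DomainName.n_telopeptide: draw_flank(n_telo),
        DomainName.triple_helix: helix,
        DomainName.c_telopeptide: draw_flank(c_telo),
        DomainName.c_propeptide: draw_flank(c_pro),
    }
    sequence = ""
    domains = []
    pos = 0
    for name, seg in parts.items():
        if not seg:
            continue
        domains.append(Domain(name, pos, pos + len(seg)))
        sequence += seg
        pos += len(seg)
    chain = ProCollagenChain(
        id=chain_id or f"sim_chain_seed{seed}", sequence=sequence
    )
    return chain, DomainMap(chain_id=chain.id, domains=domains, chain_length=len(chain))


def _mixture_totals(
    truth: TrimerComposition | Sequence[tuple[TrimerComposition, float]],
    chain_compositions: Mapping[str, CompositionVector],
    residue: str,
) -> float:
    if isinstance(truth, TrimerComposition):
        return _residue_totals(truth, chain_compositions, residue)
    return sum(
        frac * _residue_totals(comp, chain_compositions, residue)
        for comp, frac in truth
    )


def simulate_hydrolysate(
    true_composition: TrimerComposition | Sequence[tuple[TrimerComposition, float]],
    chain_compositions: Mapping[str, CompositionVector] | None = None,
    pair: tuple[str, str] = ("I", "L"),
    noise_sd: float = 0.05,
    n_measurements: int = 3,
    marker: str = "Y",
    marker_noise_sd: float = 0.3,
    tissue: str = "synthetic",
    seed: int = 0,
) -> list[HydrolysateMeasurement]:
    """Simulate hydrolysate ratio measurements for a known trimer truth.

    The truth is a single composition or a mixture [(composition,
    fraction), ...].  Each measurement draws the true pooled ratio plus
    Gaussian noise; marker counts get their own Gaussian noise.  The
    ``sd`` field of every returned measurement is the sample SD across
    the ``n_measurements`` draws (0 when n = 1), mirroring how replicate
    analyses are reported as mean +- sd.
    """
    if noise_sd < 0 or n_measurements < 1:
        raise ValueError("noise_sd must be >= 0 and n_measurements >= 1")
    if chain_compositions is None:
        chain_compositions = zebrafish_like_compositions()
    num = _mixture_totals(true_composition, chain_compositions, pair[0])
    den = _mixture_totals(true_composition, chain_compositions, pair[1])
    true_ratio = num / den
    true_marker = _mixture_totals(true_composition, chain_compositions, marker)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ratios = true_ratio + rng.normal(0.0, noise_sd, size=n_measurements)
    markers = true_marker + rng.normal(0.0, marker_noise_sd, size=n_measurements)
    ratio_sd = float(np.std(ratios, ddof=1)) if n_measurements > 1 else 0.0
    marker_sd = float(np.std(markers, ddof=1)) if n_measurements > 1 else marker_noise_sd
    out = []
    for r, mk in zip(ratios, markers):
        out.append(
            HydrolysateMeasurement(
                tissue=tissue,
                ratio_pair=pair,
                observed_ratio=float(max(r, 1e-9)),
                sd=ratio_sd,
                marker_counts={marker: (float(max(mk, 0.0)), marker_sd)},
            )
        )
    return out


def aggregate_measurements(
    measurements: Sequence[HydrolysateMeasurement],
) -> HydrolysateMeasurement:
    """Pool replicate measurements into one mean +- sample-SD measurement."""
    if not measurements:
        raise ValueError("no measurements to aggregate")
    first = measurements[0]
    ratios = np.array([m.observed_ratio for m in measurements])
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else first.sd
    marker_counts = None
    if first.marker_counts:
        marker_counts = {}
        for res in first.marker_counts:
            vals = np.array([m.marker_counts[res][0] for m in measurements])
            msd = float(vals.std(ddof=1)) if len(vals) > 1 else first.marker_counts[res][1]
            marker_counts[res] = (float(vals.mean()), msd)
    return HydrolysateMeasurement(
        tissue=first.tissue,
        ratio_pair=first.ratio_pair,
        observed_ratio=float(ratios.mean()),
        sd=sd,
        marker_counts=marker_counts,
    )


@dataclass
class SRMTruth:
    """Ground truth underlying a simulated SRM table."""

    tissue_ratios: dict[str, float]
    efficiencies: tuple[float, ...]
    base_abundance_fmol: float
    spike_fmol: float
    noise_sd: float


DEFAULT_TISSUE_RATIOS = (("bone", 0.6), ("skin", 1.0), ("scales", 1.0))
DEFAULT_EFFICIENCIES = (1.0, 0.7, 0.5, 0.35)


def simulate_srm(
    tissues: Sequence[tuple[str, float]] = DEFAULT_TISSUE_RATIOS,
    n_bio: int = 3,
    n_tech: int = 2,
    n_peptides: int = 4,
    hydroxylation_efficiencies: Sequence[float] = DEFAULT_EFFICIENCIES,
    noise_sd: float = 0.15,
    spike_fmol: float = 50.0,
    base_abundance_fmol: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SRMTruth]:
    """Simulate a light/heavy spike-in SRM table with known tissue ratios.

    For each (tissue, biological, technical) replicate and each peptide of
    the alpha1 and alpha3 proteins:
    light = abundance x peptide response x detection efficiency x lognormal
    noise, heavy = spike x peptide response x lognormal noise.  Detection
    efficiency < 1 models variable proline hydroxylation depleting the
    unmodified (monitored) light form; the per-peptide response cancels in
    light/heavy.  Alpha3 abundance = true_ratio x alpha1 abundance.
    """
    if n_bio < 1 or n_tech < 1 or n_peptides < 1:
        raise ValueError("replicate and peptide counts must be >= 1")
    effs = tuple(hydroxylation_efficiencies)[:n_peptides]
    if len(effs) < n_peptides:
        raise ValueError("need one detection efficiency per peptide")
    if any(not 0 < e <= 1 for e in effs):
        raise ValueError("efficiencies must lie in (0, 1]")

    resp_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))
    responses = {
        (prot, p): float(resp_rng.lognormal(0.0, 0.3))
        for prot in ("alpha1", "alpha3")
        for p in range(n_peptides)
    }

    rows = []
    for ti, (tissue, true_ratio) in enumerate(tissues):
        for bio in range(1, n_bio + 1):
            for tech in range(1, n_tech + 1):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=seed, spawn_key=(1, ti, bio, tech))
                )
                for prot, abundance in (
                    ("alpha1", base_abundance_fmol),
                    ("alpha3", true_ratio * base_abundance_fmol),
                ):
                    for p in range(n_peptides):
                        resp = responses[(prot, p)]
                        light = abundance * effs[p] * resp * rng.lognormal(0.0, noise_sd)
                        heavy = spike_fmol * resp * rng.lognormal(0.0, noise_sd)
                        rows.append(
                            {
                                "protein": prot,
                                "peptide": f"{prot}_pep{p + 1}",
                                "tissue": tissue,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "light_area": light,
                                "heavy_area": heavy,
                                "spike_fmol": spike_fmol,
                            }
                        )
    truth = SRMTruth(
        tissue_ratios=dict(tissues),
        efficiencies=effs,
        base_abundance_fmol=base_abundance_fmol,
        spike_fmol=spike_fmol,
        noise_sd=noise_sd,
    )
    return pd.DataFrame(rows), truth
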
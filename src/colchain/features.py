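"""Per-chain descriptive statistics for collagen chains.

Covers the triplet structure of the collagenous domain (Gly-X-Y parsing,
GPP / GG+GGG stability motifs, X/Y-position identity), whole-chain and
per-domain amino-acid composition, theoretical average mass and
isoelectric point, and conservation reports for the functionally critical
sites: C-propeptide cysteines (inter- vs intra-chain disulfides), the
cross-link Lys/Hyl residues, and the 15-residue chain recognition region.

All statistics are "theoretical" in the sequence sense: hydroxyproline and
hydroxylysine are counted as Pro and Lys, and no post-translational mass
is added.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

from Bio.SeqUtils import molecular_weight
from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

from .align import AlignmentParams, PairwiseAlignment, global_align, map_site, percent_identity
from .core import DomainMap, DomainName, ProCollagenChain

WATER_DA = 18.0153


# --------------------------------------------------------------------------
# Triplet structure


@dataclass
class TripletParse:
    """G-X-Y decomposition of a chain's collagenous span.

    ``triplets`` each start with Gly; ``interruptions`` are (chain 0-based
    position, length) stretches inside the span that do not fit the
    triplet frame.  Concatenating triplets and interruptions in positional
    order reconstructs the span exactly.
    """

    chain_id: str
    helix_start: int
    helix_end: int
    triplets: list[str]
    interruptions: list[tuple[int, int]]
    _segments: list[tuple[str, str]] = field(default_factory=list, repr=False)

    @property
    def helix_sequence(self) -> str:
        return "".join(seg for _, seg in self._segments)

    def reconstruct(self) -> str:
        return self.helix_sequence


def parse_collagenous_domain(
    chain: ProCollagenChain, domains: DomainMap | None = None
) -> TripletParse:
    """Parse the collagenous span of a chain into G-X-Y triplets.

    With a :class:`DomainMap`, the span is its annotated triple helix;
    otherwise it is the longest run of consecutive in-frame G-X-Y
    triplets.  Residues inside the span that break the triplet frame are
    recorded as interruptions.
    """
    s = chain.sequence
    n = len(s)
    if domains is not None:
        helix = domains.get(DomainName.triple_helix)
        start, end = helix.start, helix.end
    else:
        # longest run of consecutive triplets, each starting with G
        run = [0] * (n + 3)
        for i in range(n - 3, -1, -1):
            if s[i] == "G":
                run[i] = 1 + run[i + 3]
        best = max(range(n), key=lambda i: run[i], default=None)
        if best is None or run[best] == 0:
            raise ValueError(f"chain {chain.id!r}: no G-X-Y triplet found")
        # earliest start among maximal runs
        best_len = run[best]
        start = min(i for i in range(n) if run[i] == best_len)
        end = start + 3 * best_len

    triplets: list[str] = []
    interruptions: list[tuple[int, int]] = []
    segments: list[tuple[str, str]] = []
    i = start
    while i < end:
        if s[i] == "G" and i + 3 <= end:
            triplets.append(s[i : i + 3])
            segments.append(("T", s[i : i + 3]))
            i += 3
        else:
            j = i
            while j < end and not (s[j] == "G" and j + 3 <= end):
                j += 1
            interruptions.append((i, j - i))
            segments.append(("I", s[i:j]))
            i = j
    if not triplets:
        raise ValueError(f"chain {chain.id!r}: no G-X-Y triplet found in helix span")
    return TripletParse(
        chain_id=chain.id,
        helix_start=start,
        helix_end=end,
        triplets=triplets,
        interruptions=interruptions,
        _segments=segments,
    )


@dataclass
class MotifCounts:
    """Triple-helix stability motif counts.

    GPP triplets stabilize the helix; glycine runs (GG, GGG) destabilize
    it.  Runs of >= 4 glycines are decomposed greedily into GGG units plus
    a remainder (a remainder of 2 counts as one GG, a remainder of 1 is
    dropped) and flagged in ``long_runs`` since run handling is a
    convention, not a measurement.
    """

    chain_id: str
    gpp: int
    gg: int
    ggg: int
    n_triplets: int
    long_runs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def gg_plus_ggg(self) -> int:
        return self.gg + self.ggg


def count_stability_motifs(parse: TripletParse) -> MotifCounts:
    gpp = sum(1 for t in parse.triplets if t == "GPP")
    helix = parse.helix_sequence
    gg = ggg = 0
    long_runs: list[tuple[int, int]] = []
    for m in re.finditer(r"G+", helix):
        length = m.end() - m.start()
        if length == 2:
            gg += 1
        elif length == 3:
            ggg += 1
        elif length >= 4:
            ggg += length // 3
            if length % 3 == 2:
                gg += 1
            long_runs.append((parse.helix_start + m.start(), length))
    return MotifCounts(
        chain_id=parse.chain_id,
        gpp=gpp,
        gg=gg,
        ggg=ggg,
        n_triplets=len(parse.triplets),
        long_runs=long_runs,
    )


def xy_identity(
    parse_a: TripletParse,
    parse_b: TripletParse,
    params: AlignmentParams | None = None,
) -> float:
    """Percent identity between the concatenated X+Y residues of two chains.

    Strips every triplet to its second and third position (the
    non-glycine residues), globally aligns the two reduced strings, and
    returns percent identity.  Removing the invariant glycines avoids the
    identity inflation caused by the obligatory G every third residue.
    """
    xy_a = "".join(t[1:] for t in parse_a.triplets)
    xy_b = "".join(t[1:] for t in parse_b.triplets)
    if not xy_a or not xy_b:
        raise ValueError("empty X/Y string")
    a = ProCollagenChain(id=f"{parse_a.chain_id}|xy", sequence=xy_a)
    b = ProCollagenChain(id=f"{parse_b.chain_id}|xy", sequence=xy_b)
    return percent_identity(global_align(a, b, params=params))


# --------------------------------------------------------------------------
# Composition, mass, pI


@dataclass
class CompositionVector:
    """Residue counts for one region of one chain."""

    chain_id: str
    region: str
    counts: dict[str, int]

    @property
    def length(self) -> int:
        return sum(self.counts.values())

    def ratio(self, a: str, b: str) -> float:
        if self.counts.get(b, 0) == 0:
            raise ZeroDivisionError(f"no {b} residues in {self.chain_id}/{self.region}")
        return self.counts.get(a, 0) / self.counts[b]


def _resolve_region(
    chain: ProCollagenChain, region: str | DomainName, domains: DomainMap | None
) -> str:
    if region == "full":
        return chain.sequence
    if domains is None:
        raise ValueError(f"region {region!r} requested without a DomainMap")
    dom = domains.get(region)
    return chain.region(dom.start, dom.end)


def aa_composition(
    chain: ProCollagenChain,
    region: str | DomainName = "full",
    domains: DomainMap | None = None,
) -> CompositionVector:
    """Exact residue counts over the requested region (all 20 residues)."""
    seq = _resolve_region(chain, region, domains)
    if not seq:
        raise ValueError(f"empty region {region!r} on chain {chain.id!r}")
    counts = {aa: 0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
    for ch in seq:
        counts[ch] = counts.get(ch, 0) + 1
    region_name = region.value if isinstance(region, DomainName) else str(region)
    return CompositionVector(chain_id=chain.id, region=region_name, counts=counts)


def theoretical_mass(
    chain: ProCollagenChain,
    region: str | DomainName = "full",
    domains: DomainMap | None = None,
) -> float:
    """Average (not monoisotopic) molecular mass in Da of the unmodified region."""
    seq = _resolve_region(chain, region, domains)
    if not seq:
        raise ValueError(f"empty region {region!r} on chain {chain.id!r}")
    try:
        return float(molecular_weight(seq, seq_type="protein"))
    except ValueError as exc:
        raise ValueError(f"chain {chain.id!r}: {exc}") from exc


def mass_kda(mass_da: float, sig_figs: int = 3) -> float:
    """Mass in kDa rounded to ``sig_figs`` significant figures (137.2 kDa -> 137)."""
    from math import floor, log10

    kda = mass_da / 1000.0
    if kda == 0:
        return 0.0
    return round(kda, -int(floor(log10(abs(kda)))) + (sig_figs - 1))


def theoretical_pI(
    chain: ProCollagenChain,
    region: str | DomainName = "full",
    domains: DomainMap | None = None,
) -> float:
    """Isoelectric point by bisection of the Henderson-Hasselbalch net charge.

    Uses the Bjellqvist pKa set (terminal groups plus D, E, C, Y, H, K, R
    side chains) and bisects on pH in [0, 14]; the net charge is strictly
    decreasing in pH so the root is unique.  Report to one decimal.
    """
    seq = _resolve_region(chain, region, domains)
    if not seq:
        raise ValueError(f"empty region {region!r} on chain {chain.id!r}")
    return float(IsoelectricPoint(seq).pi(pH=7.0, min_=0.0, max_=14.0))


def net_charge(sequence: str, pH: float) -> float:
    """Net charge of a sequence at a given pH under the same pKa set as the pI."""
    return float(IsoelectricPoint(sequence).charge_at_pH(pH))


# --------------------------------------------------------------------------
# Conservation reports


@dataclass
class ConservationItem:
    site_label: str
    reference_residue: str
    target_residue: str  # one-letter code or "deleted"
    conserved: bool
    target_position: int | None = None  # 1-based, site's coordinate system
    note: str = ""
    compensating_offset: int | None = None


@dataclass
class ConservationReport:
    chain_id: str
    items: list[ConservationItem]

    def summary(self) -> dict[str, int]:
        return {
            "n_sites": len(self.items),
            "n_conserved": sum(i.conserved for i in self.items),
            "n_substituted": sum(
                (not i.conserved) and i.target_residue != "deleted" for i in self.items
            ),
            "n_deleted": sum(i.target_residue == "deleted" for i in self.items),
        }


def cysteine_conservation(
    target_c_propeptide: ProCollagenChain,
    reference_c_propeptide: ProCollagenChain,
    cysteines: Sequence[tuple[int, str]],
    params: AlignmentParams | None = None,
) -> ConservationReport:
    """Conservation of annotated C-propeptide cysteines on a target chain.

    ``cysteines`` lists (1-based C-propeptide-local position, role) pairs
    with role ``inter_chain`` or ``intra_chain``.  Disulfide-forming
    cysteines in the C-propeptide control trimer folding; a missing
    inter-chain cysteine changes which disulfide-linked trimers can form.
    """
    ref_seq = reference_c_propeptide.sequence
    for pos, role in cysteines:
        if not 1 <= pos <= len(ref_seq):
            raise IndexError(f"cysteine position {pos} outside the reference")
        if ref_seq[pos - 1] != "C":
            raise ValueError(
                f"annotation error: reference residue at {pos} is {ref_seq[pos - 1]!r}, not Cys"
            )
    aln = global_align(reference_c_propeptide, target_c_propeptide, params=params)
    items = []
    for pos, role in cysteines:
        sm = map_site(aln, pos, "chain")
        if sm.target_position == "deleted":
            items.append(
                ConservationItem(f"Cys{pos}[{role}]", "C", "deleted", False, None, "deleted in target")
            )
        else:
            res = sm.target_residue or ""
            conserved = res == "C"
            note = "" if conserved else f"substituted by {res}"
            items.append(
                ConservationItem(f"Cys{pos}[{role}]", "C", res, conserved, sm.target_position, note)
            )
    return ConservationReport(chain_id=target_c_propeptide.id, items=items)


@dataclass(frozen=True)
class CrosslinkSite:
    """One cross-link Lys/Hyl site in reference coordinates."""

    label: str
    coordinate_system: Literal["chain", "triple_helix", "n_telopeptide", "c_telopeptide"]
    position: int


def crosslink_site_report(
    target: ProCollagenChain,
    reference: ProCollagenChain,
    sites: Sequence[CrosslinkSite],
    ref_domains: DomainMap | None = None,
    target_domains: DomainMap | None = None,
    scan_window: int = 5,
    params: AlignmentParams | None = None,
    aln: PairwiseAlignment | None = None,
) -> ConservationReport:
    """Conservation of cross-link lysines, with a compensating-Lys scan.

    Lys counts as conserved (hydroxylysine is a modification of Lys and
    indistinguishable at the sequence level).  When the homologous target
    residue is not Lys, the surrounding ``+-scan_window`` residues are
    scanned for a Lys that could carry the cross-link instead, and the
    nearest one is reported by its offset; Arg/His substitutions are
    flagged as basic.  A precomputed reference-to-target alignment may be
    supplied via ``aln``.
    """
    if aln is None:
        aln = global_align(reference, target, params=params)
    items = []
    t_helix_start = None
    if target_domains is not None and DomainName.triple_helix in target_domains:
        t_helix_start = target_domains.get(DomainName.triple_helix).start
    for site in sites:
        sm = map_site(aln, site.position, site.coordinate_system, ref_domains=ref_domains)
        if sm.target_position == "deleted":
            items.append(
                ConservationItem(site.label, "K", "deleted", False, None, "deleted in target")
            )
            continue
        t_idx = sm.target_position - 1  # chain 0-based
        res = sm.target_residue or ""
        conserved = res == "K"
        report_pos = sm.target_position
        if site.coordinate_system == "triple_helix" and t_helix_start is not None:
            report_pos = t_idx - t_helix_start + 1
        note = ""
        comp_offset = None
        if not conserved:
            note = "basic substitution" if res in ("R", "H") else f"substituted by {res}"
            offsets = sorted(
                (
                    off
                    for off in range(-scan_window, scan_window + 1)
                    if off != 0
                    and 0 <= t_idx + off < len(target)
                    and target.sequence[t_idx + off] == "K"
                ),
                key=lambda o: (abs(o), o),
            )
            if offsets:
                comp_offset = offsets[0]
                note += f"; compensating Lys at offset {comp_offset:+d}"
        items.append(
            ConservationItem(
                site.label, "K", res, conserved, report_pos, note, comp_offset
            )
        )
    return ConservationReport(chain_id=target.id, items=items)


def recognition_region_diff(
    target: ProCollagenChain,
    reference: ProCollagenChain,
    window: tuple[int, int],
    params: AlignmentParams | None = None,
) -> tuple[int, str, str]:
    """Differences in the C-propeptide chain recognition region.

    ``window`` is the (1-based inclusive) span of the ~15-residue
    recognition region on the reference sequence.  Returns the number of
    non-identical alignment columns in the window (a gap counts as a
    difference) plus the aligned reference and target window strings.
    """
    start, end = window
    aln = global_align(reference, target, params=params)
    cols = aln.columns_of("a")
    if not 1 <= start <= end <= len(aln.seq_a):
        raise IndexError(f"window {window} outside the reference sequence")
    lo, hi = cols[start - 1], cols[end - 1] + 1
    win_a = aln.aligned_a[lo:hi]
    win_b = aln.aligned_b[lo:hi]
    if all(ch == "-" for ch in win_b):
        raise ValueError("recognition window is entirely deleted in the target")
    n_diff = sum(1 for ca, cb in zip(win_a, win_b) if ca != cb or ca == "-")
    return n_diff, win_a, win_b
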
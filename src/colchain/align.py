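"""Global pairwise alignment, identity and annotation transfer.

Chains are compared with Needleman-Wunsch global alignment (BLOSUM62,
gap open 10, gap extend 0.5, EMBOSS-style affine cost: a gap of length L
costs 10 + 0.5*(L-1)).  Domain boundaries and individual sites (cross-link
lysines, cysteines) are transferred between chains through the alignment
columns.

Coordinate conventions: 0-based half-open internally; 1-based inclusive in
reports and in :class:`SiteMapping`.  Triple-helix numbering starts at 1 on
the first Gly of the helical domain, the convention used for collagen
cross-link sites (87, 930, 933).
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Literal

from Bio import Align
from Bio.Align import substitution_matrices

from .core import Domain, DomainMap, DomainName, ProCollagenChain

GAP = "-"


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of two chains."""

    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    score: float
    params: AlignmentParams = field(default_factory=AlignmentParams)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == GAP and cb == GAP:
                raise ValueError("gap-in-both column")

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace(GAP, "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace(GAP, "")

    def columns_of(self, which: Literal["a", "b"]) -> list[int]:
        """Column index of each residue of sequence a (or b)."""
        aligned = self.aligned_a if which == "a" else self.aligned_b
        return [c for c, ch in enumerate(aligned) if ch != GAP]

    def position_at_column(self, which: Literal["a", "b"], col: int) -> int | None:
        """0-based residue index of a/b at an alignment column, or None on a gap."""
        aligned = self.aligned_a if which == "a" else self.aligned_b
        if aligned[col] == GAP:
            return None
        return sum(1 for ch in aligned[:col] if ch != GAP)

    def swapped(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            seq_a_id=self.seq_b_id,
            seq_b_id=self.seq_a_id,
            aligned_a=self.aligned_b,
            aligned_b=self.aligned_a,
            score=self.score,
            params=self.params,
        )


@dataclass(frozen=True)
class SiteMapping:
    """Homolog of one reference residue on a target chain.

    ``target_position`` is a 1-based chain coordinate, or the string
    ``"deleted"`` when the reference residue aligns to a gap.
    """

    ref_position: int
    coordinate_system: str
    target_position: int | Literal["deleted"]
    target_residue: str | None


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    a: ProCollagenChain,
    b: ProCollagenChain,
    params: AlignmentParams | None = None,
) -> PairwiseAlignment:
    """Optimal global alignment of two chains (first optimum is reported)."""
    if params is None:
        params = AlignmentParams()
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    aln = _aligner(params).align(a.sequence, b.sequence)[0]
    return PairwiseAlignment(
        seq_a_id=a.id,
        seq_b_id=b.id,
        aligned_a=aln[0],
        aligned_b=aln[1],
        score=float(aln.score),
        params=params,
    )


def _core_span(aln: PairwiseAlignment) -> tuple[int, int]:
    """Half-open column range excluding terminal gap overhangs."""
    cols_a = aln.columns_of("a")
    cols_b = aln.columns_of("b")
    lo = max(cols_a[0], cols_b[0])
    hi = min(cols_a[-1], cols_b[-1]) + 1
    return lo, hi


def percent_identity(
    aln: PairwiseAlignment,
    domains: DomainMap | None = None,
    domain: str | DomainName | None = None,
) -> float:
    """Percent identical columns over columns with at least one residue.

    Terminal gap overhangs are excluded from the denominator.  With a
    ``domains``/``domain`` restriction, only columns overlapping that
    region of the named chain are counted; the DomainMap must belong to
    one of the two aligned chains.
    """
    lo, hi = _core_span(aln)
    if domains is not None:
        if domain is None:
            raise ValueError("a domain name is required with a DomainMap restriction")
        if domains.chain_id == aln.seq_a_id:
            which: Literal["a", "b"] = "a"
        elif domains.chain_id == aln.seq_b_id:
            which = "b"
        else:
            raise ValueError(
                f"DomainMap chain {domains.chain_id!r} is not part of this alignment"
            )
        dom = domains.get(domain)
        cols = aln.columns_of(which)
        lo = max(lo, cols[dom.start])
        hi = min(hi, cols[dom.end - 1] + 1)
        if lo >= hi:
            raise ValueError(f"domain {dom.name.value!r} lies in a terminal overhang")
    n_cols = hi - lo
    if n_cols <= 0:
        raise ValueError("no alignable columns in the requested span")
    ident = sum(
        1
        for c in range(lo, hi)
        if aln.aligned_a[c] == aln.aligned_b[c] and aln.aligned_a[c] != GAP
    )
    return 100.0 * ident / n_cols


def transfer_annotation(
    reference: ProCollagenChain,
    ref_domains: DomainMap,
    target: ProCollagenChain,
    aln: PairwiseAlignment | None = None,
    params: AlignmentParams | None = None,
) -> DomainMap:
    """Project reference domain boundaries onto a target chain.

    Each boundary maps to the first target residue aligned at or after
    the reference boundary column, which keeps the transferred domains
    contiguous and non-overlapping by construction.  A domain whose image
    is empty (entirely deleted in the target) raises.
    """
    ref_domains.validate_against(reference)
    if aln is None:
        aln = global_align(reference, target, params=params)
    elif aln.seq_a != reference.sequence or aln.seq_b != target.sequence:
        raise ValueError("supplied alignment does not match reference/target sequences")

    cols_a = aln.columns_of("a")
    cols_b = aln.columns_of("b")
    n_target = len(target)

    def map_boundary(ref_idx: int) -> int:
        """First target residue index at or after the column of ref residue ref_idx."""
        if ref_idx >= len(reference):
            return n_target
        col = cols_a[ref_idx]
        return bisect.bisect_left(cols_b, col)

    mapped: list[Domain] = []
    boundaries = [(d.name, d.start, d.end) for d in ref_domains.domains]
    for name, start, end in boundaries:
        t_start = map_boundary(start)
        t_end = map_boundary(end)
        if t_start >= t_end:
            raise ValueError(
                f"domain {name.value!r} is entirely deleted in target {target.id!r}"
            )
        mapped.append(Domain(name, t_start, min(t_end, n_target)))

    out = DomainMap(chain_id=target.id, domains=mapped, chain_length=n_target)
    if DomainName.triple_helix in out:
        th = out.get(DomainName.triple_helix)
        if target.sequence[th.start] != "G":
            warnings.warn(
                f"transferred triple helix on {target.id!r} does not start with Gly",
                stacklevel=2,
            )
    return out


def map_site(
    aln: PairwiseAlignment,
    ref_position: int,
    coordinate_system: Literal[
        "chain", "triple_helix", "n_telopeptide", "c_telopeptide"
    ] = "chain",
    ref_domains: DomainMap | None = None,
) -> SiteMapping:
    """Map a 1-based reference site onto the aligned target chain.

    Domain-local coordinate systems (``triple_helix``, ``n_telopeptide``,
    ``c_telopeptide``) count from 1 at the first residue of that domain on
    the reference chain and require ``ref_domains``; cross-link sites are
    conventionally given this way (helix 87/930/933, telopeptide 9N/16C).
    """
    if coordinate_system != "chain":
        if ref_domains is None:
            raise ValueError(
                f"{coordinate_system} coordinates require the reference DomainMap"
            )
        dom = ref_domains.get(DomainName(coordinate_system))
        ref_idx = dom.start + ref_position - 1
        if not dom.start <= ref_idx < dom.end:
            raise IndexError(
                f"position {ref_position} outside the reference {coordinate_system}"
            )
    else:
        ref_idx = ref_position - 1
        if not 0 <= ref_idx < len(aln.seq_a):
            raise IndexError(f"position {ref_position} outside the reference chain")

    col = aln.columns_of("a")[ref_idx]
    t_idx = aln.position_at_column("b", col)
    if t_idx is None:
        return SiteMapping(ref_position, coordinate_system, "deleted", None)
    return SiteMapping(
        ref_position,
        coordinate_system,
        t_idx + 1,
        aln.seq_b[t_idx],
    )
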
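"""Published reference values and conventions for zebrafish type I collagen.

Zebrafish carries three type I collagen chains — alpha1(I) (col1a1a),
alpha3(I) (col1a1b) and alpha2(I) (col1a2) — versus two in tetrapods.
This module collects the published anchor values used across the
stoichiometry analysis (theoretical and experimental Ile/Leu ratios,
per-chain diagnostic ratios), the conventional cross-link site
coordinates, and a loader for user-supplied reference chain sequences.

Sequences themselves are not bundled: users fetch the zebrafish
col1a1a/col1a1b/col1a2 and human/mouse COL1A1/COL1A2 protein records from
Ensembl or UniProt and drop them under ``data/reference_chains/``; record
the accessions used alongside, since identities can shift ~1% between
isoforms.
"""

from __future__ import annotations

from pathlib import Path

from .core import ChainClass, ProCollagenChain, read_fasta
from .features import CompositionVector, CrosslinkSite
from .stoichiometry import TrimerComposition

#: Candidate stoichiometries with a single alpha2 chain per trimer
#: (in tetrapods a single alpha2 is generally present).
CANDIDATE_TRIMERS = [
    TrimerComposition(2, 1, 0),
    TrimerComposition(1, 1, 1),
    TrimerComposition(0, 1, 2),
]

#: Published theoretical Ile/Leu ratios of the candidate trimers.
ILE_LEU_THEORETIC = {
    TrimerComposition(2, 1, 0): 0.770,
    TrimerComposition(1, 1, 1): 0.584,
    TrimerComposition(0, 1, 2): 0.398,
}

#: Published experimental Ile/Leu ratios (mean +- sd of three analyses)
#: from bulk amino-acid hydrolysates of adult zebrafish tissues.
TISSUE_ILE_LEU = {
    "skin": (0.565, 0.050),
    "bone": (0.535, 0.065),
    "scales": (0.553, 0.097),
}

#: Published per-chain theoretical Ile/Leu ratios (alpha2's is not printed).
PER_CHAIN_ILE_LEU = {"alpha1": 0.92, "alpha3": 0.36}

#: Observed Tyr per trimer in hydrolysates; Tyr is theoretically absent
#: from both alpha1(I) and alpha3(I), so ~2 Tyr excludes their homotrimers.
OBSERVED_TYR_PER_TRIMER = (2.0, 0.3)

# Zebrafish-like helix Ile/Leu/Tyr counts per chain, solved from the
# published per-chain ratios (0.92, 0.36) jointly with the three candidate
# trimer ratios and rounded to integers at a realistic Leu abundance of 25
# per helix.  They reproduce the published trimer ratios within +-0.004:
# 2:1:0 -> 0.773, 1:1:1 -> 0.587, 0:1:2 -> 0.400.
_DIAGNOSTIC_COUNTS = {
    "alpha1": {"I": 23, "L": 25, "Y": 0},
    "alpha2": {"I": 12, "L": 25, "Y": 2},
    "alpha3": {"I": 9, "L": 25, "Y": 0},
}

# shared collagen-helix backbone for the non-diagnostic residues
# (~1014-residue helix: every third residue Gly, X/Y rich in Pro/Ala)
_BACKBONE = {
    "G": 338, "P": 232, "A": 110, "R": 50, "E": 70, "D": 45, "S": 40,
    "K": 36, "Q": 26, "T": 20, "N": 20, "V": 20, "F": 12, "M": 8,
    "H": 5, "C": 0, "W": 0,
}


def zebrafish_like_compositions() -> dict[str, CompositionVector]:
    """Triple-helix composition vectors emulating the three zebrafish chains.

    Diagnostic residues (Ile, Leu, Tyr) carry the published per-chain
    signal; the remaining residues share a common collagen-helix backbone.
    These are the default chain compositions for the hydrolysate
    simulator.
    """
    out = {}
    for chain, diag in _DIAGNOSTIC_COUNTS.items():
        counts = {aa: 0 for aa in "ACDEFGHIKLMNPQRSTVWY"}
        counts.update(_BACKBONE)
        counts.update(diag)
        out[chain] = CompositionVector(chain_id=chain, region="triple_helix", counts=counts)
    return out


#: Conventional cross-link Lys/Hyl sites, in the coordinates of the
#: human/mouse reference chains (helix numbering from the first helix Gly).
CROSSLINK_SITES_ALPHA1 = [
    CrosslinkSite("9N", "n_telopeptide", 9),
    CrosslinkSite("helix_87", "triple_helix", 87),
    CrosslinkSite("helix_930", "triple_helix", 930),
    CrosslinkSite("16C", "c_telopeptide", 16),
]
CROSSLINK_SITES_ALPHA2 = [
    CrosslinkSite("5N", "n_telopeptide", 5),
    CrosslinkSite("helix_87", "triple_helix", 87),
    CrosslinkSite("helix_933", "triple_helix", 933),
]

DEFAULT_REFERENCE_DIR = Path("data/reference_chains")


def load_reference_chains(
    directory: str | Path = DEFAULT_REFERENCE_DIR,
) -> dict[tuple[str, str], ProCollagenChain]:
    """Load user-supplied reference procollagen chains from a directory.

    Reads every ``*.fasta`` file and keys chains by (species, chain
    class) parsed from the ``species=`` and ``chain=`` header tokens,
    e.g. ``>col1a1a species=Danio_rerio chain=alpha1``.  Raises
    FileNotFoundError with instructions when the directory is absent.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.fasta")) if directory.is_dir() else []
    if not files:
        raise FileNotFoundError(
            f"no reference chain FASTA found under {directory}/ — fetch the "
            "zebrafish col1a1a/col1a1b/col1a2 and human/mouse COL1A1/COL1A2 "
            "protein sequences from Ensembl or UniProt, save them there with "
            "headers carrying species= and chain= tokens, and record the "
            "accessions used"
        )
    chains: dict[tuple[str, str], ProCollagenChain] = {}
    for f in files:
        for chain in read_fasta(f):
            if not chain.species or chain.chain_class is None:
                raise ValueError(
                    f"{f.name}: record {chain.id!r} lacks species=/chain= header tokens"
                )
            chains[(chain.species, chain.chain_class.value)] = chain
    return chains
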
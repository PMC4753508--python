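"""Core domain types for procollagen chain analysis.

A type I procollagen chain is the precursor of a mature collagen chain:
an N-propeptide (preceded by the signal peptide) and a C-propeptide flank
the Gly-X-Y triple-helical region via two short telopeptides.  The types
here carry one chain's sequence and the residue-level boundaries of those
five regions.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
#: 'X' is tolerated as an unknown-residue placeholder.
AA_ALPHABET_X = AA_ALPHABET | {"X"}


class ChainClass(str, enum.Enum):
    """Collagen type I alpha-chain class.

    Zebrafish carries three type I genes: col1a1a (alpha1), col1a1b
    (alpha3) and col1a2 (alpha2); tetrapods only alpha1 and alpha2.
    """

    alpha1 = "alpha1"
    alpha2 = "alpha2"
    alpha3 = "alpha3"


class DomainName(str, enum.Enum):
    """The five procollagen regions, N- to C-terminal."""

    signal_n_propeptide = "signal_n_propeptide"
    n_telopeptide = "n_telopeptide"
    triple_helix = "triple_helix"
    c_telopeptide = "c_telopeptide"
    c_propeptide = "c_propeptide"


DOMAIN_ORDER = [d.value for d in DomainName]


class FastaParseError(ValueError):
    """Raised when a FASTA record cannot be interpreted as a protein chain."""


@dataclass(frozen=True)
class ProCollagenChain:
    """One procollagen chain: identity metadata plus amino-acid sequence."""

    id: str
    sequence: str
    species: str = ""
    chain_class: ChainClass | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"chain {self.id!r}: empty sequence")
        bad = set(self.sequence) - AA_ALPHABET_X
        if bad:
            raise ValueError(
                f"chain {self.id!r}: non-amino-acid symbol(s) {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def region(self, start: int, end: int) -> str:
        """Subsequence on 0-based half-open coordinates."""
        return self.sequence[start:end]


@dataclass(frozen=True)
class Domain:
    """One annotated region, 0-based half-open internally."""

    name: DomainName
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"domain {self.name}: start {self.start} >= end {self.end}")


@dataclass
class DomainMap:
    """Ordered, non-overlapping domain boundaries on one chain.

    Internally 0-based half-open; the TSV interchange format is 1-based
    inclusive, matching how positions are reported in the collagen
    literature.
    """

    chain_id: str
    domains: list[Domain]
    chain_length: int | None = None

    def __post_init__(self) -> None:
        prev_end = None
        for d in self.domains:
            if d.start < 0:
                raise ValueError(f"domain {d.name}: negative start")
            if prev_end is not None and d.start < prev_end:
                raise ValueError(
                    f"domain {d.name}: overlaps or out of order (start {d.start} < previous end {prev_end})"
                )
            prev_end = d.end
        if self.chain_length is not None and self.domains and self.domains[-1].end > self.chain_length:
            raise ValueError("domains extend past the chain end")

    def __contains__(self, name: str | DomainName) -> bool:
        name = DomainName(name)
        return any(d.name == name for d in self.domains)

    def get(self, name: str | DomainName) -> Domain:
        name = DomainName(name)
        for d in self.domains:
            if d.name == name:
                return d
        raise KeyError(f"domain {name.value!r} not annotated on chain {self.chain_id!r}")

    def validate_against(self, chain: ProCollagenChain) -> None:
        """Check the map fits the chain; warn if the helix does not open on Gly."""
        if self.domains and self.domains[-1].end > len(chain):
            raise ValueError(
                f"domain map for {self.chain_id!r} extends past the chain end"
            )
        if DomainName.triple_helix in self:
            th = self.get(DomainName.triple_helix)
            if chain.sequence[th.start] != "G":
                warnings.warn(
                    f"chain {chain.id!r}: triple helix does not start with Gly",
                    stacklevel=2,
                )


def _parse_header(header: str) -> tuple[str, str, ChainClass | None]:
    """Split a FASTA header into id plus optional species=/chain= tokens."""
    tokens = header.split()
    rec_id = tokens[0]
    species = ""
    chain_class = None
    for tok in tokens[1:]:
        if tok.startswith("species="):
            species = tok.split("=", 1)[1].replace("_", " ")
        elif tok.startswith("chain="):
            try:
                chain_class = ChainClass(tok.split("=", 1)[1])
            except ValueError:
                pass
    return rec_id, species, chain_class


def read_fasta(path: str | Path) -> list[ProCollagenChain]:
    """Read procollagen chains from a FASTA file.

    Sequences are upper-cased; gaps and whitespace are stripped; a trailing
    ``*`` stop symbol is removed with a warning.  Any other non-amino-acid
    symbol raises :class:`FastaParseError` naming the record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    chains = []
    for rec in records:
        seq = str(rec.seq).upper().replace("-", "").replace(".", "")
        seq = "".join(seq.split())
        if seq.endswith("*"):
            warnings.warn(f"record {rec.id!r}: stripped trailing stop symbol '*'", stacklevel=2)
            seq = seq[:-1]
        if "*" in seq:
            raise FastaParseError(f"record {rec.id!r}: internal stop symbol '*'")
        bad = set(seq) - AA_ALPHABET_X
        if bad:
            raise FastaParseError(
                f"record {rec.id!r}: non-amino-acid symbol(s) {sorted(bad)!r}"
            )
        rec_id, species, chain_class = _parse_header(rec.description)
        chains.append(ProCollagenChain(id=rec_id, sequence=seq, species=species, chain_class=chain_class))
    return chains


def write_fasta(chains: Iterable[ProCollagenChain], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for c in chains:
            header = c.id
            if c.species:
                header += f" species={c.species.replace(' ', '_')}"
            if c.chain_class is not None:
                header += f" chain={c.chain_class.value}"
            fh.write(f">{header}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def read_domain_table(path: str | Path) -> dict[str, DomainMap]:
    """Read domain annotations from TSV (chain_id, domain, start_1based, end_1based_inclusive)."""
    df = pd.read_csv(path, sep="\t")
    required = {"chain_id", "domain", "start_1based", "end_1based_inclusive"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain table missing column(s): {sorted(missing)}")
    out: dict[str, DomainMap] = {}
    for chain_id, grp in df.groupby("chain_id", sort=False):
        domains = [
            Domain(DomainName(row.domain), int(row.start_1based) - 1, int(row.end_1based_inclusive))
            for row in grp.itertuples()
        ]
        domains.sort(key=lambda d: d.start)
        out[str(chain_id)] = DomainMap(chain_id=str(chain_id), domains=domains)
    return out


def write_domain_table(maps: Iterable[DomainMap], path: str | Path) -> None:
    rows = [
        {
            "chain_id": m.chain_id,
            "domain": d.name.value,
            "start_1based": d.start + 1,
            "end_1based_inclusive": d.end,
        }
        for m in maps
        for d in m.domains
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
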
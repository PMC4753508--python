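"""Characterize the simulated procollagen chains.

Reads the chains written by 01_simulate_inputs.py, parses their
collagenous domains, and tabulates the chain-level statistics the
pipeline computes on real sequences: triplet and stability-motif counts
(GPP stabilizes the helix, GG/GGG runs destabilize it), X/Y-position
identity between chains, full-chain identity, theoretical mass and pI.
Writes results/chain_features.tsv and results/chain_identity.tsv.
"""

from pathlib import Path

import pandas as pd

from colchain import (
    count_stability_motifs,
    global_align,
    mass_kda,
    parse_collagenous_domain,
    percent_identity,
    read_domain_table,
    read_fasta,
    theoretical_mass,
    theoretical_pI,
    xy_identity,
)

IN = Path("results/simulated")
OUT = Path("results")


def main() -> None:
    chains = read_fasta(IN / "chains.fasta")
    domain_maps = read_domain_table(IN / "domains.tsv")

    rows = []
    parses = {}
    for chain in chains:
        dm = domain_maps[chain.id]
        parse = parse_collagenous_domain(chain, dm)
        parses[chain.id] = parse
        motifs = count_stability_motifs(parse)
        rows.append(
            {
                "chain": chain.id,
                "length": len(chain),
                "n_triplets": motifs.n_triplets,
                "gpp": motifs.gpp,
                "gg": motifs.gg,
                "ggg": motifs.ggg,
                "gg_plus_ggg": motifs.gg_plus_ggg,
                "mass_kda": mass_kda(theoretical_mass(chain)),
                "pI": round(theoretical_pI(chain), 1),
            }
        )
    feat = pd.DataFrame(rows)
    feat.to_csv(OUT / "chain_features.tsv", sep="\t", index=False)
    print(feat.to_string(index=False))

    a1 = next(c for c in chains if "alpha1" in c.id)
    a3 = next(c for c in chains if "alpha3" in c.id)
    g13 = feat.set_index("chain")["gg_plus_ggg"]
    print(
        f"\nGG+GGG in {a3.id}: {g13[a3.id]} vs {a1.id}: {g13[a1.id]} "
        f"(ratio {g13[a3.id] / g13[a1.id]:.2f}; destabilizing runs are enriched "
        "in the alpha3-like chain by construction)"
    )

    id_rows = []
    for i, a in enumerate(chains):
        for b in chains[i + 1 :]:
            id_rows.append(
                {
                    "chain_a": a.id,
                    "chain_b": b.id,
                    "full_pct_identity": round(percent_identity(global_align(a, b)), 1),
                    "xy_pct_identity": round(xy_identity(parses[a.id], parses[b.id]), 1),
                }
            )
    ident = pd.DataFrame(id_rows)
    ident.to_csv(OUT / "chain_identity.tsv", sep="\t", index=False)
    print("\n" + ident.to_string(index=False))


if __name__ == "__main__":
    main()
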
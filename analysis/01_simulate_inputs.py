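"""Generate the synthetic study inputs used by the downstream analyses.

Writes, under results/simulated/: collagen-like procollagen chains with
their true domain maps (FASTA + TSV), a replicate hydrolysate ratio table
for a known 1:1:1 trimer truth, and a light/heavy SRM table for the
three-tissue design (bone 0.6, skin 1.0, scales 1.0; 3 biological x 2
technical replicates, 4 peptides per protein), each with a truth sidecar.
"""

import json
from pathlib import Path

import pandas as pd

from colchain import (
    TrimerComposition,
    aggregate_measurements,
    generate_chain,
    simulate_hydrolysate,
    simulate_srm,
    write_domain_table,
    write_fasta,
)
from colchain.reference import zebrafish_like_compositions

OUT = Path("results/simulated")
SEED = 20160215 % 2**31

# alpha3-like chains carry more glycines in X/Y (hence more GG/GGG runs)
# and slightly fewer GPP motifs than alpha1-like chains
CHAIN_PARAMS = {
    "alpha1_like": dict(motif_freqs=(0.12, 0.018, 0.018)),
    "alpha2_like": dict(motif_freqs=(0.11, 0.025, 0.025)),
    "alpha3_like": dict(motif_freqs=(0.10, 0.036, 0.036)),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    chains, maps = [], []
    for i, (name, params) in enumerate(CHAIN_PARAMS.items()):
        chain, dm = generate_chain(seed=SEED + i, chain_id=name, **params)
        chains.append(chain)
        maps.append(dm)
    write_fasta(chains, OUT / "chains.fasta")
    write_domain_table(maps, OUT / "domains.tsv")
    print(f"wrote {len(chains)} simulated procollagen chains "
          f"({len(chains[0])} residues each) and their true domain maps")

    comps = zebrafish_like_compositions()
    meas = simulate_hydrolysate(
        TrimerComposition(1, 1, 1), comps, noise_sd=0.05, n_measurements=3,
        tissue="synthetic_skin", seed=SEED,
    )
    agg = aggregate_measurements(meas)
    pd.DataFrame(
        [
            {
                "tissue": agg.tissue,
                "residue_A": "I",
                "residue_B": "L",
                "observed_ratio": agg.observed_ratio,
                "sd": agg.sd,
                "marker_observed": agg.marker_counts["Y"][0],
                "marker_sd": agg.marker_counts["Y"][1],
            }
        ]
    ).to_csv(OUT / "hydrolysate.tsv", sep="\t", index=False)
    print(f"wrote hydrolysate table: observed Ile/Leu {agg.observed_ratio:.3f} "
          f"+- {agg.sd:.3f} (truth 1:1:1)")

    table, truth = simulate_srm(seed=SEED)
    table.to_csv(OUT / "srm.tsv", sep="\t", index=False)
    (OUT / "truth.json").write_text(
        json.dumps(
            {
                "hydrolysate_true_composition": "1:1:1",
                "srm_tissue_ratios": truth.tissue_ratios,
                "srm_efficiencies": truth.efficiencies,
                "seed": SEED,
            },
            indent=2,
        )
    )
    print(f"wrote SRM table ({len(table)} rows) with true alpha3/alpha1 ratios "
          f"{truth.tissue_ratios}")


if __name__ == "__main__":
    main()
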
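# Reference procollagen chains (user-supplied)

Place here the protein sequences of the zebrafish and mammalian type I
procollagen chains, fetched from Ensembl or UniProt:

- zebrafish col1a1a (α1), col1a1b (α3), col1a2 (α2)
- human and/or mouse COL1A1 (α1), COL1A2 (α2)

as one or more `*.fasta` files whose headers carry `species=` and
`chain=` tokens, e.g.

    >col1a1a species=Danio_rerio chain=alpha1
    MDVKS...

Also required:

- `domains.tsv` — domain boundaries for the human/mouse chains
  (columns: `chain_id, domain, start_1based, end_1based_inclusive`;
  domains: `signal_n_propeptide, n_telopeptide, triple_helix,
  c_telopeptide, c_propeptide`). Zebrafish boundaries are inferred from
  these by alignment transfer.
- `annotations.json` — C-propeptide annotations of the human α1 chain:
  `recognition_window_cpro` (1-based inclusive span of the 15-residue
  chain recognition region, C-propeptide-local) and `cpro_cysteines`
  (list of `[position, role]` with role `inter_chain`/`intra_chain`,
  C-propeptide-local; Cys63 is the inter-chain cysteine of interest).

Record the accession and version of every sequence you place here
(isoform choice shifts identities by about one percentage point).
No sequences are bundled: none are printed in the source material and
redistribution terms vary by database.
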
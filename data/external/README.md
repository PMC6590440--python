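# External inputs (not distributed)

The package validates itself against published values when the original
inputs are placed here; nothing is downloaded automatically.

- `plastomes/` — GenBank flat files for the 14 lycophyte plastome
  records (any file names ending in `.gb`/`.gbk`; records are matched
  to species by their unique sequence length).
- `dataset_s1/` — the supplementary codon alignment matrices as
  `sc51.fasta`, `ndhB_psbM_rps7.fasta`, `rps4.fasta`, and the fixed
  topology as `topology.nwk`.
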
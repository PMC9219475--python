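# snpdiv

A population-diversity analysis toolkit for SNP-array genotype data:
quality-control filtering, per-population heterozygosity and F-statistics,
pairwise Weir–Cockerham Fst with Wright's gene-flow transform, allele-sharing
distances with neighbour-joining trees, and genotype PCA — plus a
Balding–Nichols simulator that generates multi-population datasets with
known truth so every stage is testable without external data.

## Library overview

| module | contents |
| --- | --- |
| `snpdiv.simdata` | `SimulationConfig`, `simulate_dataset` — Balding–Nichols multi-population genotype simulation with inbreeding and missingness |
| `snpdiv.genotype_io` | `GenotypeMatrix`, `read_ped_map` / `write_ped_map` — PLINK-style text PED/MAP; population labels live in the family-ID column |
| `snpdiv.qc` | `hwe_exact_test` (Levene conditional exact test), `apply_qc` — individual call rate → per-population SNP call rate → MAF → HWE cascade with an audit `QcReport` |
| `snpdiv.divstats` | `heterozygosity` (Ho, Nei unbiased He), `fis_within` and `pairwise_fst` (Weir–Cockerham variance components, ratio-of-sums over loci), `gene_flow_nm` (Nm = (1−Fst)/(4·Fst)) |
| `snpdiv.distance_nj` | `asd_matrix` (allele-sharing distance, pairwise-complete loci), `nj_tree` (Saitou–Nei with Studier–Keppler Q), `to_newick` |
| `snpdiv.pca` | `run_pca` — Patterson-normalized genotype PCA with percent-variance reporting |
| `snpdiv.pipeline` | `run_full_analysis` — simulate/load → QC → diversity → Fst/Nm → ASD → tree → PCA, with a JSON manifest; byte-identical outputs for a fixed seed |

## Command line

Each stage has a subcommand; `run-all` chains them:

```sh
# simulate a 4-population panel and analyse it end to end
snpdiv simulate --n-pops 4 --pop-sizes 11,12,12,12 --n-loci 2000 \
    --bn-f 0.15,0.05,0.04,0.06 --fis 0,0,0,0 --seed 1 --out-prefix data/sim

snpdiv run-all --ped data/sim.ped --map data/sim.map --out-dir results/run --seed 1

# or drive everything from a flat key=value config file
snpdiv run-all --config run.cfg
```

`run-all` writes `qc_report.tsv`, `diversity.tsv` (Breed/Nb/Ho/He/Fis),
`fst_nm_matrix.tsv` (Fst in the lower triangle, Nm above, mirroring the
usual mixed-triangle table layout), `asd_matrix.tsv`, `tree.nwk`,
`pca_coords.tsv`, `pca_eigen.tsv`, and `manifest.json`.

Individual stages: `snpdiv qc`, `snpdiv stats`, `snpdiv dist`, `snpdiv tree`,
`snpdiv pca` — see `snpdiv <cmd> --help` for flags (QC thresholds, HWE scope,
minimum pair overlap for ASD, number of components, …).

## Notes

- The gene-flow formula is implemented as Nm = (1 − Fst) / (4 · Fst); this
  parenthesization is the one consistent with the published worked values.
- Negative Fst estimates (sampling noise of the unbiased estimator) are
  reported as-is; Nm is reported only for Fst > 0.
- PED text cannot record the orientation of a marker observed with a single
  allele, so a write→read round trip canonicalizes such markers; all
  statistics are invariant under that relabeling.
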
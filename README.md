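# wolkdr

Analysis toolkit for *Wolbachia* release programs in pyrethroid-resistant
*Aedes aegypti* populations. It bundles four estimation stages plus a
synthetic-data generator so the whole pipeline runs without external data:

- **kdr genotypes** (`wolkdr.kdr`) — deterministic resolution of two-locus
  NaV genotypes (sites 1016 and 1534) into the three permitted haplotypes
  (S, R1, R2), with allelic/genotypic frequency estimation and Wilson
  confidence intervals.
- **Wolbachia monitoring** (`wolkdr.monitoring`) — weekly infection-frequency
  series from trap counts, mtDNA-marker maternal-transmission leakage,
  per-dam larval transmission fidelity, and the colony release-QA threshold.
- **Fitness-cost inference** (`wolkdr.fitness_cost`) — a two-allele
  viability-selection model of a laboratory colony with scheduled
  resistant-male introgression, and rejection sampling of the homozygous
  fitness cost against an observed terminal allele frequency.
- **Bioassays** (`wolkdr.bioassay`) — maximum-likelihood probit dose–response
  fits (log10 dose scale, optional Abbott control-mortality correction),
  lethal concentrations, and resistance ratios against a susceptible
  reference strain.
- **Synthetic data** (`wolkdr.simulate`) — seeded generators for every input
  format the stages consume, drawn from the statistical models the
  estimators assume.

## CLI

All stages are exposed under one entry point:

```bash
wolkdr --seed 1 simulate --outdir inputs/            # write synthetic CSV inputs
wolkdr kdr-freq --input inputs/genotypes.csv --output kdr.json
wolkdr monitor --input inputs/traps.csv --output freq.csv
wolkdr transmission --input inputs/transmission.csv \
       --exclude-uninfected-dams --output transmission.json
wolkdr bioassay --input inputs/bioassay.csv --reference reference --output bio.json
wolkdr fitness-cost --out posterior.json --draws-csv draws.csv --trajectories 5
wolkdr validate inputs/*.csv                          # schema / row diagnostics
wolkdr --seed 1 run-all --outdir run/                 # end-to-end with manifest
```

`run-all` derives one seed per stage from the global seed (SHA-256 of
`"<seed>:<stage>"`), writes all reports plus a manifest with input digests,
and is bit-reproducible for a fixed (scenario, seed, version).

### Fitness-cost configuration

`wolkdr fitness-cost --config mc.json` accepts a JSON mirror of
`MonteCarloConfig`; defaults are 100,000 draws, cost ~ U(0, 1),
initial RR frequency ~ U(0.50, 0.60) with overall allele frequency 0.60,
heterozygote cost multiplier 0.9, homozygous-resistant male introgression at
1 male : 10 females at generations 10 and 15, and an inclusive acceptance
window of 0.03 ± 0.01 on the generation-18 allele frequency.

Two introgression semantics are available via `migrants_selected`:
added males either pay the same genotype fitness weighting as colony males
(default — the cost includes adult components such as mating competitiveness)
or enter the post-selection male gamete pool unweighted. The default
reproduces the published posterior regime (mean cost ≈ 33–34%, 95% CI
≈ [30%, 37%], ≈ 6.5k of 1e5 draws accepted).

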
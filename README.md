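# commphylo

Community phylogenetics for presence/absence surveys on a reference
phylogeny:

- **Tree handling** — strict Newick parsing/writing, pruning with distance
  preservation, patristic (cophenetic) distance matrices. Polytomies and
  zero-length branches are supported; trees are never assumed ultrametric.
- **Diversity metrics** — Faith's PD (with or without the root path), MPD
  and MNTD within an assemblage, and between-assemblage MPD/MNTD
  (phylogenetic beta diversity).
- **Null models** — richness-preserving randomisation from the pooled
  species list (999 replicates by default) with standardised effect sizes:
  PDI = (PD_obs − mean_null) / sd_null and NTI = −SES(MNTD). Positive NTI
  means phylogenetic clustering. Fully seeded; per-site substreams make
  results independent of which other sites are present.
- **Ordination** — classical PCoA (Gower double-centering) of between-site
  distance matrices, with Lingoes/Cailliez corrections, negative-eigenvalue
  reporting and per-axis variance explained.
- **Groups & life forms** — life-form proportion tables per site and per
  wetland type; NTI of a flagged species group (dominant / invasive)
  against the pool; nearest-taxon separation between a group and its
  complement with a seeded label-permutation reference.
- **Synthetic data** — seeded Yule trees and incidence tables with
  controllable assembly structure (neutral / clustered / overdispersed),
  life-form mixes and flag placement, so every stage has ground truth.

## CLI

Generate a synthetic fixture and run the full analysis:

```sh
commphylo synth --tips 200 --sites 28 --richness 10 40 --seed 1 --out fixture/
printf 'replicates = 999\nseed = 1\nout = results\n' > fixture/study.cfg
commphylo run fixture/study.cfg
```

The config file is flat `key = value` text; every key has a default
(`tree`, `community`, `attributes`, `metadata`, `out`, `replicates`,
`seed`, `include_root`, `pool`, `align_policy`, `pcoa_metric`,
`pcoa_correction`, `rank_stat`, `plot`). Paths are resolved relative to
the config file. Outputs are CSVs (per-site diversity, wetland-type
summary with ranks, correlations, PCoA coordinates/eigenvalues, group
statistics, life-form tables, NTI sign tally) plus `run_metadata.json`
recording the seed, replicate count and every setting in effect. Two runs
with the same config are byte-identical.

Individual stages are also exposed: `commphylo pdi-nti`, `commphylo pcoa`,
`commphylo groups` (see `--help` for flags, including
`--include-root/--no-include-root` and `--pool {union,weighted}`).

## Input formats

All tables are UTF-8 CSV/TSV (delimiter auto-detected):

- **community**: rows = sites, header = species, cells 0/1;
- **attributes**: `species,life_form,dominant,invasive` with life form in
  {annual, perennial, woody, other} (biennials are recorded as perennials
  on ingest);
- **metadata**: `site,wetland_type` with type in
  {lake, marsh, coastal, river, human-made};
- **tree**: one rooted Newick tree with branch lengths, trailing `;`.

Species labels are whitespace-trimmed and spaces map to underscores to
match Newick conventions. By default every table species must be a tree
tip (`align_policy = strict`); `drop` removes and logs the mismatches.

## Notes on conventions

- `faith_pd` includes the root path by default, so monotypic assemblages
  have nonzero PD; switch with `include_root=False`.
- Between-group MNTD averages the per-taxon nearest distances of *both*
  groups with equal taxon weight; shared species contribute zeros.
- Null standard deviations use the n−1 denominator; an (effectively) zero
  null sd yields a missing PDI/NTI with an explanatory note, as does
  richness < 2 for NTI.
- Pearson p-values use the standard two-tailed t-transform with n−2
  degrees of freedom.
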
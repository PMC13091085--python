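# Methods

## The quantification model

`spikequant` converts compositional 16S amplicon data to absolute cell
counts using foreign spike-in bacteria added at a known dose before DNA
extraction. The estimator rests on three assumptions:

1. **Proportional observation.** A taxon's share of classified reads
   equals its share of 16S gene copies in the extract. Extraction,
   amplification and classification treat spike and native DNA alike, so
   any systematic loss cancels between numerator and denominator.
2. **Known spike dose.** The number of spike 16S copies delivered per
   sample is known, either directly (cells added × copies per genome) or
   via the dilution arithmetic: `volume added ÷ dilution factor ÷
   reference volume × stock copies per reference volume`. With the
   shipped preset (10 µL of a 100-fold dilution against a 20 µL
   reference aliquot; 100,000 cells of each species; 3 and 7 copies per
   genome) the doses are 300,000 and 700,000 copies.
3. **A community copy number.** Converting copy totals to cell totals
   requires the average number of 16S operons per genome in the unknown
   community; 5 is the accepted default for mixed bacterial populations.
   When a per-taxon copy-number table is available it is used instead,
   taxon by taxon.

Each spike species yields an independent estimate of the sample's total
16S copies (`dose ÷ observed fraction`) and hence of total cells. The two
estimates are combined by an arithmetic mean; their max/min ratio is kept
as a QC metric because a ratio far from 1 indicates unequal recovery or a
copy-number error for one spike. Spike cells are then subtracted, spike
rows removed, the remaining percentages rescaled by `100/(100−s)`, and
per-taxon cell counts obtained as adjusted-percent × adjusted total.

At the phylum rank the spikes are not separate rows — Imtechella sits in
Bacteroidota, Allobacillus in Bacillota — so each spike's species-level
percentage is subtracted from its host phylum before rescaling. This uses
the identity that a taxon's relative abundance is the same at every rank
that resolves it. When no species-rank profile is available the deepest
rank resolving the spike is used instead.

## Parameters and defaults

| parameter | default | units | why |
|---|---|---|---|
| `volume_added` | 10 | µL | shipped preset's dosing protocol |
| `dilution_factor` | 100 | fold | same |
| `reference_volume` | 20 | µL | aliquot size the stock copy counts refer to |
| `mean_copies_per_genome_community` | 5 | copies/genome | accepted average for mixed bacterial communities |
| sample mass | 100 | mg | metadata only; a per-gram conversion helper is provided |
| profile sum tolerance | ±0.5 | % absolute | accommodates upstream rounding of percent tables |
| QC detection floor | 0.1 | % per spike | below this a spike is treated as undetected (inclusive bound) |
| QC soft working range | 0.5–20 | % summed spikes | brackets the ~4% spike fraction of a well-dosed low-biomass sample |
| QC hard ceiling | 50 | % | a spike-dominated sample carries little native signal |
| QC concordance ratio | 2.0 | — | max/min of the two cell estimates before warning |

The working-range thresholds are deliberate package choices, not measured
constants: no published working range exists for mucosal samples, so the
soft range is centred comfortably around the few-percent spike fractions
the protocol targets. All are configurable.

## Rounding policy

All arithmetic is carried at full floating precision; rounding is applied
only when rendering. Published worked examples of this protocol mix two
conventions — rescaling 45% by the exact factor 100/96 (46.875% → shown
as 46.88%) but rescaling 49% by the factor pre-rounded to 1.042 (51.058 →
shown as 51.06%, where exact arithmetic gives 51.0417%). Full precision
is the only self-consistent choice, so it is the default everywhere;
`paper_rounded_rescale` and the `--paper-rounding` flag reproduce the
rounded-factor display when needed for comparison against printed tables.

## The synthetic-community simulator

`simulate` generates ground-truth communities for end-to-end validation:

* **Composition.** Native cell counts are a symmetric Dirichlet draw
  scaled to the total; concentration 0.3 by default, producing the
  skewed, few-dominant-taxa profiles typical of mucosal communities.
  Lineages nest deterministically (fan-out 3 per rank) so rank
  aggregation is exact by construction.
* **Scale.** Default totals of ~5×10⁶ cells per 100 mg sample match the
  order of magnitude of jejunal mucosa; spikes are added at 100,000 cells
  each, putting the summed spike fraction in the few-percent range.
* **Observation.** Read probability ∝ cells × 16S copies per genome;
  either exact (infinite depth) or multinomial at a finite depth (50,000
  reads by default, the per-sample depth typical of the target
  application). All randomness flows from explicit integer seeds.
* **Noise knobs.** Per-spike recovery multipliers (1.0 = perfect; 0
  simulates a lost spike, which must fail QC) and finite-depth sampling.

What the simulator deliberately omits: PCR amplification bias, chimeras,
taxonomic misclassification, reagent contamination, host-DNA load and
index hopping. Passing recovery tests therefore demonstrates the
*arithmetic* of the chain — not robustness to those wet-lab artefacts,
which must be controlled upstream.

Useful closed forms on exact-mode synthetic data, used as test oracles:

* flat copy number matching the assumed mean and perfect recovery → the
  pipeline is the identity on absolute abundances;
* both spikes recovered at fraction r → estimated totals are exactly
  1/r × truth (r = 0.5 doubles them);
* true copy number c for a taxon under the flat-5 assumption → that
  taxon's estimate is inflated by exactly c/5;
* supplying the true per-taxon copy table removes that bias exactly.

## Numerical choices and degenerate inputs

* Taxon identity at any rank is the full lineage truncated to that rank,
  never the bare name, so same-named genera in different families cannot
  collide during aggregation. Aggregate labels without a lineage
  (`Others`) are carried as opaque taxa outside all lineage logic.
* Zero-abundance native taxa are kept in outputs with 0 cells to keep
  sample joins rectangular.
* A spike observed at 0% raises a spike-not-detected error (QC flags it
  first); spikes summing to ≥100% are an error unless every native taxon
  is at 0, the pure-spike boundary, where the adjusted total is 0.
* At the phylum rank a spike percent exceeding its host phylum's percent
  is an error beyond 1e-9 tolerance and a clamp-to-zero within it.
* Writers sort taxa by canonical lineage and serialise at full precision,
  so reruns are byte-identical.

## Problem sizes used in the validation suite

The packaged validation runs use communities of 5–40 taxa, totals of
5×10⁵–2×10⁷ cells, 50,000-read observation, 1,000 random samples for the
conservation checks and 100 seeds for the exact-recovery check — sizes at
which every structural property (conservation to 1e-9 relative,
recovery to 1e-6 relative in the noiseless limit) is already fully
exercised.

## Known limitations

* The estimator is only as good as the spike dose and recovery; unequal
  recovery between the two spike species biases the mean estimate and is
  surfaced (not corrected) via the concordance ratio.
* The flat copies-per-genome assumption biases individual taxa by their
  true copy number relative to the assumed mean; supply a per-taxon copy
  table when genomes are known.
* Quantification starts at the relative-abundance table: OTU/ASV calling,
  taxonomy assignment and read QC are upstream concerns.
* Group-comparison statistics on the resulting absolute abundances are
  out of scope; export the tables to your statistics environment.
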
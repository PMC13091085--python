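"""The spike-in quantification chain.

Given a sample's relative-abundance profile containing the spike-in taxa,
the chain runs:

1. copies added per spike species (dose arithmetic),
2. total 16S copies in the sample from each spike's observed percent,
3. copies → cells via the assumed community mean copy number,
4. average of the per-spike cell estimates,
5. spike-in cell counts in the sample, subtracted to give the adjusted
   (native-only) total,
6. spike removal and rescaling of the profile to 100%,
7. per-taxon absolute abundance = adjusted percent × adjusted total.

At the phylum rank the spikes are not distinct rows, so their
species-level percentages (relative abundance is invariant across ranks)
are subtracted from their host phyla before rescaling.

All arithmetic is carried at full floating precision; any rounding
(2 decimals for percent, 3 for the rescaling factor) is a display
concern handled by the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import replace
from typing import Mapping, Optional, Sequence

from .errors import (
    ConfigurationError,
    ProfileError,
    SpikeDominatesSampleError,
    SpikeNotDetectedError,
)
from .lineage import RANKS, Rank, Taxon, TaxonLineage
from .model import (
    AbsoluteAbundanceTable,
    RelativeAbundanceProfile,
    SampleQuantification,
    SpikeEstimate,
    SpikeInProtocol,
    SpikeInSpeciesSpec,
)

__all__ = [
    "copies_added_per_species",
    "total_copies_from_spike",
    "copies_to_cells",
    "average_cell_estimates",
    "spikein_cells_in_sample",
    "adjusted_total_cells",
    "remove_and_rescale",
    "absolute_abundance",
    "phylum_adjust",
    "quantify_sample",
    "rescale_factor",
    "paper_rounded_rescale",
]

#: relative tolerance for the cells-vs-stock dose consistency check
_DOSE_RTOL = 1e-6


def copies_added_per_species(
    protocol: SpikeInProtocol, species: SpikeInSpeciesSpec
) -> float:
    """16S copies of one spike species delivered into each sample.

    Stock route: (volume added ÷ dilution factor ÷ reference volume) ×
    stock copies per reference volume — i.e. the fraction of a standard
    undiluted aliquot actually delivered, times that aliquot's copy count.
    Cells route: cells added × the species' own 16S copies per genome.
    If both are configured they must agree to within 1e-6 relative.
    """
    stock = None
    if species.stock_copies_per_reference_volume is not None:
        delivered_ul = protocol.volume_added / protocol.dilution_factor
        stock = (delivered_ul / protocol.reference_volume) * \
            species.stock_copies_per_reference_volume
    cells = None
    if species.cells_added is not None:
        cells = species.cells_added * species.copies_per_genome
    if stock is not None and cells is not None:
        if abs(stock - cells) > _DOSE_RTOL * max(abs(stock), abs(cells)):
            raise ConfigurationError(
                f"{species.name}: stock route gives {stock:.6g} copies but "
                f"cells route gives {cells:.6g}; the two dose fields disagree"
            )
        return cells
    if cells is not None:
        return cells
    if stock is not None:
        return stock
    raise ConfigurationError(
        f"{species.name}: no dose information configured"
    )


def total_copies_from_spike(
    observed_rel_abund: float, copies_added: float
) -> float:
    """Total 16S copies in the sample from one spike's observed percent.

    The spike's known copy dose constitutes ``observed_rel_abund`` percent
    of all copies, so the total is ``copies_added / (percent/100)``.
    """
    if observed_rel_abund <= 0:
        raise SpikeNotDetectedError(
            "spike-in relative abundance is zero; total copies undefined"
        )
    if observed_rel_abund > 100:
        raise ProfileError(
            f"relative abundance {observed_rel_abund} exceeds 100%"
        )
    return copies_added / (observed_rel_abund / 100.0)


def copies_to_cells(total_copies: float, mean_copies_per_genome: float) -> float:
    """Convert a 16S copy total to a cell count via the mean copy number."""
    if mean_copies_per_genome <= 0:
        raise ConfigurationError("mean_copies_per_genome must be > 0")
    return total_copies / mean_copies_per_genome


def average_cell_estimates(estimates: Sequence[float]) -> float:
    """Combine per-spike total-cell estimates (arithmetic mean)."""
    if not estimates:
        raise ValueError("no cell estimates to average")
    if any(e <= 0 for e in estimates):
        raise ValueError("cell estimates must be positive")
    return float(sum(estimates)) / len(estimates)


def spikein_cells_in_sample(
    observed_rel_abund: float, average_cells: float
) -> float:
    """Cells of one spike species present in the sample.

    Its observed percent applied to the averaged total-cell estimate.
    """
    if average_cells <= 0:
        raise ValueError("average_cells must be > 0")
    return (observed_rel_abund / 100.0) * average_cells


def adjusted_total_cells(
    average_cells: float, spike_cells: Sequence[float]
) -> float:
    """Native-community cell total: average estimate minus spike cells."""
    total_spike = float(sum(spike_cells))
    adjusted = average_cells - total_spike
    if adjusted < 0:
        raise SpikeDominatesSampleError(
            f"spike-in cells ({total_spike:.6g}) exceed the estimated "
            f"total ({average_cells:.6g}); spike fraction "
            f"{100 * total_spike / average_cells:.2f}% dominates the sample"
        )
    return adjusted


def remove_and_rescale(
    profile: RelativeAbundanceProfile,
    spike_taxa: Sequence[Taxon],
) -> RelativeAbundanceProfile:
    """Drop the spike taxa and rescale the remainder to sum to 100%.

    Every remaining percent is multiplied by 100/(100−s) at full
    precision, where s is the summed spike percent.
    """
    spike_taxa = list(spike_taxa)
    if not spike_taxa:
        return profile
    missing = [t for t in spike_taxa if t not in profile.abundances]
    if missing:
        raise SpikeNotDetectedError(
            f"sample {profile.sample_id}: spike taxa absent from "
            f"{profile.rank.value} profile: "
            + ", ".join(t.key for t in missing)
        )
    s = sum(profile.abundances[t] for t in spike_taxa)
    remaining = profile.without(spike_taxa)
    if s >= 100:
        # pure-spike boundary: legal only when nothing native was observed
        if any(v > 0 for v in remaining.abundances.values()):
            raise SpikeDominatesSampleError(
                f"sample {profile.sample_id}: spike taxa sum to {s:.6g}%"
            )
        return remaining
    factor = 100.0 / (100.0 - s)
    return replace(
        remaining,
        abundances={t: v * factor for t, v in remaining.abundances.items()},
    )


def phylum_adjust(
    phylum_profile: RelativeAbundanceProfile,
    spike_species_abundances: Mapping[str, float],
    spike_lineages: Mapping[str, TaxonLineage],
    tolerance: float = 1e-9,
) -> RelativeAbundanceProfile:
    """Remove spike contributions from a phylum-rank profile.

    The spikes share phyla with native taxa, so each spike's own
    (species-level) percent — identical at every rank — is subtracted
    from its host phylum; all phyla are then rescaled by 100/(100−s).
    A spike percent exceeding its phylum's percent by more than
    ``tolerance`` is an error; within tolerance the phylum clamps to 0.
    """
    if not spike_species_abundances:
        return phylum_profile
    abundances = dict(phylum_profile.abundances)
    s = 0.0
    for name, percent in spike_species_abundances.items():
        lineage = spike_lineages[name]
        phylum_taxon = Taxon(
            label=lineage.phylum, lineage=lineage.truncate(Rank.PHYLUM)
        )
        if phylum_taxon not in abundances:
            raise SpikeNotDetectedError(
                f"sample {phylum_profile.sample_id}: phylum "
                f"{lineage.phylum!r} of spike {name!r} absent from profile"
            )
        current = abundances[phylum_taxon]
        if percent > current + tolerance:
            raise ProfileError(
                f"sample {phylum_profile.sample_id}: spike {name!r} at "
                f"{percent:.6g}% exceeds its phylum {lineage.phylum!r} "
                f"at {current:.6g}%"
            )
        abundances[phylum_taxon] = max(current - percent, 0.0)
        s += percent
    if s >= 100:
        raise SpikeDominatesSampleError(
            f"sample {phylum_profile.sample_id}: spike taxa sum to {s:.6g}%"
        )
    factor = 100.0 / (100.0 - s)
    return replace(
        phylum_profile,
        abundances={t: v * factor for t, v in abundances.items()},
    )


def rescale_factor(summed_spike_percent: float) -> float:
    """The 100/(100−s) multiplier restoring a spike-free profile to 100%."""
    if summed_spike_percent >= 100:
        raise SpikeDominatesSampleError(
            f"spike taxa sum to {summed_spike_percent:.6g}%"
        )
    return 100.0 / (100.0 - summed_spike_percent)


def paper_rounded_rescale(
    raw_percent: float,
    summed_spike_percent: float,
    factor_decimals: int = 3,
    display_decimals: int = 2,
) -> float:
    """Display-convention rescaling with a pre-rounded factor.

    Published worked examples sometimes quote the rescaling factor rounded
    (1.042 for s = 4%) and multiply with the rounded value; this helper
    reproduces that display arithmetic. Machine outputs always use
    :func:`rescale_factor` at full precision.
    """
    factor = round(rescale_factor(summed_spike_percent), factor_decimals)
    return round(raw_percent * factor, display_decimals)


def absolute_abundance(
    adjusted_profile: RelativeAbundanceProfile,
    adjusted_total: float,
) -> AbsoluteAbundanceTable:
    """Per-taxon cells: adjusted percent of the adjusted total."""
    cells = {
        taxon: (percent / 100.0) * adjusted_total
        for taxon, percent in adjusted_profile.abundances.items()
    }
    return AbsoluteAbundanceTable(
        sample_id=adjusted_profile.sample_id,
        rank=adjusted_profile.rank,
        cells=cells,
        adjusted_percent=dict(adjusted_profile.abundances),
        mass_mg=adjusted_profile.mass_mg,
    )


def observed_spike_percent(
    profiles_by_rank: Mapping[Rank, RelativeAbundanceProfile],
    species: SpikeInSpeciesSpec,
    rank: Rank,
) -> float:
    """Observed percent of one spike species for quantification at ``rank``.

    For species/genus/family the spike is its own row in that rank's
    profile. For phylum the spike is folded into a native phylum, so the
    percent is read from the deepest available profile where the spike
    taxon is resolved (species preferred), relying on rank-invariance of
    relative abundance.
    """
    if rank is not Rank.PHYLUM:
        profile = profiles_by_rank[rank]
        value = profile.get(species.taxon.at_rank(rank))
        if value is None:
            raise SpikeNotDetectedError(
                f"sample {profile.sample_id}: spike {species.name!r} absent "
                f"from {rank.value} profile"
            )
        return value
    for deep_rank in reversed(RANKS):
        if deep_rank is Rank.PHYLUM or deep_rank not in profiles_by_rank:
            continue
        value = profiles_by_rank[deep_rank].get(species.taxon.at_rank(deep_rank))
        if value is not None:
            return value
    raise SpikeNotDetectedError(
        f"spike {species.name!r}: no sub-phylum profile resolves its "
        "abundance (needed for phylum-level adjustment)"
    )


def quantify_sample(
    profiles_by_rank: Mapping[Rank, RelativeAbundanceProfile],
    protocol: SpikeInProtocol,
    rank: Rank,
    per_taxon_copies: Optional[Mapping[Taxon, float]] = None,
) -> tuple[SampleQuantification, AbsoluteAbundanceTable]:
    """Run the full chain for one sample at one rank.

    ``profiles_by_rank`` must contain the target rank's profile; for
    phylum-rank quantification a deeper profile (species preferred) must
    also be present to read the spike abundances. If
    ``per_taxon_copies`` maps taxa to known 16S copies per genome, those
    taxa get species-specific copy correction instead of the flat
    community mean.
    """
    profile = profiles_by_rank[rank]
    mean_copies = protocol.mean_copies_per_genome_community

    estimates: list[SpikeEstimate] = []
    cell_estimates: list[float] = []
    for species in protocol.species:
        observed = observed_spike_percent(profiles_by_rank, species, rank)
        if observed <= 0:
            raise SpikeNotDetectedError(
                f"sample {profile.sample_id}: spike {species.name!r} "
                "observed at 0%"
            )
        copies_added = copies_added_per_species(protocol, species)
        total_copies = total_copies_from_spike(observed, copies_added)
        cells = copies_to_cells(total_copies, mean_copies)
        cell_estimates.append(cells)
        estimates.append(
            SpikeEstimate(
                species=species.name,
                observed_percent=observed,
                copies_added=copies_added,
                total_copies_estimate=total_copies,
                cells_estimate=cells,
                spikein_cells_in_sample=math.nan,  # filled below
            )
        )

    average_cells = average_cell_estimates(cell_estimates)
    spike_cells = [
        spikein_cells_in_sample(e.observed_percent, average_cells)
        for e in estimates
    ]
    estimates = [
        replace(e, spikein_cells_in_sample=sc)
        for e, sc in zip(estimates, spike_cells)
    ]
    adjusted_total = adjusted_total_cells(average_cells, spike_cells)

    if rank is Rank.PHYLUM:
        adjusted_profile = phylum_adjust(
            profile,
            {e.species: e.observed_percent for e in estimates},
            {s.name: s.lineage for s in protocol.species},
        )
    else:
        adjusted_profile = remove_and_rescale(
            profile, list(protocol.spike_taxa(rank))
        )

    if per_taxon_copies:
        table = _absolute_abundance_per_taxon_copies(
            adjusted_profile, estimates, mean_copies, per_taxon_copies
        )
    else:
        table = absolute_abundance(adjusted_profile, adjusted_total)

    quant = SampleQuantification(
        sample_id=profile.sample_id,
        rank=rank,
        spike_estimates=tuple(estimates),
        average_cells_estimate=average_cells,
        adjusted_total_cells=adjusted_total,
        mass_mg=profile.mass_mg,
    )
    return quant, table


def _absolute_abundance_per_taxon_copies(
    adjusted_profile: RelativeAbundanceProfile,
    estimates: Sequence[SpikeEstimate],
    mean_copies: float,
    per_taxon_copies: Mapping[Taxon, float],
) -> AbsoluteAbundanceTable:
    """Species-specific copy-number correction.

    Copy-share arithmetic per taxon: its share of native 16S copies times
    the native copy total, divided by its own copies per genome. Taxa
    without a known copy number fall back to the community mean.
    """
    avg_total_copies = sum(
        e.total_copies_estimate for e in estimates
    ) / len(estimates)
    native_copies_total = avg_total_copies * (
        1.0 - sum(e.observed_percent for e in estimates) / 100.0
    )
    cells = {}
    for taxon, percent in adjusted_profile.abundances.items():
        copies = per_taxon_copies.get(taxon, mean_copies)
        if copies <= 0:
            raise ConfigurationError(
                f"{taxon.key}: copies per genome must be > 0"
            )
        taxon_copies = (percent / 100.0) * native_copies_total
        cells[taxon] = taxon_copies / copies
    return AbsoluteAbundanceTable(
        sample_id=adjusted_profile.sample_id,
        rank=adjusted_profile.rank,
        cells=cells,
        adjusted_percent=dict(adjusted_profile.abundances),
        mass_mg=adjusted_profile.mass_mg,
    )
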
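"""Shipped spike-in protocol presets.

The ``zymo-spikein-control-I`` preset describes the ZymoBIOMICS Spike-in
Control I two-species standard dosed as 10 µL of a 100-fold dilution
(against a 20 µL reference aliquot of undiluted stock): 100,000 cells of
each species per sample, *Imtechella halotolerans* at 3 and *Allobacillus
halotolerans* at 7 16S copies per genome, hence 300,000 and 700,000 16S
copies added.

Lineages are configuration, not biology baked into the code: the preset
places Imtechella in Bacteroidota and Allobacillus in Bacillota (the phyla
relevant for phylum-level spike removal) with standard genus/family
placements; override them in a config file if your classifier says
otherwise.
"""

from __future__ import annotations

from .errors import ConfigurationError
from .lineage import TaxonLineage
from .model import SpikeInProtocol, SpikeInSpeciesSpec

__all__ = ["get_preset", "PRESETS"]

IMTECHELLA_LINEAGE = TaxonLineage(
    phylum="Bacteroidota",
    class_="Flavobacteriia",
    order="Flavobacteriales",
    family="Crocinitomicaceae",
    genus="Imtechella",
    species="Imtechella halotolerans",
)

ALLOBACILLUS_LINEAGE = TaxonLineage(
    phylum="Bacillota",
    class_="Bacilli",
    order="Bacillales",
    family="Bacillaceae",
    genus="Allobacillus",
    species="Allobacillus halotolerans",
)


def _zymo_spikein_control_i() -> SpikeInProtocol:
    return SpikeInProtocol(
        species=(
            SpikeInSpeciesSpec(
                name="Imtechella halotolerans",
                lineage=IMTECHELLA_LINEAGE,
                copies_per_genome=3,
                cells_added=100_000,
            ),
            SpikeInSpeciesSpec(
                name="Allobacillus halotolerans",
                lineage=ALLOBACILLUS_LINEAGE,
                copies_per_genome=7,
                cells_added=100_000,
            ),
        ),
        volume_added=10.0,
        dilution_factor=100.0,
        reference_volume=20.0,
        mean_copies_per_genome_community=5.0,
    )


PRESETS = {
    "zymo-spikein-control-I": _zymo_spikein_control_i,
}


def get_preset(name: str) -> SpikeInProtocol:
    """Return a fresh protocol object for a named preset."""
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    return factory()
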
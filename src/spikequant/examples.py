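"""The packaged worked example.

A single hypothetical sample dosed with the Zymo two-species spike-in:
at the species rank Imtechella halotolerans reads 1%, Allobacillus
halotolerans 3%, Lactobacillus delbrueckii 45% and an aggregate remainder
51%; at the phylum rank Bacteroidota holds 50% (including the Imtechella
1%) and Bacillota 30% (including the Allobacillus 3%). Running the chain
on it gives round numbers at every stage (3.0e7 and ~2.33e7 total copies,
adjusted total 5.12e6 cells, L. delbrueckii 46.875% and 2.4e6 cells),
which makes it the canonical smoke test and the ``demo`` subcommand's
input.
"""

from __future__ import annotations

from .lineage import Rank, Taxon, TaxonLineage
from .model import RelativeAbundanceProfile, SpikeInProtocol
from .presets import get_preset

__all__ = [
    "worked_example_protocol",
    "worked_example_profiles",
    "LACTOBACILLUS_DELBRUECKII",
]

LACTOBACILLUS_DELBRUECKII = Taxon(
    label="Lactobacillus delbrueckii",
    lineage=TaxonLineage(
        phylum="Bacillota",
        class_="Bacilli",
        order="Lactobacillales",
        family="Lactobacillaceae",
        genus="Lactobacillus",
        species="Lactobacillus delbrueckii",
    ),
)


def worked_example_protocol() -> SpikeInProtocol:
    return get_preset("zymo-spikein-control-I")


def worked_example_profiles(
    sample_id: str = "example",
) -> dict[Rank, RelativeAbundanceProfile]:
    """Species- and phylum-rank profiles of the worked example sample."""
    protocol = worked_example_protocol()
    imtechella, allobacillus = (s.taxon for s in protocol.species)

    species_profile = RelativeAbundanceProfile(
        sample_id=sample_id,
        rank=Rank.SPECIES,
        abundances={
            imtechella: 1.0,
            allobacillus: 3.0,
            LACTOBACILLUS_DELBRUECKII: 45.0,
            Taxon(label="Others"): 51.0,
        },
    )

    def phylum(name: str) -> Taxon:
        return Taxon(label=name, lineage=TaxonLineage(phylum=name))

    phylum_profile = RelativeAbundanceProfile(
        sample_id=sample_id,
        rank=Rank.PHYLUM,
        abundances={
            phylum("Bacteroidota"): 50.0,   # includes the 1% Imtechella
            phylum("Bacillota"): 30.0,      # includes the 3% Allobacillus
            phylum("Pseudomonadota"): 12.0,
            phylum("Actinomycetota"): 8.0,
        },
    )
    return {Rank.SPECIES: species_profile, Rank.PHYLUM: phylum_profile}
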
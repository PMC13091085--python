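"""Domain types for spike-in based absolute quantification.

Conventions used throughout:

* relative abundances are stored and exchanged in **percent** (the scale
  every formula in the protocol is written in); fractions appear only
  transiently inside computations;
* absolute abundances are **cells per sample** (a sample being the stated
  mass of material, 100 mg by default);
* a "spike-in species" is a foreign bacterium added at a known cell dose
  before DNA extraction, whose observed relative abundance anchors the
  total microbial load of the sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

from .errors import ConfigurationError
from .lineage import Rank, Taxon, TaxonLineage

__all__ = [
    "SpikeInSpeciesSpec",
    "SpikeInProtocol",
    "RelativeAbundanceProfile",
    "SpikeEstimate",
    "SampleQuantification",
    "AbsoluteAbundanceTable",
    "ProfileValidationReport",
    "validate_profile",
]

#: default tolerance (absolute percent) on the 100% sum of a profile
DEFAULT_SUM_TOLERANCE = 0.5


@dataclass(frozen=True)
class SpikeInSpeciesSpec:
    """One foreign spike-in species and its per-sample dose.

    The dose may be given directly as ``cells_added`` or indirectly via
    ``stock_copies_per_reference_volume`` (16S copies contained in one
    reference-volume aliquot of the undiluted stock, converted to copies
    added by the protocol's volume/dilution arithmetic).
    """

    name: str
    lineage: TaxonLineage
    copies_per_genome: int
    cells_added: Optional[float] = None
    stock_copies_per_reference_volume: Optional[float] = None

    def __post_init__(self) -> None:
        if self.copies_per_genome < 1:
            raise ConfigurationError(
                f"{self.name}: copies_per_genome must be >= 1, "
                f"got {self.copies_per_genome}"
            )
        if self.cells_added is None and \
                self.stock_copies_per_reference_volume is None:
            raise ConfigurationError(
                f"{self.name}: provide cells_added or "
                "stock_copies_per_reference_volume"
            )
        if self.cells_added is not None and self.cells_added <= 0:
            raise ConfigurationError(f"{self.name}: cells_added must be > 0")
        if self.stock_copies_per_reference_volume is not None and \
                self.stock_copies_per_reference_volume <= 0:
            raise ConfigurationError(
                f"{self.name}: stock_copies_per_reference_volume must be > 0"
            )

    @property
    def taxon(self) -> Taxon:
        return Taxon(label=self.name, lineage=self.lineage)


@dataclass(frozen=True)
class SpikeInProtocol:
    """The full spike-in dosing protocol applied to every sample.

    ``volume_added`` µL of a ``dilution_factor``-fold dilution of stock is
    pipetted into each sample; stock copy numbers are quoted per
    ``reference_volume`` µL of undiluted stock.
    ``mean_copies_per_genome_community`` is the assumed average number of
    16S operons per genome in the unknown community (5 is the accepted
    default for mixed bacterial populations).
    """

    species: tuple[SpikeInSpeciesSpec, ...]
    volume_added: float = 10.0
    dilution_factor: float = 100.0
    reference_volume: float = 20.0
    mean_copies_per_genome_community: float = 5.0

    def __post_init__(self) -> None:
        if self.volume_added <= 0:
            raise ConfigurationError("volume_added must be > 0")
        if self.dilution_factor < 1:
            raise ConfigurationError("dilution_factor must be >= 1")
        if self.reference_volume <= 0:
            raise ConfigurationError("reference_volume must be > 0")
        if self.mean_copies_per_genome_community <= 0:
            raise ConfigurationError(
                "mean_copies_per_genome_community must be > 0"
            )
        if not self.species:
            raise ConfigurationError("at least one spike-in species required")
        object.__setattr__(self, "species", tuple(self.species))

    def spike_taxa(self, rank: Rank = Rank.SPECIES) -> tuple[Taxon, ...]:
        return tuple(s.taxon.at_rank(rank) for s in self.species)


@dataclass
class RelativeAbundanceProfile:
    """One sample's taxon → percent map at a single taxonomic rank."""

    sample_id: str
    rank: Rank
    abundances: dict[Taxon, float]
    mass_mg: float = 100.0

    def total(self) -> float:
        return float(sum(self.abundances.values()))

    def get(self, taxon: Taxon) -> Optional[float]:
        return self.abundances.get(taxon)

    def without(self, taxa: Sequence[Taxon]) -> "RelativeAbundanceProfile":
        drop = set(taxa)
        return replace(
            self,
            abundances={t: v for t, v in self.abundances.items()
                        if t not in drop},
        )

    def sorted_taxa(self) -> list[Taxon]:
        return sorted(self.abundances, key=lambda t: t.key)


@dataclass(frozen=True)
class ProfileValidationReport:
    sample_id: str
    violations: tuple[str, ...]

    @property
    def accepted(self) -> bool:
        return not self.violations


def validate_profile(
    profile: RelativeAbundanceProfile,
    tolerance: float = DEFAULT_SUM_TOLERANCE,
) -> ProfileValidationReport:
    """Check a profile against its invariants, returning a report.

    Violations (never exceptions): a negative value, a total outside
    100 ± ``tolerance`` absolute percent, or a non-finite value. Duplicate
    taxa cannot survive the dict container, so they are caught at parse
    time; here we re-assert uniqueness of canonical keys defensively.
    """
    violations: list[str] = []
    for taxon, value in profile.abundances.items():
        if not math.isfinite(value):
            violations.append(f"non-finite abundance for {taxon.key}")
        elif value < 0:
            violations.append(
                f"negative abundance {value} for {taxon.key}"
            )
    total = profile.total()
    if abs(total - 100.0) > tolerance:
        if total == 0:
            violations.append("sum = 0")
        else:
            violations.append(
                f"abundances sum to {total:.6g}, outside 100 ± {tolerance}"
            )
    keys = [t.key for t in profile.abundances]
    if len(keys) != len(set(keys)):
        violations.append("duplicate taxon keys in profile")
    return ProfileValidationReport(
        sample_id=profile.sample_id, violations=tuple(violations)
    )


@dataclass(frozen=True)
class SpikeEstimate:
    """Per-spike-species intermediates of the quantification chain."""

    species: str
    observed_percent: float
    copies_added: float
    total_copies_estimate: float
    cells_estimate: float
    spikein_cells_in_sample: float


@dataclass(frozen=True)
class SampleQuantification:
    """Every intermediate of one sample's absolute quantification."""

    sample_id: str
    rank: Rank
    spike_estimates: tuple[SpikeEstimate, ...]
    average_cells_estimate: float
    adjusted_total_cells: float
    mass_mg: float = 100.0

    @property
    def concordance_ratio(self) -> float:
        """max/min of the per-spike cell estimates (1 = perfect agreement)."""
        cells = [e.cells_estimate for e in self.spike_estimates]
        return max(cells) / min(cells)


@dataclass(frozen=True)
class AbsoluteAbundanceTable:
    """Per-taxon absolute abundance (cells per sample) at one rank."""

    sample_id: str
    rank: Rank
    cells: Mapping[Taxon, float]
    adjusted_percent: Mapping[Taxon, float]
    mass_mg: float = 100.0

    def total_cells(self) -> float:
        return float(sum(self.cells.values()))

    def cells_per_gram(self) -> dict[Taxon, float]:
        scale = 1000.0 / self.mass_mg
        return {t: v * scale for t, v in self.cells.items()}
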
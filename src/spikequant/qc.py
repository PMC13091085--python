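"""Quality control of spike-in recovery.

The spike-in method is only valid inside a working range: a spike too
scarce may drop below the detection floor of sequencing, while a spike too
abundant crowds out the community of interest. The paper-free defaults
below bracket the ~4% spike fraction typical of a well-dosed low-biomass
mucosa sample:

* detection floor 0.1% per species,
* soft working range 0.5–20% for the summed spike fraction (outside →
  warn),
* hard ceiling 50% (at or above → fail),
* dual-spike concordance ratio (max/min of the two total-cell estimates)
  above 2.0 → warn; discordance signals unequal recovery or copy-number
  error.

All thresholds are configurable; QC is a pure function of the profile and
the thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

from .lineage import Rank, Taxon
from .model import RelativeAbundanceProfile, SpikeInProtocol
from .quantify import (
    copies_added_per_species,
    copies_to_cells,
    total_copies_from_spike,
)

__all__ = [
    "QCStatus",
    "QCThresholds",
    "QCReport",
    "check_spike_detection",
    "check_working_range",
    "check_concordance",
    "qc_sample",
]


class QCStatus(str, Enum):
    PASS = "pass"
    WARN = "warn"
    FAIL = "fail"

    def combine(self, other: "QCStatus") -> "QCStatus":
        order = [QCStatus.PASS, QCStatus.WARN, QCStatus.FAIL]
        return max(self, other, key=order.index)


@dataclass(frozen=True)
class QCThresholds:
    """Tunable QC limits, all in percent except the unitless ratio."""

    min_detection_percent: float = 0.1
    soft_range: tuple[float, float] = (0.5, 20.0)
    hard_ceiling_percent: float = 50.0
    max_concordance_ratio: float = 2.0


@dataclass(frozen=True)
class QCReport:
    """Per-sample spike-in QC outcome with every measured quantity."""

    sample_id: str
    spike_percent: Mapping[str, float]  # species -> observed %, 0 if absent
    detected: Mapping[str, bool]
    summed_spike_percent: float
    range_status: QCStatus
    concordance_ratio: Optional[float]  # None when a spike is undetected
    concordance_status: QCStatus
    status: QCStatus
    notes: tuple[str, ...] = field(default=())


def check_spike_detection(
    profile: RelativeAbundanceProfile,
    spike_taxa: Sequence[Taxon],
    min_percent: float = 0.1,
) -> dict[Taxon, bool]:
    """Flag each spike taxon detected iff present at >= ``min_percent``.

    The bound is inclusive: a spike sitting exactly at the floor counts
    as detected.
    """
    flags: dict[Taxon, bool] = {}
    for taxon in spike_taxa:
        value = profile.get(taxon)
        flags[taxon] = value is not None and value >= min_percent
    return flags


def check_working_range(
    summed_spike_percent: float,
    soft_range: tuple[float, float] = (0.5, 20.0),
    hard_ceiling: float = 50.0,
) -> QCStatus:
    """Grade the summed spike percent against the working range."""
    if summed_spike_percent <= 0 or summed_spike_percent >= hard_ceiling:
        return QCStatus.FAIL
    lo, hi = soft_range
    if lo <= summed_spike_percent <= hi:
        return QCStatus.PASS
    return QCStatus.WARN


def check_concordance(
    cell_estimates: Sequence[float],
    max_ratio: float = 2.0,
) -> tuple[QCStatus, float]:
    """Ratio (max/min) of per-spike total-cell estimates, graded."""
    if not cell_estimates:
        raise ValueError("no cell estimates supplied")
    if any(e <= 0 for e in cell_estimates):
        raise ValueError("cell estimates must be positive")
    ratio = max(cell_estimates) / min(cell_estimates)
    status = QCStatus.WARN if ratio > max_ratio else QCStatus.PASS
    return status, ratio


def qc_sample(
    profile: RelativeAbundanceProfile,
    protocol: SpikeInProtocol,
    thresholds: QCThresholds = QCThresholds(),
    rank: Rank = Rank.SPECIES,
) -> QCReport:
    """Full spike-in QC for one sample at the rank where spikes are rows."""
    spike_taxa = list(protocol.spike_taxa(rank))
    detection = check_spike_detection(
        profile, spike_taxa, thresholds.min_detection_percent
    )
    percents: dict[str, float] = {}
    detected: dict[str, bool] = {}
    notes: list[str] = []
    for species, taxon in zip(protocol.species, spike_taxa):
        value = profile.get(taxon) or 0.0
        percents[species.name] = value
        detected[species.name] = detection[taxon]
        if not detection[taxon]:
            notes.append(
                f"spike {species.name!r} undetected "
                f"(<{thresholds.min_detection_percent}%)"
            )

    summed = sum(percents.values())
    range_status = check_working_range(
        summed, thresholds.soft_range, thresholds.hard_ceiling_percent
    )
    if range_status is not QCStatus.PASS:
        notes.append(
            f"summed spike percent {summed:.4g}% outside working range"
        )

    status = range_status
    concordance_ratio: Optional[float] = None
    concordance_status = QCStatus.PASS
    if all(detected.values()):
        cells = [
            copies_to_cells(
                total_copies_from_spike(
                    percents[s.name], copies_added_per_species(protocol, s)
                ),
                protocol.mean_copies_per_genome_community,
            )
            for s in protocol.species
        ]
        concordance_status, concordance_ratio = check_concordance(
            cells, thresholds.max_concordance_ratio
        )
        if concordance_status is QCStatus.WARN:
            notes.append(
                f"spike cell estimates discordant (ratio "
                f"{concordance_ratio:.3g} > {thresholds.max_concordance_ratio})"
            )
        status = status.combine(concordance_status)
    else:
        status = QCStatus.FAIL

    return QCReport(
        sample_id=profile.sample_id,
        spike_percent=percents,
        detected=detected,
        summed_spike_percent=summed,
        range_status=range_status,
        concordance_ratio=concordance_ratio,
        concordance_status=concordance_status,
        status=status,
        notes=tuple(notes),
    )
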
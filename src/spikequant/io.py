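"""Readers and writers for abundance tables, configs and reports.

Table layout: delimited text (tab for ``.tsv``/``.txt``, comma for
``.csv``), first column the taxon lineage string, one column per sample,
values in percent. Spike-in protocols are YAML documents, optionally
based on a shipped preset. All writers order taxa by canonical lineage so
reruns are byte-identical, and serialise values at full precision —
rounding is opt-in display behaviour.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ProfileError
from .lineage import (
    LineageDialect,
    LineageParseError,
    Rank,
    Taxon,
    parse_lineage,
    parse_taxon,
)
from .model import (
    DEFAULT_SUM_TOLERANCE,
    AbsoluteAbundanceTable,
    RelativeAbundanceProfile,
    SampleQuantification,
    SpikeInProtocol,
    SpikeInSpeciesSpec,
    validate_profile,
)
from .presets import get_preset
from .qc import QCReport

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_spike_config",
    "read_per_taxon_copies",
    "write_absolute_tables",
    "write_quantification_report",
    "write_run_log",
]


def _separator_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_abundance_table(
    path: str | Path,
    dialect: LineageDialect | str = LineageDialect.RANK_PREFIXED,
    rank: Optional[Rank] = None,
    mass_mg: float = 100.0,
    sum_tolerance: float = DEFAULT_SUM_TOLERANCE,
    validate: bool = True,
) -> dict[str, RelativeAbundanceProfile]:
    """Read one profile per sample column from a delimited table.

    The rank is inferred as the deepest rank populated by any lineage in
    the table unless given explicitly. Parse problems are reported with
    row/column coordinates; validation failures list every violation.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_separator_for(path), index_col=0)
    except pd.errors.EmptyDataError:
        raise ProfileError(f"{path}: table is empty") from None
    if frame.shape[1] == 0:
        raise ProfileError(f"{path}: no sample columns after the lineage column")
    if frame.shape[0] == 0:
        raise ProfileError(f"{path}: no taxon rows")

    taxa: list[Taxon] = []
    for row_num, label in enumerate(frame.index, start=2):
        try:
            taxa.append(parse_taxon(str(label), dialect))
        except LineageParseError as exc:
            raise ProfileError(f"{path}: row {row_num}: {exc}") from exc
    keys = [t.key for t in taxa]
    dupes = {k for k in keys if keys.count(k) > 1}
    if dupes:
        raise ProfileError(
            f"{path}: duplicate lineage rows: {', '.join(sorted(dupes))}"
        )

    if rank is None:
        depths = [
            t.lineage.deepest_rank for t in taxa if t.lineage is not None
        ]
        if not depths:
            raise ProfileError(
                f"{path}: no parseable lineages; pass the rank explicitly"
            )
        rank = max(depths, key=lambda r: r.depth)

    profiles: dict[str, RelativeAbundanceProfile] = {}
    for col_num, sample in enumerate(frame.columns, start=2):
        values = frame[sample]
        numeric = pd.to_numeric(values, errors="coerce")
        bad = numeric.isna() & values.notna()
        if bad.any():
            row = frame.index.get_loc(values[bad].index[0]) + 2
            raise ProfileError(
                f"{path}: non-numeric value at row {row}, column {col_num} "
                f"(sample {sample!r})"
            )
        profile = RelativeAbundanceProfile(
            sample_id=str(sample),
            rank=rank,
            abundances={
                taxon: float(v)
                for taxon, v in zip(taxa, numeric.fillna(0.0))
            },
            mass_mg=mass_mg,
        )
        if validate:
            report = validate_profile(profile, sum_tolerance)
            if not report.accepted:
                raise ProfileError(
                    f"{path}: sample {sample!r}: "
                    + "; ".join(report.violations)
                )
        profiles[str(sample)] = profile
    return profiles


def write_abundance_table(
    profiles: Mapping[str, RelativeAbundanceProfile],
    path: str | Path,
) -> None:
    """Write profiles in the same layout the reader accepts."""
    path = Path(path)
    all_taxa = sorted(
        {t for p in profiles.values() for t in p.abundances},
        key=lambda t: t.key,
    )
    frame = pd.DataFrame(
        {
            sample: [p.abundances.get(t, 0.0) for t in all_taxa]
            for sample, p in profiles.items()
        },
        index=[t.key for t in all_taxa],
    )
    frame.index.name = "lineage"
    frame.to_csv(path, sep=_separator_for(path), float_format="%.12g")


def _species_from_mapping(entry: Mapping) -> SpikeInSpeciesSpec:
    for field in ("name", "lineage", "copies_per_genome"):
        if field not in entry:
            raise ConfigurationError(
                f"spike species entry missing required field {field!r}"
            )
    lineage = entry["lineage"]
    if isinstance(lineage, str):
        lineage = parse_lineage(
            lineage, entry.get("lineage_dialect", "rank-prefixed")
        )
    def _maybe_float(value):
        # YAML 1.1 reads "1.0e7" (no sign) as a string; coerce defensively
        return None if value is None else float(value)

    return SpikeInSpeciesSpec(
        name=str(entry["name"]),
        lineage=lineage,
        copies_per_genome=int(entry["copies_per_genome"]),
        cells_added=_maybe_float(entry.get("cells_added")),
        stock_copies_per_reference_volume=_maybe_float(
            entry.get("stock_copies_per_reference_volume")
        ),
    )


def read_spike_config(path: str | Path) -> SpikeInProtocol:
    """Load a spike-in protocol from a YAML document.

    A ``preset`` key loads a shipped protocol; any other keys override
    preset fields. Without a preset, ``species`` is required and each
    entry needs ``name``, ``lineage`` and ``copies_per_genome`` plus at
    least one dose field.
    """
    path = Path(path)
    with open(path) as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: config must be a mapping")

    base: Optional[SpikeInProtocol] = None
    if "preset" in doc:
        base = get_preset(str(doc["preset"]))

    species: Optional[tuple[SpikeInSpeciesSpec, ...]] = None
    if "species" in doc:
        entries = doc["species"]
        if not isinstance(entries, Sequence) or not entries:
            raise ConfigurationError(f"{path}: species must be a non-empty list")
        species = tuple(_species_from_mapping(e) for e in entries)
    elif base is not None:
        species = base.species
    else:
        raise ConfigurationError(
            f"{path}: missing required field 'species' (or a 'preset')"
        )

    def _field(name: str, default):
        if name in doc:
            return doc[name]
        if base is not None:
            return getattr(base, name)
        return default

    return SpikeInProtocol(
        species=species,
        volume_added=float(_field("volume_added", 10.0)),
        dilution_factor=float(_field("dilution_factor", 100.0)),
        reference_volume=float(_field("reference_volume", 20.0)),
        mean_copies_per_genome_community=float(
            _field("mean_copies_per_genome_community", 5.0)
        ),
    )


def read_per_taxon_copies(
    path: str | Path,
    dialect: LineageDialect | str = LineageDialect.RANK_PREFIXED,
) -> dict[Taxon, float]:
    """Two-column table: lineage, 16S copies per genome."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_separator_for(path), index_col=0)
    column = frame.iloc[:, 0]
    return {
        parse_taxon(str(label), dialect): float(v)
        for label, v in column.items()
    }


def _round_mapping(mapping: Mapping[Taxon, float], decimals: Optional[int]):
    if decimals is None:
        return dict(mapping)
    return {t: round(v, decimals) for t, v in mapping.items()}


def write_absolute_tables(
    tables: Mapping[str, AbsoluteAbundanceTable],
    path: str | Path,
    paper_rounding: bool = False,
) -> None:
    """Absolute-abundance TSV: one percent + cells column pair per sample.

    ``paper_rounding`` renders percents at 2 decimals and cells as
    integers; otherwise values are full precision.
    """
    path = Path(path)
    all_taxa = sorted(
        {t for tab in tables.values() for t in tab.cells},
        key=lambda t: t.key,
    )
    columns: dict[str, list[float]] = {}
    for sample, table in tables.items():
        percents = _round_mapping(
            table.adjusted_percent, 2 if paper_rounding else None
        )
        cells = _round_mapping(table.cells, 0 if paper_rounding else None)
        columns[f"{sample}.adjusted_percent"] = [
            percents.get(t, 0.0) for t in all_taxa
        ]
        columns[f"{sample}.cells"] = [cells.get(t, 0.0) for t in all_taxa]
    frame = pd.DataFrame(columns, index=[t.key for t in all_taxa])
    frame.index.name = "lineage"
    frame.to_csv(path, sep=_separator_for(path), float_format="%.12g")


def _qc_record(report: QCReport) -> dict:
    record = dataclasses.asdict(report)
    record["range_status"] = report.range_status.value
    record["concordance_status"] = report.concordance_status.value
    record["status"] = report.status.value
    record["notes"] = list(report.notes)
    return record


def write_quantification_report(
    quantifications: Mapping[str, SampleQuantification],
    qc_reports: Mapping[str, QCReport],
    path: str | Path,
) -> None:
    """JSON report carrying every per-sample intermediate and QC record."""
    payload = {
        "samples": {
            sample: {
                "quantification": dataclasses.asdict(quant)
                | {"rank": quant.rank.value},
                "qc": _qc_record(qc_reports[sample])
                if sample in qc_reports else None,
            }
            for sample, quant in quantifications.items()
        }
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def write_run_log(
    path: str | Path,
    protocol: SpikeInProtocol,
    thresholds=None,
    seed: Optional[int] = None,
    extra: Optional[Mapping] = None,
) -> None:
    """Machine-readable provenance record for a run."""
    record = {
        "software": "spikequant",
        "version": __version__,
        "protocol": {
            "volume_added_ul": protocol.volume_added,
            "dilution_factor": protocol.dilution_factor,
            "reference_volume_ul": protocol.reference_volume,
            "mean_copies_per_genome_community":
                protocol.mean_copies_per_genome_community,
            "species": [
                {
                    "name": s.name,
                    "lineage": s.lineage.format(),
                    "copies_per_genome": s.copies_per_genome,
                    "cells_added": s.cells_added,
                    "stock_copies_per_reference_volume":
                        s.stock_copies_per_reference_volume,
                }
                for s in protocol.species
            ],
        },
        "qc_thresholds": dataclasses.asdict(thresholds) if thresholds else None,
        "seed": seed,
    }
    if extra:
        record.update(extra)
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True))
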
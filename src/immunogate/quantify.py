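"""Absolute-count normalization and the analysis-scale transform.

Gated event counts are converted to cells per µL of whole blood:
the suspension concentration (count / acquired volume) multiplied by
the blood-to-total-suspension dilution factor
((blood + diluent) / blood; 11 for 50 µL blood in 550 µL total).
Counts on the analysis scale are log10(x + offset) with a default
offset of 1 so zero counts stay representable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import EventTable, SubsetResult

DEFAULT_LOG_OFFSET = 1.0


def dilution_factor(blood_volume: float, diluent_volume: float) -> float:
    """Whole-blood dilution correction, exposed separately for audit."""
    if blood_volume <= 0:
        raise ValueError("blood_volume must be positive")
    if diluent_volume < 0:
        raise ValueError("diluent_volume must be non-negative")
    return (blood_volume + diluent_volume) / blood_volume


def absolute_count(
    gate_count: float,
    acquired_volume: float,
    blood_volume: float,
    diluent_volume: float,
) -> float:
    """Cells/µL of whole blood from a gated event count.

    ``acquired_volume`` is µL of suspension run through the instrument;
    linear in ``gate_count`` and inverse in ``acquired_volume``.
    """
    if acquired_volume <= 0:
        raise ValueError("acquired_volume must be positive")
    if gate_count < 0:
        raise ValueError("gate_count must be non-negative")
    return gate_count / acquired_volume * dilution_factor(blood_volume, diluent_volume)


def log10_series(values, offset: float = DEFAULT_LOG_OFFSET) -> np.ndarray:
    """log10(value + offset), the analysis scale for abundances.

    The default offset of 1 maps a zero count to 0.  A zero offset is
    allowed only when every value is strictly positive.
    """
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("negative abundance")
    if ((arr + offset) <= 0).any():
        raise ValueError("offset too small: log10 undefined for some values")
    return np.log10(arr + offset)


@dataclass
class AbsoluteCountTable:
    """Tidy per-(sample, node) absolute counts with provenance metadata."""

    table: pd.DataFrame
    log_offset: float = DEFAULT_LOG_OFFSET

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def quantify_sample(
    result: SubsetResult,
    events: EventTable,
    reported_only: bool = True,
    log_offset: float = DEFAULT_LOG_OFFSET,
) -> AbsoluteCountTable:
    """Absolute counts for every (reported) gate node of one sample."""
    df = result.table
    if reported_only:
        df = df[df["reported"]]
    factor = dilution_factor(events.blood_volume, events.diluent_volume)
    cells = df["count"].to_numpy() / events.acquired_volume * factor
    out = pd.DataFrame(
        {
            "sample_id": events.sample_id,
            "animal_id": events.animal_id,
            "timepoint": events.timepoint,
            "group": events.group,
            "block": events.block,
            "panel": result.panel_name,
            "node": df["node"].to_numpy(),
            "count": df["count"].to_numpy(),
            "fraction_of_leukocytes": df["fraction_of_leukocytes"].to_numpy(),
            "cells_per_uL": cells,
            "log10_value": log10_series(cells, log_offset),
        }
    )
    return AbsoluteCountTable(out, log_offset)


def quantify_study(
    results: list[tuple[SubsetResult, EventTable]],
    reported_only: bool = True,
    log_offset: float = DEFAULT_LOG_OFFSET,
) -> AbsoluteCountTable:
    """Concatenated absolute-count table for a whole study."""
    parts = [
        quantify_sample(r, e, reported_only, log_offset).table for r, e in results
    ]
    return AbsoluteCountTable(pd.concat(parts, ignore_index=True), log_offset)
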
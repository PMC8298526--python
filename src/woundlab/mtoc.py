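"""MTOC orientation scoring and polarized-fraction time courses.

A cell counts as polarized when its nucleus→MTOC vector deviates from the
wound-closure direction by at most a cone half-angle (60°, boundary
inclusive).  Fractions of polarized cells are aggregated per condition,
time after scratch and monolayer row (first/second line), with Wilson 95%
binomial confidence intervals.  Under uniformly random MTOC placement the
expected polarized fraction is cone/180 (33.3% at 60°), the chance baseline
against which observed polarization is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

CONE_DEG_DEFAULT = 60.0


@dataclass
class CellPolarityRecord:
    cell_id: str
    nucleus: tuple[float, float]
    mtoc: tuple[float, float]
    wound_direction_deg: float
    deviation_deg: float
    polarized: bool
    row: str = "first_line"
    time_post_scratch: float = 0.0
    condition: str = ""
    valid: bool = True


def classify_polarized(
    nucleus: tuple[float, float],
    mtoc: tuple[float, float],
    wound_direction_deg: float,
    cone_deg: float = CONE_DEG_DEFAULT,
) -> tuple[float, bool]:
    """Unsigned deviation (degrees, [0, 180]) and the cone classification.

    Coincident nucleus/MTOC points leave the deviation undefined (NaN,
    unpolarized, to be flagged by the caller).
    """
    dx = mtoc[0] - nucleus[0]
    dy = mtoc[1] - nucleus[1]
    if dx == 0.0 and dy == 0.0:
        return float("nan"), False
    ang = math.degrees(math.atan2(dy, dx))
    dev = abs((ang - wound_direction_deg + 180.0) % 360.0 - 180.0)
    return dev, dev <= cone_deg


def make_record(
    cell_id: str,
    nucleus: tuple[float, float],
    mtoc: tuple[float, float],
    wound_direction_deg: float,
    cone_deg: float = CONE_DEG_DEFAULT,
    **meta,
) -> CellPolarityRecord:
    dev, pol = classify_polarized(nucleus, mtoc, wound_direction_deg, cone_deg)
    return CellPolarityRecord(
        cell_id=cell_id,
        nucleus=tuple(nucleus),
        mtoc=tuple(mtoc),
        wound_direction_deg=wound_direction_deg,
        deviation_deg=dev,
        polarized=pol,
        valid=not math.isnan(dev),
        **meta,
    )


def records_table(records: list[CellPolarityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": r.cell_id,
                "condition": r.condition,
                "row": r.row,
                "time_post_scratch": r.time_post_scratch,
                "deviation_deg": r.deviation_deg,
                "polarized": r.polarized,
                "valid": r.valid,
            }
            for r in records
        ]
    )


def polarized_fraction(
    records: list[CellPolarityRecord],
    group_keys: list[str] = ("condition", "time_post_scratch", "row"),
) -> pd.DataFrame:
    """Percent polarized with Wilson 95% CI per group.

    Records with undefined deviation are dropped; empty groups are omitted.
    """
    tab = records_table(records)
    tab = tab[tab["valid"]]
    if tab.empty:
        raise ValueError("no valid records")
    rows = []
    for keys, grp in tab.groupby(list(group_keys)):
        n = len(grp)
        k = int(grp["polarized"].sum())
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        row = dict(zip(group_keys, keys if isinstance(keys, tuple) else (keys,)))
        row.update(
            {
                "fraction_polarized": 100.0 * k / n,
                "n_cells": n,
                "ci_low": 100.0 * lo,
                "ci_high": 100.0 * hi,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
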
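"""Quality control of raw KASP fluorescence: read-cycle selection,
low-fluorescence exclusion, control screening and replicate averaging.

The low-fluorescence region is a triangle in the (FAM, HEX) plane, by default
with vertices (0,0), (2,0), (0,2): signals there are dominated by background
noise and failed amplifications.  The triangle boundary counts as *inside*
(excluded) — the region is a noise floor, so the inclusive boundary is the
conservative choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import QcConfig

__all__ = [
    "points_in_triangle",
    "filter_low_fluorescence",
    "CycleSelection",
    "select_read_cycle",
    "screen_field_controls",
    "average_replicates",
]

#: Dataset labels treated as amplification controls for cycle selection.
CONTROL_LABELS = ("ntc", "lab_negative")

_BARY_TOL = 1e-12


def points_in_triangle(
    fam: np.ndarray,
    hex_: np.ndarray,
    vertices: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Boolean mask: which (fam, hex) points lie inside or on the triangle.

    Membership is decided by barycentric coordinates; the boundary is
    inclusive.  Degenerate (collinear) vertices raise ``ValueError``.
    """
    (x1, y1), (x2, y2), (x3, y3) = [(float(x), float(y)) for x, y in vertices]
    det = (x1 - x3) * (y2 - y3) - (x2 - x3) * (y1 - y3)
    if abs(det) < 1e-300:
        raise ValueError("degenerate triangle: vertices are collinear")
    fam = np.asarray(fam, dtype=float)
    hex_ = np.asarray(hex_, dtype=float)
    l1 = ((y2 - y3) * (fam - x3) + (x3 - x2) * (hex_ - y3)) / det
    l2 = ((y3 - y1) * (fam - x3) + (x1 - x3) * (hex_ - y3)) / det
    l3 = 1.0 - l1 - l2
    return (l1 >= -_BARY_TOL) & (l2 >= -_BARY_TOL) & (l3 >= -_BARY_TOL)


def filter_low_fluorescence(
    readings: pd.DataFrame,
    triangle: Sequence[tuple[float, float]] = ((0.0, 0.0), (2.0, 0.0), (0.0, 2.0)),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split readings into (retained, excluded) by the low-fluorescence triangle.

    A reading is excluded iff its (fam, hex) point lies inside the triangle or
    on its boundary.  The two frames partition the input.
    """
    inside = points_in_triangle(
        readings["fam"].to_numpy(), readings["hex"].to_numpy(), triangle
    )
    return readings.loc[~inside].copy(), readings.loc[inside].copy()


def exclusion_counts(excluded: pd.DataFrame, total: pd.DataFrame) -> pd.DataFrame:
    """Per-dataset counts and fractions of low-signal exclusions."""
    n_total = total.groupby("dataset").size().rename("n_total")
    n_excl = excluded.groupby("dataset").size().rename("n_excluded")
    out = pd.concat([n_total, n_excl], axis=1).fillna(0).astype({"n_excluded": int})
    out["fraction"] = out["n_excluded"] / out["n_total"]
    return out.reset_index()


@dataclass
class CycleSelection:
    """Outcome of the read-cycle selection rule."""

    cycle: int
    clean_cycles: list[int]
    dimer_cycles: list[int]
    fallback: bool = False  # True when every candidate showed dimers

    def __int__(self) -> int:
        return self.cycle


def select_read_cycle(
    readings: pd.DataFrame,
    candidate_cycles: Sequence[int],
    triangle: Sequence[tuple[float, float]] = ((0.0, 0.0), (2.0, 0.0), (0.0, 2.0)),
) -> CycleSelection:
    """Choose the analysis read cycle for a plate.

    The rule: take the largest candidate cycle at which no NTC or lab-negative
    reading falls outside the low-fluorescence triangle.  Fluorescence outside
    the noise floor in a no-template well is the operational proxy for
    primer-dimer formation, which grows with cycle count.  If every candidate
    cycle shows such signal, the smallest candidate is returned with a
    ``fallback`` flag and a warning.

    Cycles with no control readings cannot be verified and are never selected.
    """
    candidates = sorted(int(c) for c in candidate_cycles)
    if not candidates:
        raise ValueError("candidate_cycles must be non-empty")
    controls = readings[readings["dataset"].isin(CONTROL_LABELS)]
    if controls.empty or not controls["read_cycle"].isin(candidates).any():
        raise ValueError("cycle selection impossible without controls")

    clean, dimer = [], []
    for cyc in candidates:
        ctl = controls[controls["read_cycle"] == cyc]
        if ctl.empty:
            continue
        outside = ~points_in_triangle(
            ctl["fam"].to_numpy(), ctl["hex"].to_numpy(), triangle
        )
        (dimer if outside.any() else clean).append(cyc)

    if clean:
        return CycleSelection(cycle=max(clean), clean_cycles=clean, dimer_cycles=dimer)
    warnings.warn(
        "all candidate cycles show control signal outside the low-fluorescence "
        f"triangle; falling back to the smallest candidate ({candidates[0]})",
        stacklevel=2,
    )
    return CycleSelection(
        cycle=candidates[0], clean_cycles=[], dimer_cycles=dimer, fallback=True
    )


def screen_field_controls(
    readings: pd.DataFrame,
    triangle: Sequence[tuple[float, float]] = ((0.0, 0.0), (2.0, 0.0), (0.0, 2.0)),
) -> pd.DataFrame:
    """Contamination screen for field negative controls.

    For each field-control sample and SNP, count PCRs with fluorescence
    outside the low-fluorescence triangle.  Any control with at least one
    such PCR is flagged as possible contamination; this is a warning only —
    downstream analysis proceeds.

    Returns a frame with per-(sample, snp) counts plus a per-sample summary
    row (snp_id = "ALL") carrying the overall fraction and flag.
    """
    ctl = readings[readings["dataset"] == "field_negative"]
    rows = []
    for sample_id, grp in ctl.groupby("sample_id", sort=True):
        outside = ~points_in_triangle(
            grp["fam"].to_numpy(), grp["hex"].to_numpy(), triangle
        )
        grp = grp.assign(_outside=outside)
        for snp_id, sub in grp.groupby("snp_id", sort=True):
            rows.append(
                dict(
                    sample_id=sample_id,
                    snp_id=snp_id,
                    n_pcrs=len(sub),
                    n_outside=int(sub["_outside"].sum()),
                )
            )
        rows.append(
            dict(
                sample_id=sample_id,
                snp_id="ALL",
                n_pcrs=len(grp),
                n_outside=int(grp["_outside"].sum()),
            )
        )
    report = pd.DataFrame(rows, columns=["sample_id", "snp_id", "n_pcrs", "n_outside"])
    if not report.empty:
        report["fraction"] = report["n_outside"] / report["n_pcrs"]
        report["flagged"] = report["n_outside"] >= 1
    else:
        report["fraction"] = pd.Series(dtype=float)
        report["flagged"] = pd.Series(dtype=bool)
    return report


def average_replicates(
    retained: pd.DataFrame,
    excluded: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average retained PCR replicates per (sample, SNP).

    Arithmetic means of FAM and HEX over the retained replicates reduce
    stochastic per-well variation.  Groups whose replicates were all excluded
    by the low-fluorescence filter yield no averaged signal; they are returned
    in the ``dropped`` frame (requires passing ``excluded``).

    Returns
    -------
    (averaged, dropped)
        ``averaged`` has columns sample_id, snp_id, dataset, fam_mean,
        hex_mean, n_replicates; ``dropped`` lists fully-excluded groups.
    """
    key = ["sample_id", "snp_id", "dataset"]
    averaged = (
        retained.groupby(key, sort=True)
        .agg(fam_mean=("fam", "mean"), hex_mean=("hex", "mean"), n_replicates=("fam", "size"))
        .reset_index()
    )
    if excluded is not None and not excluded.empty:
        excl_groups = excluded[key].drop_duplicates()
        have = averaged[key].drop_duplicates()
        dropped = excl_groups.merge(have, on=key, how="left", indicator=True)
        dropped = dropped[dropped["_merge"] == "left_only"].drop(columns="_merge")
        dropped = dropped.reset_index(drop=True)
    else:
        dropped = pd.DataFrame(columns=key)
    return averaged, dropped
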
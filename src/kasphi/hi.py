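"""Mapping fluorescence angles to the hybrid index (HI).

HI is the proportion of *T. macedonicus* alleles: 0 = pure *T. ivanbureschi*,
1 = pure *T. macedonicus*, 0.5 = F1-like composition.  Per SNP, the map is a
piecewise-linear interpolation along the arc defined by the three genotype
centroid angles: HI = 0 at alpha_a, 0.5 at alpha_ab, 1 at alpha_b.  Samples
beyond the homozygote anchors are linearly extrapolated rather than
truncated, preserving linearity and allowing minor excursions outside [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import GENOTYPE_HI, PopulationDesign, SnpCalibration

__all__ = [
    "angle_of",
    "angle_to_hi",
    "hi_to_angle",
    "expected_hi",
    "biomass_corrected_hi",
    "population_hi",
]


def angle_of(fam, hex_):
    """Angle (degrees) of a fluorescence point from the origin.

    0 deg along the FAM axis, 90 deg along the HEX axis; the origin itself
    has no angle and raises ``ValueError``.  Accepts scalars or arrays.
    """
    fam = np.asarray(fam, dtype=float)
    hex_ = np.asarray(hex_, dtype=float)
    if np.any((fam == 0.0) & (hex_ == 0.0)):
        raise ValueError("cannot take the angle of the origin (fam = hex = 0)")
    out = np.degrees(np.arctan2(hex_, fam))
    return float(out) if out.ndim == 0 else out


def angle_to_hi(alpha, cal: SnpCalibration):
    """Piecewise-linear HI of an angle under a SNP's calibration.

    On [alpha_ab, alpha_a]: HI = 0.5 * (alpha_a - alpha) / (alpha_a - alpha_ab);
    on [alpha_b, alpha_ab]: HI = 0.5 + 0.5 * (alpha_ab - alpha) / (alpha_ab - alpha_b).
    Outside [alpha_b, alpha_a] the adjacent segment extends linearly — no
    truncation.  The map is continuous and strictly decreasing in alpha.
    """
    cal.validate()
    alpha = np.asarray(alpha, dtype=float)
    upper = 0.5 * (cal.alpha_a - alpha) / (cal.alpha_a - cal.alpha_ab)
    lower = 0.5 + 0.5 * (cal.alpha_ab - alpha) / (cal.alpha_ab - cal.alpha_b)
    out = np.where(alpha >= cal.alpha_ab, upper, lower)
    return float(out) if out.ndim == 0 else out


def hi_to_angle(hi, cal: SnpCalibration):
    """Inverse of :func:`angle_to_hi` (used by the simulator)."""
    cal.validate()
    hi = np.asarray(hi, dtype=float)
    upper = cal.alpha_a - 2.0 * hi * (cal.alpha_a - cal.alpha_ab)
    lower = cal.alpha_ab - 2.0 * (hi - 0.5) * (cal.alpha_ab - cal.alpha_b)
    out = np.where(hi <= 0.5, upper, lower)
    return float(out) if out.ndim == 0 else out


def expected_hi(
    design: PopulationDesign,
    verified: dict[tuple[str, str], str] | None = None,
    snp_ids: list[str] | None = None,
) -> dict[str, float | None]:
    """Expected HI of a population per SNP, from verified member genotypes.

    ``verified`` maps (animal_id, snp_id) -> genotype class for calls that
    survived genotype verification.  A (population, SNP) where any member
    lacks a verified call is unavailable (``None``) and propagates as an
    exclusion downstream.  With ``verified=None`` the design's expected
    genotypes are taken at face value for every SNP in ``snp_ids``.
    """
    if snp_ids is None:
        if verified is None:
            raise ValueError("need snp_ids when no verified map is given")
        snp_ids = sorted({snp for _, snp in verified})
    out: dict[str, float | None] = {}
    for snp in snp_ids:
        contribs = []
        ok = True
        for animal_id, exp_geno, _ in design.members:
            if verified is None:
                geno = exp_geno
            else:
                geno = verified.get((animal_id, snp))
                if geno is None:
                    ok = False
                    break
            contribs.append(GENOTYPE_HI[geno])
        out[snp] = float(np.mean(contribs)) if ok else None
    return out


def biomass_corrected_hi(design: PopulationDesign) -> float:
    """Biomass-weighted expected HI: sum(mass_i * hi_i) / sum(mass_i).

    Weights each member's genotype contribution by its body mass, emulating
    mass-proportional eDNA shedding.  With equal masses this reduces to the
    unweighted expected HI.
    """
    masses = np.array([m for _, _, m in design.members], dtype=float)
    if np.any(~np.isfinite(masses)) or np.any(masses <= 0):
        raise ValueError(
            f"population {design.population_id}: member masses must be positive"
        )
    his = np.array([GENOTYPE_HI[g] for _, g, _ in design.members], dtype=float)
    return float(np.sum(masses * his) / np.sum(masses))


def population_hi(per_snp_hi) -> tuple[float, int]:
    """Aggregate one eDNA sample's per-SNP HI values into a single estimate.

    Arithmetic mean over the available (non-excluded) SNP estimates; returns
    (mean, number of SNPs used).  Zero available SNPs is an error.
    """
    vals = np.asarray([v for v in per_snp_hi if v is not None and np.isfinite(v)], dtype=float)
    if vals.size == 0:
        raise ValueError("no available per-SNP HI estimates to aggregate")
    return float(vals.mean()), int(vals.size)
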
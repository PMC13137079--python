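"""Per-SNP calibration from verified skin-swab genotypes.

The calibration turns each SNP's raw fluorescence geometry into three anchor
angles.  Homozygotes for the HEX-reported allele (class A) should cluster near
90 deg and FAM-reported homozygotes (class B) near 0 deg, but residual
fluorescence in the opposite channel pulls both inward, and unequal
allele-specific primer competition displaces the heterozygous cluster away
from the theoretical 45 deg differently for every SNP.  Anchoring the hybrid
index to the *measured* centroid angles absorbs this SNP-specific technical
variation.

Pipeline order (each step feeds the next):

1. ``compute_centroids`` — component-wise median centroid per genotype class.
2. ``flag_mismatches``  — nearest-centroid check of every swab against its
   expected genotype; mismatches are excluded together with the linked eDNA
   calls, because those environmental samples can no longer be validated.
3. ``exclude_outliers`` — within-cluster distances >= median + 3 x MAD.
4. centroid recomputation on the cleaned clusters, then ``centroid_angles``.

``calibrate_panel`` runs all four.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    GENOTYPES,
    CalibrationError,
    PopulationDesign,
    QcConfig,
    SnpCalibration,
)

__all__ = [
    "compute_centroids",
    "MismatchResult",
    "flag_mismatches",
    "exclude_outliers",
    "centroid_angles",
    "CalibrationResult",
    "calibrate_panel",
]


def compute_centroids(
    signals: pd.DataFrame,
    expected: Mapping[str, str],
) -> pd.DataFrame:
    """Median centroid per (SNP, genotype class) from averaged swab signals.

    The centroid is the component-wise (marginal) median of the class's
    averaged FAM/HEX values — the robust location estimate "median
    fluorescence" taken per channel.

    Parameters
    ----------
    signals
        Averaged swab signals (columns sample_id, snp_id, fam_mean, hex_mean).
    expected
        animal_id -> expected genotype class ("A" | "AB" | "B").

    Returns
    -------
    Frame indexed by rows (snp_id, genotype, fam, hex, n_points).

    Raises
    ------
    CalibrationError
        If any SNP lacks samples for one of the three classes.
    """
    df = signals.copy()
    df["genotype"] = df["sample_id"].map(expected)
    df = df[df["genotype"].notna()]
    rows = []
    for snp_id, snp_grp in df.groupby("snp_id", sort=True):
        present = set(snp_grp["genotype"])
        missing = [g for g in GENOTYPES if g not in present]
        if missing:
            raise CalibrationError(
                f"SNP {snp_id}: no swab samples for genotype class(es) {missing}"
            )
        for genotype, cls in snp_grp.groupby("genotype"):
            rows.append(
                dict(
                    snp_id=snp_id,
                    genotype=genotype,
                    fam=float(cls["fam_mean"].median()),
                    hex=float(cls["hex_mean"].median()),
                    n_points=len(cls),
                )
            )
    return pd.DataFrame(rows)


def _centroid_lookup(centroids: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float]]:
    return {
        (r.snp_id, r.genotype): (r.fam, r.hex) for r in centroids.itertuples()
    }


@dataclass
class MismatchResult:
    """Mismatched-genotype calls and everything they drag out of the analysis."""

    mismatches: pd.DataFrame
    #: (sample_id, snp_id) swab calls to drop.
    excluded_swab_calls: set[tuple[str, str]]
    #: (population_id, snp_id) eDNA calls to drop (populations housing the animal).
    excluded_edna_calls: set[tuple[str, str]]
    #: Animals mismatched at every SNP — excluded entirely.
    excluded_animals: set[str]
    #: Populations excluded entirely (they housed a fully-excluded animal).
    excluded_populations: set[str]


def flag_mismatches(
    signals: pd.DataFrame,
    expected: Mapping[str, str],
    centroids: pd.DataFrame,
    designs: list[PopulationDesign] | None = None,
) -> MismatchResult:
    """Nearest-centroid genotype verification of swab samples.

    Each swab (sample, SNP) point is compared with all three class centroids
    by Euclidean distance.  A call whose nearest centroid differs from the
    expected class is a *mismatched genotype* — potential genotyping error or
    mislabelling.  Exact distance ties are ambiguous and treated as
    mismatches, since an ambiguous call cannot validate anything.

    Exclusion propagation: a mismatched swab call drops (a) itself and (b)
    the eDNA calls at that SNP for every population housing the animal.  An
    animal mismatched at *all* SNPs it was typed at is presumed mislabelled
    and excluded entirely, along with all eDNA samples from its containers.
    """
    lut = _centroid_lookup(centroids)
    rows = []
    snps_typed: dict[str, set[str]] = {}
    snps_mismatched: dict[str, set[str]] = {}
    for r in signals.itertuples():
        exp = expected.get(r.sample_id)
        if exp is None:
            continue
        snps_typed.setdefault(r.sample_id, set()).add(r.snp_id)
        dists = {}
        for g in GENOTYPES:
            cf, ch = lut[(r.snp_id, g)]
            dists[g] = math.hypot(r.fam_mean - cf, r.hex_mean - ch)
        dmin = min(dists.values())
        nearest = [g for g in GENOTYPES if dists[g] == dmin]
        ambiguous = len(nearest) > 1
        is_mismatch = ambiguous or nearest[0] != exp
        if is_mismatch:
            snps_mismatched.setdefault(r.sample_id, set()).add(r.snp_id)
            rows.append(
                dict(
                    sample_id=r.sample_id,
                    snp_id=r.snp_id,
                    assigned_genotype=exp,
                    nearest_genotype=nearest[0],
                    fam=r.fam_mean,
                    hex=r.hex_mean,
                    own_dist=dists[exp],
                    nearest_dist=dmin,
                    ambiguous=ambiguous,
                )
            )
    mismatches = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "snp_id", "assigned_genotype", "nearest_genotype",
            "fam", "hex", "own_dist", "nearest_dist", "ambiguous",
        ],
    )

    excluded_animals = {
        a for a, typed in snps_typed.items()
        if typed and snps_mismatched.get(a, set()) >= typed
    }
    excluded_swab = {
        (r.sample_id, r.snp_id) for r in mismatches.itertuples()
    }

    excluded_edna: set[tuple[str, str]] = set()
    excluded_pops: set[str] = set()
    if designs:
        housing: dict[str, set[str]] = {}
        for d in designs:
            for animal_id, _, _ in d.members:
                housing.setdefault(animal_id, set()).add(d.population_id)
        for sample_id, snp_id in excluded_swab:
            for pop in housing.get(sample_id, ()):  # all containers of the animal
                excluded_edna.add((pop, snp_id))
        for animal in excluded_animals:
            excluded_pops |= housing.get(animal, set())

    return MismatchResult(
        mismatches=mismatches,
        excluded_swab_calls=excluded_swab,
        excluded_edna_calls=excluded_edna,
        excluded_animals=excluded_animals,
        excluded_populations=excluded_pops,
    )


def exclude_outliers(
    signals: pd.DataFrame,
    centroids: pd.DataFrame,
    expected: Mapping[str, str],
    k: float = 3.0,
    c: float = 1.4826,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Robust within-cluster outlier exclusion at median + k x MAD.

    For every (SNP, genotype) cluster, Euclidean distances d_i to the assigned
    centroid are screened against ``median(d) + k * MAD(d)`` with
    ``MAD(d) = c * median(|d_i - median(d)|)`` (c = 1.4826 makes MAD consistent
    for the normal SD).  Points with d_i >= threshold are outliers.

    Degenerate branches:

    * cluster of size 1 — nothing excluded, a warning is issued;
    * MAD = 0 (at least half the distances tie at the median) — the literal
      ">=" rule would void the whole tied cluster, so only points with
      d strictly greater than the median are excluded, with a warning.

    Returns (retained, outliers); ``outliers`` carries the per-cluster
    threshold used.
    """
    df = signals.copy()
    df["genotype"] = df["sample_id"].map(expected)
    df = df[df["genotype"].notna()]
    lut = _centroid_lookup(centroids)

    keep_mask = pd.Series(True, index=df.index)
    out_rows = []
    for (snp_id, genotype), cls in df.groupby(["snp_id", "genotype"], sort=True):
        cf, ch = lut[(snp_id, genotype)]
        d = np.hypot(cls["fam_mean"].to_numpy() - cf, cls["hex_mean"].to_numpy() - ch)
        if len(d) < 2:
            warnings.warn(
                f"cluster ({snp_id}, {genotype}) has a single point; "
                "MAD undefined, no exclusion",
                stacklevel=2,
            )
            continue
        med = float(np.median(d))
        mad = float(c * np.median(np.abs(d - med)))
        threshold = med + k * mad
        if mad == 0.0:
            mask = d > med
            if mask.any():
                warnings.warn(
                    f"cluster ({snp_id}, {genotype}) has zero MAD; excluding "
                    "only points strictly above the median distance",
                    stacklevel=2,
                )
        else:
            mask = d >= threshold
        for idx, dist, is_out in zip(cls.index, d, mask):
            if is_out:
                keep_mask.loc[idx] = False
                out_rows.append(
                    dict(
                        snp_id=snp_id,
                        sample_id=df.loc[idx, "sample_id"],
                        assigned_genotype=genotype,
                        fam=df.loc[idx, "fam_mean"],
                        hex=df.loc[idx, "hex_mean"],
                        genotype_fam=cf,
                        genotype_hex=ch,
                        dist_to_genotype=float(dist),
                        threshold=float(threshold),
                    )
                )
    outliers = pd.DataFrame(
        out_rows,
        columns=[
            "snp_id", "sample_id", "assigned_genotype", "fam", "hex",
            "genotype_fam", "genotype_hex", "dist_to_genotype", "threshold",
        ],
    )
    retained = df.loc[keep_mask[keep_mask].index].drop(columns="genotype")
    return retained, outliers


def _angle_deg(fam: float, hex_: float) -> float:
    if fam == 0.0 and hex_ == 0.0:
        raise CalibrationError("centroid at the origin has no angle")
    return math.degrees(math.atan2(hex_, fam))


def centroid_angles(centroids: pd.DataFrame) -> dict[str, SnpCalibration]:
    """Angles of the final genotype centroids, packaged per SNP.

    The angle is measured from the origin of the (FAM, HEX) plane, 0 deg
    along the FAM axis and 90 deg along the HEX axis.  The ordering
    alpha_b < alpha_ab < alpha_a is enforced; a violating SNP is unusable
    and raises :class:`CalibrationError`.
    """
    cals: dict[str, SnpCalibration] = {}
    for snp_id, grp in centroids.groupby("snp_id", sort=True):
        by_g = {r.genotype: r for r in grp.itertuples()}
        missing = [g for g in GENOTYPES if g not in by_g]
        if missing:
            raise CalibrationError(f"SNP {snp_id}: missing centroid(s) for {missing}")
        cal = SnpCalibration(
            snp_id=str(snp_id),
            centroid_a=(by_g["A"].fam, by_g["A"].hex),
            centroid_ab=(by_g["AB"].fam, by_g["AB"].hex),
            centroid_b=(by_g["B"].fam, by_g["B"].hex),
            alpha_a=_angle_deg(by_g["A"].fam, by_g["A"].hex),
            alpha_ab=_angle_deg(by_g["AB"].fam, by_g["AB"].hex),
            alpha_b=_angle_deg(by_g["B"].fam, by_g["B"].hex),
            n_points_a=int(getattr(by_g["A"], "n_points", 0)),
            n_points_ab=int(getattr(by_g["AB"], "n_points", 0)),
            n_points_b=int(getattr(by_g["B"], "n_points", 0)),
        )
        cal.validate()
        cals[str(snp_id)] = cal
    return cals


@dataclass
class CalibrationResult:
    """Everything the calibration step produces."""

    calibrations: dict[str, SnpCalibration]
    raw_centroids: pd.DataFrame
    final_centroids: pd.DataFrame
    mismatch: MismatchResult
    outliers: pd.DataFrame
    retained_signals: pd.DataFrame


def calibrate_panel(
    swab_signals: pd.DataFrame,
    expected: Mapping[str, str],
    designs: list[PopulationDesign] | None = None,
    config: QcConfig | None = None,
) -> CalibrationResult:
    """Full calibration pipeline on averaged swab signals.

    Steps: raw median centroids -> nearest-centroid mismatch flagging (with
    eDNA exclusion propagation) -> MAD outlier exclusion on the cleaned
    clusters -> centroid recomputation -> angle extraction.  Mismatch
    flagging deliberately uses the pre-exclusion centroids; the outlier
    screen then runs on the mismatch-cleaned set, so the two exclusion
    mechanisms are accounted separately.
    """
    config = config or QcConfig()
    raw_centroids = compute_centroids(swab_signals, expected)
    mm = flag_mismatches(swab_signals, expected, raw_centroids, designs)

    cleaned = swab_signals[
        ~swab_signals.apply(
            lambda r: (r["sample_id"], r["snp_id"]) in mm.excluded_swab_calls
            or r["sample_id"] in mm.excluded_animals,
            axis=1,
        )
    ]
    retained, outliers = exclude_outliers(
        cleaned,
        raw_centroids,
        expected,
        k=config.mad_multiplier,
        c=config.mad_scale_constant,
    )
    final_centroids = compute_centroids(retained, expected)
    calibrations = centroid_angles(final_centroids)
    return CalibrationResult(
        calibrations=calibrations,
        raw_centroids=raw_centroids,
        final_centroids=final_centroids,
        mismatch=mm,
        outliers=outliers,
        retained_signals=retained,
    )
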
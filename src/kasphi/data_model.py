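"""Domain types and tabular I/O for KASP fluorescence and mesocosm design data.

KASP (Kompetitive Allele-Specific PCR) genotypes biallelic SNPs from end-point
fluorescence in two channels: HEX reports the *Triturus ivanbureschi*-diagnostic
allele (genotype class ``A``), FAM the *T. macedonicus*-diagnostic allele
(class ``B``).  A well's raw (FAM, HEX) reading, together with sample / SNP /
replicate / read-cycle labels, is the atomic record of the whole pipeline.

Tables are plain delimiter-separated text with a header.  The canonical column
names below can be remapped at read time, since plate-reader exports differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DATASET_LABELS",
    "GENOTYPES",
    "GENOTYPE_HI",
    "FLUOR_COLUMNS",
    "DESIGN_COLUMNS",
    "REGIMES",
    "TableFormatError",
    "DesignError",
    "CalibrationError",
    "FluorescenceReading",
    "SnpCalibration",
    "PopulationDesign",
    "QcConfig",
    "read_fluorescence_table",
    "write_fluorescence_table",
    "read_design_table",
    "write_design_table",
    "designs_from_frame",
    "edna_sample_id",
    "split_edna_sample_id",
    "CALIBRATION_COLUMNS",
    "write_calibration_table",
    "read_calibration_table",
]

#: Valid values of the ``dataset`` column.
DATASET_LABELS = (
    "swab",
    "edna",
    "ntc",
    "lab_negative",
    "field_negative",
    "positive",
)

#: Genotype classes: A = T. ivanbureschi homozygote, AB = F1 hybrid,
#: B = T. macedonicus homozygote.
GENOTYPES = ("A", "AB", "B")

#: Hybrid-index contribution of each genotype class (proportion of
#: T. macedonicus alleles).
GENOTYPE_HI = {"A": 0.0, "AB": 0.5, "B": 1.0}

#: The two eDNA sampling regimes (30 L container = low, 6 L = high).
REGIMES = ("low_conc", "high_conc")

#: Canonical fluorescence-table columns.
FLUOR_COLUMNS = (
    "sample_id",
    "snp_id",
    "fam",
    "hex",
    "replicate",
    "read_cycle",
    "dataset",
)

#: Canonical design-table columns (one row per housed animal).
DESIGN_COLUMNS = (
    "population_id",
    "animal_id",
    "expected_genotype",
    "body_mass_g",
    "water_volume_l",
    "regime",
    "profile",
)


class TableFormatError(ValueError):
    """A tabular input violates the expected schema or value constraints."""


class DesignError(ValueError):
    """A design table is internally inconsistent."""


class CalibrationError(ValueError):
    """A per-SNP calibration is unusable (e.g. centroid-angle ordering broken)."""


@dataclass(frozen=True)
class FluorescenceReading:
    """One PCR well: raw FAM/HEX intensities plus identifying labels."""

    sample_id: str
    snp_id: str
    fam: float
    hex: float
    replicate: int
    read_cycle: int
    dataset: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.fam) and self.fam >= 0):
            raise ValueError(f"fam must be finite and >= 0, got {self.fam!r}")
        if not (np.isfinite(self.hex) and self.hex >= 0):
            raise ValueError(f"hex must be finite and >= 0, got {self.hex!r}")
        if self.dataset not in DATASET_LABELS:
            raise ValueError(f"unknown dataset label {self.dataset!r}")


@dataclass
class SnpCalibration:
    """Per-SNP genotype centroids and their angles from the origin.

    Angles are measured in the (FAM, HEX) plane from the origin, in degrees,
    with 0° along the FAM axis and 90° along the HEX axis.  A valid
    calibration satisfies ``alpha_b < alpha_ab < alpha_a`` (the HEX-reported
    allele A sits near 90°, the FAM-reported allele B near 0°).
    """

    snp_id: str
    centroid_a: tuple[float, float]
    centroid_ab: tuple[float, float]
    centroid_b: tuple[float, float]
    alpha_a: float
    alpha_ab: float
    alpha_b: float
    n_points_a: int = 0
    n_points_ab: int = 0
    n_points_b: int = 0

    def validate(self) -> None:
        if not (self.alpha_b < self.alpha_ab < self.alpha_a):
            raise CalibrationError(
                f"SNP {self.snp_id}: centroid-angle ordering violated "
                f"(alpha_b={self.alpha_b:.3f}, alpha_ab={self.alpha_ab:.3f}, "
                f"alpha_a={self.alpha_a:.3f}); SNP unusable"
            )

    def centroid(self, genotype: str) -> tuple[float, float]:
        return {"A": self.centroid_a, "AB": self.centroid_ab, "B": self.centroid_b}[genotype]

    def alpha(self, genotype: str) -> float:
        return {"A": self.alpha_a, "AB": self.alpha_ab, "B": self.alpha_b}[genotype]


@dataclass
class PopulationDesign:
    """One mesocosm container: its members, volume, regime and expected HI."""

    population_id: str
    members: list[tuple[str, str, float]]  # (animal_id, expected_genotype, body_mass_g)
    water_volume_l: float
    regime: str
    profile: float

    def recomputed_profile(self) -> float:
        return float(np.mean([GENOTYPE_HI[g] for _, g, _ in self.members]))


@dataclass
class QcConfig:
    """Thresholds and reproducibility knobs for QC, calibration and statistics.

    The defaults are the study's analysis settings: a low-fluorescence
    triangle with vertices (0,0), (2,0), (0,2); outliers at
    median + 3 x MAD with the normal-consistency constant 1.4826; SNP
    retention when the bootstrap CI of the median bias lies within
    +/-0.05 HI units (B = 2000 resamples); 95% limits of agreement at
    z = 1.96; 5000 permutations for the ANCOVA.
    """

    triangle_vertices: tuple[tuple[float, float], ...] = ((0.0, 0.0), (2.0, 0.0), (0.0, 2.0))
    mad_multiplier: float = 3.0
    mad_scale_constant: float = 1.4826
    bias_tolerance: float = 0.05
    bootstrap_reps: int = 2000
    loa_z: float = 1.96
    permutations: int = 5000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mad_multiplier", "mad_scale_constant", "bias_tolerance",
                     "loa_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bootstrap_reps <= 0 or self.permutations <= 0:
            raise ValueError("bootstrap_reps and permutations must be strictly positive")
        if len(self.triangle_vertices) != 3:
            raise ValueError("triangle_vertices must contain exactly three points")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "QcConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        bad = set(mapping) - known
        if bad:
            raise KeyError(f"unknown config key(s): {sorted(bad)}")
        kwargs = dict(mapping)
        if "triangle_vertices" in kwargs:
            kwargs["triangle_vertices"] = tuple(
                (float(x), float(y)) for x, y in kwargs["triangle_vertices"]
            )
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Fluorescence table I/O
# ---------------------------------------------------------------------------

def read_fluorescence_table(
    path,
    delimiter: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a fluorescence table into a validated DataFrame.

    Parameters
    ----------
    path
        Delimiter-separated text file with a header row.
    delimiter
        Field separator (``","`` or ``"\\t"``).
    column_map
        Optional mapping from canonical column names (see
        :data:`FLUOR_COLUMNS`) to the names used in the file.

    Returns
    -------
    DataFrame with the canonical columns, one row per PCR reading.

    Raises
    ------
    TableFormatError
        If a required column is missing, an intensity is non-numeric or
        negative, a dataset label is unknown, or the
        (sample_id, snp_id, replicate, read_cycle) key is duplicated.
    """
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in FLUOR_COLUMNS}
    missing = [column_map.get(c, c) for c in FLUOR_COLUMNS if column_map.get(c, c) not in raw.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {missing}")
    df = raw.rename(columns=rename)[list(FLUOR_COLUMNS)].copy()

    for col in ("fam", "hex"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise TableFormatError(
                f"non-numeric {col} value {df[col].iloc[row]!r} in row {row + 1}"
            )
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise TableFormatError(f"missing {col} value in row {row + 1}")
        if (vals < 0).any() or ~np.isfinite(vals).all():
            row = int(np.flatnonzero(((vals < 0) | ~np.isfinite(vals)).to_numpy())[0])
            raise TableFormatError(
                f"negative or non-finite {col} value {vals.iloc[row]!r} in row {row + 1}"
            )
        df[col] = vals.astype(float)

    for col in ("replicate", "read_cycle"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(np.flatnonzero(vals.isna().to_numpy())[0])
            raise TableFormatError(f"unparsable {col} value in row {row + 1}")
        df[col] = vals.astype(int)

    unknown = ~df["dataset"].isin(DATASET_LABELS)
    if unknown.any():
        bad_labels = sorted(df.loc[unknown, "dataset"].unique())
        raise TableFormatError(f"unknown dataset label(s): {bad_labels}")

    key = ["sample_id", "snp_id", "replicate", "read_cycle"]
    if df.duplicated(key).any():
        dup = df[df.duplicated(key, keep=False)].iloc[0]
        raise TableFormatError(
            "duplicate reading key "
            f"({dup['sample_id']}, {dup['snp_id']}, rep {dup['replicate']}, "
            f"cycle {dup['read_cycle']})"
        )
    return df


def write_fluorescence_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df[list(FLUOR_COLUMNS)].to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# Design table I/O
# ---------------------------------------------------------------------------

def read_design_table(path, delimiter: str = ",") -> pd.DataFrame:
    """Read a design table (one row per housed animal) and validate it.

    The population profile (expected HI) is recomputed from the members'
    genotype contributions and cross-checked against the stated ``profile``
    column; a mismatch raises :class:`DesignError` naming the population.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"population_id": str, "animal_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required design column(s): {missing}")
    bad_geno = ~df["expected_genotype"].isin(GENOTYPES)
    if bad_geno.any():
        raise TableFormatError(
            f"unknown genotype label(s): {sorted(df.loc[bad_geno, 'expected_genotype'].unique())}"
        )
    _check_profiles(df)
    return df


def _check_profiles(df: pd.DataFrame) -> None:
    contrib = df["expected_genotype"].map(GENOTYPE_HI)
    recomputed = contrib.groupby(df["population_id"]).mean()
    stated = df.groupby("population_id")["profile"].first().astype(float)
    off = (recomputed - stated).abs() > 1e-9
    if off.any():
        bad = sorted(off[off].index)
        raise DesignError(
            f"stated profile disagrees with member genotypes for population(s): {bad}"
        )


def write_design_table(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    df[list(DESIGN_COLUMNS)].to_csv(path, sep=delimiter, index=False)


def designs_from_frame(df: pd.DataFrame) -> list[PopulationDesign]:
    """Group a validated design frame into :class:`PopulationDesign` objects.

    Each population is sampled once per regime, so one object is produced
    per (population_id, regime) pair — the unit that yields one eDNA sample.
    """
    out: list[PopulationDesign] = []
    for (pop_id, regime), grp in df.groupby(["population_id", "regime"], sort=True):
        members = [
            (str(r.animal_id), str(r.expected_genotype), float(r.body_mass_g))
            for r in grp.itertuples()
        ]
        out.append(
            PopulationDesign(
                population_id=str(pop_id),
                members=members,
                water_volume_l=float(grp["water_volume_l"].iloc[0]),
                regime=str(regime),
                profile=float(grp["profile"].iloc[0]),
            )
        )
    return out


#: Canonical calibration-table columns.
CALIBRATION_COLUMNS = (
    "snp_id",
    "alpha_a", "alpha_ab", "alpha_b",
    "centroid_a_fam", "centroid_a_hex",
    "centroid_ab_fam", "centroid_ab_hex",
    "centroid_b_fam", "centroid_b_hex",
    "n_points_a", "n_points_ab", "n_points_b",
)


def write_calibration_table(
    calibrations: Mapping[str, SnpCalibration], path, delimiter: str = ","
) -> None:
    rows = []
    for snp_id in sorted(calibrations):
        c = calibrations[snp_id]
        rows.append(
            dict(
                snp_id=snp_id,
                alpha_a=c.alpha_a, alpha_ab=c.alpha_ab, alpha_b=c.alpha_b,
                centroid_a_fam=c.centroid_a[0], centroid_a_hex=c.centroid_a[1],
                centroid_ab_fam=c.centroid_ab[0], centroid_ab_hex=c.centroid_ab[1],
                centroid_b_fam=c.centroid_b[0], centroid_b_hex=c.centroid_b[1],
                n_points_a=c.n_points_a, n_points_ab=c.n_points_ab,
                n_points_b=c.n_points_b,
            )
        )
    pd.DataFrame(rows, columns=list(CALIBRATION_COLUMNS)).to_csv(
        path, sep=delimiter, index=False
    )


def read_calibration_table(path, delimiter: str = ",") -> dict[str, SnpCalibration]:
    df = pd.read_csv(path, sep=delimiter)
    missing = [c for c in CALIBRATION_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing required calibration column(s): {missing}")
    out: dict[str, SnpCalibration] = {}
    for r in df.itertuples():
        cal = SnpCalibration(
            snp_id=str(r.snp_id),
            centroid_a=(float(r.centroid_a_fam), float(r.centroid_a_hex)),
            centroid_ab=(float(r.centroid_ab_fam), float(r.centroid_ab_hex)),
            centroid_b=(float(r.centroid_b_fam), float(r.centroid_b_hex)),
            alpha_a=float(r.alpha_a), alpha_ab=float(r.alpha_ab),
            alpha_b=float(r.alpha_b),
            n_points_a=int(r.n_points_a), n_points_ab=int(r.n_points_ab),
            n_points_b=int(r.n_points_b),
        )
        cal.validate()
        out[cal.snp_id] = cal
    return out


def edna_sample_id(population_id: str, regime: str) -> str:
    """Naming convention linking an eDNA water sample to its sampling event."""
    return f"{population_id}.{regime}"


def split_edna_sample_id(sample_id: str) -> tuple[str, str]:
    """Inverse of :func:`edna_sample_id`."""
    pop, _, regime = sample_id.rpartition(".")
    if not pop or regime not in REGIMES:
        raise ValueError(f"not a recognised eDNA sample id: {sample_id!r}")
    return pop, regime
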
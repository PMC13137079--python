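"""Synthetic KASP fluorescence data with the mesocosm study's structure.

The generator emulates both arms of the validation experiment:

* **Skin swabs** — one reading per animal x SNP x replicate, placed at the
  genotype's calibration angle plus angular noise, with the empirically
  observed error modes: allelic dropout (a heterozygote renders at a random
  homozygote angle), false heterozygotes (a homozygote renders at the
  heterozygote angle) and low-fluorescence failures (the point lands in the
  background-noise triangle).
* **eDNA samples** — one water sample per mesocosm population and sampling
  regime.  Individuals shed DNA unequally: per sampling event, shedding
  weights are Dirichlet-distributed over the members, the latent allele
  proportion is the weighted mean of the members' HI contributions, and each
  replicate reads that proportion through the inverse piecewise HI map plus
  regime-scaled angular noise.

Default parameters are the study's measured conditions: centroid-angle
distributions alpha_A ~ N(82.0, 1.13), alpha_AB ~ N(46.6, 6.05),
alpha_B ~ N(12.9, 1.46) degrees; allelic dropout 3.5% of heterozygote calls;
false heterozygotes 1.27% of homozygote calls; 4.5% low-signal reactions;
four PCR replicates; five genotypic profiles with 3/3/6/3/3 replicate
populations of two animals each, sampled under a low- (30 L) and a high-
(6 L) concentration regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import (
    GENOTYPE_HI,
    PopulationDesign,
    SnpCalibration,
    designs_from_frame,
    edna_sample_id,
)
from .hi import hi_to_angle

__all__ = [
    "SimConfig",
    "SimulatedExperiment",
    "simulate_snp_panel",
    "simulate_swabs",
    "simulate_edna",
    "simulate_experiment",
    "STUDY_PROFILES",
]

#: Genotype pairs per profile and the study's replicate-population counts.
STUDY_PROFILES: dict[float, tuple[tuple[str, str], int]] = {
    0.0: (("A", "A"), 3),
    0.25: (("A", "AB"), 3),
    0.5: (("AB", "AB"), 6),
    0.75: (("B", "AB"), 3),
    1.0: (("B", "B"), 3),
}

#: Container volume (litres) per sampling regime.
REGIME_VOLUMES = {"low_conc": 30.0, "high_conc": 6.0}


@dataclass
class SimConfig:
    """Generator parameters; the defaults reproduce the study conditions."""

    n_snps: int = 9
    # Per-SNP true centroid-angle distributions (degrees).
    alpha_a_mean: float = 82.0
    alpha_a_sd: float = 1.13
    alpha_ab_mean: float = 46.6
    alpha_ab_sd: float = 6.05
    alpha_b_mean: float = 12.9
    alpha_b_sd: float = 1.46
    # Fluorescence magnitude: radius is lognormal around ``radius_median``.
    radius_median: float = 3.0
    radius_log_sd: float = 0.15
    # Angular noise (degrees): swabs carry more template and are cleaner.
    swab_angle_sd: float = 2.0
    edna_angle_sd: float = 4.0
    #: Regime noise multipliers; low concentration is noisier (the study saw
    #: ~35% higher deviation variance at low concentration, i.e. SD x ~1.25).
    regime_noise_scale: Mapping[str, float] = field(
        default_factory=lambda: {"low_conc": 1.25, "high_conc": 1.0}
    )
    # Error modes (probabilities per call / per reaction).
    dropout_rate: float = 0.035
    false_het_rate: float = 0.0127
    low_signal_rate: float = 0.045
    #: Dirichlet concentration of per-individual shedding weights; smaller
    #: values mean more unequal contributions to the eDNA pool.
    shedding_concentration: float = 5.0
    replicates: int = 4
    read_cycle: int = 48
    #: profile -> number of replicate populations (study layout by default).
    profile_replicates: Mapping[float, int] = field(
        default_factory=lambda: {p: n for p, (_, n) in STUDY_PROFILES.items()}
    )
    # Control wells per SNP.
    n_ntc: int = 4
    n_lab_negative: int = 4
    n_field_negatives: int = 2

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "false_het_rate", "low_signal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


@dataclass
class SimulatedExperiment:
    """One synthetic run: raw tables, ground truth and the true panel."""

    fluorescence: pd.DataFrame
    design: pd.DataFrame
    truth: pd.DataFrame
    panel: dict[str, SnpCalibration]
    animals: list[tuple[str, str]]  # (animal_id, true genotype)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_snp_panel(config: SimConfig, seed=0) -> dict[str, SnpCalibration]:
    """Draw per-SNP true calibrations (centroid angles and positions).

    Angles are drawn from the configured normal distributions and redrawn for
    a SNP whenever the ordering alpha_b < alpha_ab < alpha_a would be
    violated, so every simulated SNP is usable.  Centroids sit at
    ``radius_median`` along their angle.  Deterministic for a fixed seed.
    """
    rng = _rng(seed)
    panel: dict[str, SnpCalibration] = {}
    for i in range(config.n_snps):
        snp_id = f"snp{i + 1:02d}"
        while True:
            a = rng.normal(config.alpha_a_mean, config.alpha_a_sd)
            ab = rng.normal(config.alpha_ab_mean, config.alpha_ab_sd)
            b = rng.normal(config.alpha_b_mean, config.alpha_b_sd)
            if 0.0 <= b < ab < a <= 90.0:
                break
        r = config.radius_median

        def _c(angle: float) -> tuple[float, float]:
            t = np.radians(angle)
            return (r * float(np.cos(t)), r * float(np.sin(t)))

        panel[snp_id] = SnpCalibration(
            snp_id=snp_id,
            centroid_a=_c(a), centroid_ab=_c(ab), centroid_b=_c(b),
            alpha_a=float(a), alpha_ab=float(ab), alpha_b=float(b),
        )
    return panel


def _triangle_point(rng: np.random.Generator) -> tuple[float, float]:
    """Uniform point in the default low-fluorescence triangle (0,0)-(2,0)-(0,2)."""
    u, v = rng.random(2)
    if u + v > 1.0:
        u, v = 1.0 - u, 1.0 - v
    return 2.0 * u, 2.0 * v


def _emit(
    rows: list,
    sample_id: str,
    snp_id: str,
    dataset: str,
    angle: float,
    config: SimConfig,
    rng: np.random.Generator,
    angle_sd: float,
) -> None:
    """Append ``config.replicates`` readings around ``angle`` for one reaction set."""
    for rep in range(1, config.replicates + 1):
        if rng.random() < config.low_signal_rate:
            fam, hx = _triangle_point(rng)
        else:
            a = angle if angle_sd == 0.0 else rng.normal(angle, angle_sd)
            a = min(max(a, 0.0), 90.0)
            r = config.radius_median * float(
                np.exp(rng.normal(0.0, config.radius_log_sd))
            ) if config.radius_log_sd > 0 else config.radius_median
            t = np.radians(a)
            fam, hx = r * float(np.cos(t)), r * float(np.sin(t))
        rows.append(
            dict(
                sample_id=sample_id, snp_id=snp_id, fam=fam, hex=hx,
                replicate=rep, read_cycle=config.read_cycle, dataset=dataset,
            )
        )


def simulate_swabs(
    animals: Sequence[tuple[str, str]],
    panel: Mapping[str, SnpCalibration],
    config: SimConfig,
    seed=0,
) -> pd.DataFrame:
    """Simulate the skin-swab validation arm.

    Error modes act at the call (animal x SNP) level, as they do in the wet
    lab: allelic dropout renders a heterozygote at a random homozygote angle
    across all its replicates, a false heterozygote renders a homozygote at
    the heterozygote angle.  Low-signal failures strike individual reactions.
    """
    rng = _rng(seed)
    rows: list = []
    for animal_id, genotype in animals:
        for snp_id in sorted(panel):
            cal = panel[snp_id]
            render = genotype
            if genotype == "AB" and rng.random() < config.dropout_rate:
                render = "A" if rng.random() < 0.5 else "B"
            elif genotype in ("A", "B") and rng.random() < config.false_het_rate:
                render = "AB"
            _emit(rows, animal_id, snp_id, "swab", cal.alpha(render),
                  config, rng, config.swab_angle_sd)
    return pd.DataFrame(rows)


def simulate_edna(
    designs: Sequence[PopulationDesign],
    panel: Mapping[str, SnpCalibration],
    config: SimConfig,
    seed=0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the eDNA arm: one water sample per (population, regime).

    Per sampling event, shedding weights w ~ Dirichlet(c, ..., c) over the
    members give a latent allele proportion p = sum(w_i * hi_i); each SNP's
    reading sits at the inverse piecewise HI map of p plus regime-scaled
    angular noise.  Returns (readings, truth) where ``truth`` records the
    expected profile and the realised latent proportion per sample.
    """
    rng = _rng(seed)
    rows: list = []
    truth_rows: list = []
    for d in designs:
        sample = edna_sample_id(d.population_id, d.regime)
        conc = config.shedding_concentration
        if np.isfinite(conc):
            w = rng.dirichlet(np.full(len(d.members), conc))
        else:  # infinite concentration: exactly equal shedding
            w = np.full(len(d.members), 1.0 / len(d.members))
        his = np.array([GENOTYPE_HI[g] for _, g, _ in d.members])
        latent = float(np.dot(w, his))
        scale = dict(config.regime_noise_scale).get(d.regime, 1.0)
        sd = config.edna_angle_sd * scale
        for snp_id in sorted(panel):
            angle = hi_to_angle(latent, panel[snp_id])
            _emit(rows, sample, snp_id, "edna", angle, config, rng, sd)
        truth_rows.append(
            dict(
                sample_id=sample, population_id=d.population_id, regime=d.regime,
                profile=d.profile, latent_hi=latent,
            )
        )
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def _build_design(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Lay out populations and animals for the configured profile replicates."""
    rows = []
    pop_i = 0
    animal_i = 0
    for profile in sorted(config.profile_replicates):
        genotypes, _ = STUDY_PROFILES.get(profile, (None, None))
        if genotypes is None:
            raise ValueError(f"no genotype pair defined for profile {profile}")
        for _ in range(config.profile_replicates[profile]):
            pop_i += 1
            pop_id = f"P{pop_i:03d}"
            members = []
            for g in genotypes:
                animal_i += 1
                mass = float(np.clip(rng.normal(10.0, 1.5), 5.0, None))
                members.append((f"M{animal_i:03d}", g, mass))
            for regime, volume in REGIME_VOLUMES.items():
                for animal_id, g, mass in members:
                    rows.append(
                        dict(
                            population_id=pop_id, animal_id=animal_id,
                            expected_genotype=g, body_mass_g=mass,
                            water_volume_l=volume, regime=regime,
                            profile=profile,
                        )
                    )
    return pd.DataFrame(rows)


def _simulate_controls(
    panel: Mapping[str, SnpCalibration],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """NTC / lab-negative / field-negative / positive control wells.

    Negative wells read background fluorescence near the origin (inside the
    low-fluorescence triangle); positives read the pure-genotype angles.
    """
    rows: list = []
    for snp_id in sorted(panel):
        cal = panel[snp_id]
        for i in range(config.n_ntc):
            fam, hx = (v * 0.3 for v in _triangle_point(rng))
            rows.append(dict(sample_id=f"NTC{i + 1:02d}", snp_id=snp_id,
                             fam=fam, hex=hx, replicate=1,
                             read_cycle=config.read_cycle, dataset="ntc"))
        for i in range(config.n_lab_negative):
            fam, hx = (v * 0.3 for v in _triangle_point(rng))
            rows.append(dict(sample_id=f"LNEG{i + 1:02d}", snp_id=snp_id,
                             fam=fam, hex=hx, replicate=1,
                             read_cycle=config.read_cycle, dataset="lab_negative"))
        for species, genotype in (("iv", "A"), ("mac", "B")):
            _emit(rows, f"POS_{species}", snp_id, "positive",
                  cal.alpha(genotype), config, rng, config.swab_angle_sd)
    for i in range(config.n_field_negatives):
        for snp_id in sorted(panel):
            for rep in range(1, config.replicates + 1):
                fam, hx = (v * 0.3 for v in _triangle_point(rng))
                rows.append(dict(sample_id=f"FNEG{i + 1:02d}", snp_id=snp_id,
                                 fam=fam, hex=hx, replicate=rep,
                                 read_cycle=config.read_cycle,
                                 dataset="field_negative"))
    return pd.DataFrame(rows)


def simulate_experiment(config: SimConfig | None = None, seed=0) -> SimulatedExperiment:
    """Simulate the full study: swabs, eDNA, controls, design and truth.

    The default layout is the study's: 5 genotypic profiles with 3/3/6/3/3
    replicate populations of two animals each (36 animals: 9 A, 18 AB, 9 B),
    each population sampled under both regimes (36 eDNA samples), 9 SNPs,
    4 PCR replicates -> 1296 swab and 1296 eDNA reactions, plus NTC,
    lab-negative, field-negative and positive control wells.
    Bit-reproducible for a fixed seed.
    """
    config = config or SimConfig()
    rng = _rng(seed)
    panel = simulate_snp_panel(config, rng)
    design = _build_design(config, rng)
    designs = designs_from_frame(design)
    animal_rows = design.drop_duplicates("animal_id")
    animals = [
        (str(r.animal_id), str(r.expected_genotype)) for r in animal_rows.itertuples()
    ]
    swabs = simulate_swabs(animals, panel, config, rng)
    edna, truth = simulate_edna(designs, panel, config, rng)
    controls = _simulate_controls(panel, config, rng)
    fluorescence = pd.concat([swabs, edna, controls], ignore_index=True)
    return SimulatedExperiment(
        fluorescence=fluorescence, design=design, truth=truth,
        panel=panel, animals=animals,
    )
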
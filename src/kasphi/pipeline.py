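"""End-to-end orchestration: QC -> calibration -> HI estimation -> validation.

These functions are the library-level equivalents of the CLI subcommands and
operate on in-memory DataFrames; the CLI adds file I/O and logging on top.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import calibrate as _calibrate
from . import hi as _hi
from . import qc as _qc
from . import stats as _stats
from .data_model import (
    GENOTYPE_HI,
    PopulationDesign,
    QcConfig,
    SnpCalibration,
    designs_from_frame,
    split_edna_sample_id,
)

__all__ = [
    "QcResult",
    "run_qc",
    "run_calibration",
    "EstimateResult",
    "run_estimation",
    "run_validation",
]


@dataclass
class QcResult:
    """Outcome of the shared QC front end."""

    selected_cycle: int
    cycle_selection: _qc.CycleSelection | None
    retained: pd.DataFrame
    excluded: pd.DataFrame
    averaged: pd.DataFrame
    dropped_groups: pd.DataFrame
    exclusion_counts: pd.DataFrame
    field_control_report: pd.DataFrame


def run_qc(fluorescence: pd.DataFrame, config: QcConfig | None = None) -> QcResult:
    """Select the read cycle, filter low signal, screen controls, average.

    With multiple read cycles present, the cycle is chosen by the NTC /
    negative-control dimer rule; a table already reduced to one cycle is
    taken as pre-selected.
    """
    config = config or QcConfig()
    cycles = sorted(fluorescence["read_cycle"].unique())
    selection = None
    if len(cycles) > 1:
        selection = _qc.select_read_cycle(fluorescence, cycles, config.triangle_vertices)
        cycle = selection.cycle
    else:
        cycle = int(cycles[0])
    at_cycle = fluorescence[fluorescence["read_cycle"] == cycle]

    retained, excluded = _qc.filter_low_fluorescence(at_cycle, config.triangle_vertices)
    counts = _qc.exclusion_counts(excluded, at_cycle)
    field_report = _qc.screen_field_controls(at_cycle, config.triangle_vertices)
    analysed = retained[retained["dataset"].isin(["swab", "edna"])]
    excluded_analysed = excluded[excluded["dataset"].isin(["swab", "edna"])]
    averaged, dropped = _qc.average_replicates(analysed, excluded_analysed)
    return QcResult(
        selected_cycle=cycle,
        cycle_selection=selection,
        retained=retained,
        excluded=excluded,
        averaged=averaged,
        dropped_groups=dropped,
        exclusion_counts=counts,
        field_control_report=field_report,
    )


def _expected_map(design: pd.DataFrame) -> dict[str, str]:
    return dict(
        design.drop_duplicates("animal_id")[["animal_id", "expected_genotype"]]
        .itertuples(index=False, name=None)
    )


def run_calibration(
    fluorescence: pd.DataFrame,
    design: pd.DataFrame,
    config: QcConfig | None = None,
) -> tuple[_calibrate.CalibrationResult, QcResult]:
    """QC the raw table, then calibrate the SNP panel from the swab arm."""
    config = config or QcConfig()
    qc_res = run_qc(fluorescence, config)
    swab_avg = qc_res.averaged[qc_res.averaged["dataset"] == "swab"]
    cal = _calibrate.calibrate_panel(
        swab_avg, _expected_map(design), designs_from_frame(design), config
    )
    return cal, qc_res


@dataclass
class EstimateResult:
    """Per sample-SNP HI estimates plus per-eDNA-sample aggregates."""

    per_snp: pd.DataFrame
    population: pd.DataFrame
    verified: dict[tuple[str, str], str]


def run_estimation(
    fluorescence: pd.DataFrame,
    calibrations: Mapping[str, SnpCalibration],
    design: pd.DataFrame,
    config: QcConfig | None = None,
    mismatch: _calibrate.MismatchResult | None = None,
    qc_res: QcResult | None = None,
) -> EstimateResult:
    """Map averaged signals to HI and aggregate eDNA samples.

    Exclusion propagation from genotype verification is honoured when a
    ``mismatch`` result is supplied: mismatched swab calls, their linked
    eDNA (population, SNP) calls, fully-excluded animals and their
    containers all drop out before aggregation.
    """
    config = config or QcConfig()
    qc_res = qc_res or run_qc(fluorescence, config)
    expected = _expected_map(design)
    designs = designs_from_frame(design)
    avg = qc_res.averaged

    unknown = set(avg["snp_id"]) - set(calibrations)
    if unknown:
        raise KeyError(f"SNP(s) present in data but not calibrated: {sorted(unknown)}")

    mm = mismatch
    excluded_swab = mm.excluded_swab_calls if mm else set()
    excluded_edna = mm.excluded_edna_calls if mm else set()
    excluded_animals = mm.excluded_animals if mm else set()
    excluded_pops = mm.excluded_populations if mm else set()

    # Verified genotypes: swab calls that survived QC and verification.
    verified: dict[tuple[str, str], str] = {}
    swab_avg = avg[avg["dataset"] == "swab"]
    for r in swab_avg.itertuples():
        key = (r.sample_id, r.snp_id)
        if r.sample_id in excluded_animals or key in excluded_swab:
            continue
        geno = expected.get(r.sample_id)
        if geno is not None:
            verified[key] = geno

    snp_ids = sorted(calibrations)
    hi_exp_pop: dict[tuple[str, str], dict[str, float | None]] = {}
    prof_by_pop: dict[str, float] = {}
    for d in designs:
        hi_exp_pop[(d.population_id, d.regime)] = _hi.expected_hi(d, verified, snp_ids)
        prof_by_pop[d.population_id] = d.profile

    rows = []
    for r in avg.itertuples():
        cal = calibrations[r.snp_id]
        alpha = _hi.angle_of(r.fam_mean, r.hex_mean)
        hi_obs = _hi.angle_to_hi(alpha, cal)
        if r.dataset == "swab":
            if r.sample_id in excluded_animals or (r.sample_id, r.snp_id) in excluded_swab:
                continue
            geno = expected.get(r.sample_id)
            if geno is None:
                continue
            hi_exp = GENOTYPE_HI[geno]
            rows.append(
                dict(sample_id=r.sample_id, snp_id=r.snp_id, dataset="swab",
                     population_id=None, regime=None, profile=None,
                     alpha=alpha, hi_obs=hi_obs, hi_exp=hi_exp,
                     deviation=hi_obs - hi_exp, n_replicates=r.n_replicates)
            )
        elif r.dataset == "edna":
            pop, regime = split_edna_sample_id(r.sample_id)
            if pop in excluded_pops or (pop, r.snp_id) in excluded_edna:
                continue
            hi_exp = hi_exp_pop.get((pop, regime), {}).get(r.snp_id)
            if hi_exp is None:
                continue  # unavailable: some member unverified at this SNP
            rows.append(
                dict(sample_id=r.sample_id, snp_id=r.snp_id, dataset="edna",
                     population_id=pop, regime=regime,
                     profile=prof_by_pop.get(pop),
                     alpha=alpha, hi_obs=hi_obs, hi_exp=hi_exp,
                     deviation=hi_obs - hi_exp, n_replicates=r.n_replicates)
            )
    per_snp = pd.DataFrame(
        rows,
        columns=["sample_id", "snp_id", "dataset", "population_id", "regime",
                 "profile", "alpha", "hi_obs", "hi_exp", "deviation",
                 "n_replicates"],
    )

    pop_rows = []
    edna = per_snp[per_snp["dataset"] == "edna"]
    for sample_id, grp in edna.groupby("sample_id", sort=True):
        hi_obs, n_snps = _hi.population_hi(grp["hi_obs"].tolist())
        hi_exp = float(grp["hi_exp"].mean())
        pop_rows.append(
            dict(sample_id=sample_id,
                 population_id=grp["population_id"].iloc[0],
                 regime=grp["regime"].iloc[0],
                 profile=grp["profile"].iloc[0],
                 hi_obs=hi_obs, hi_exp=hi_exp,
                 deviation=hi_obs - hi_exp, n_snps=n_snps)
        )
    population = pd.DataFrame(
        pop_rows,
        columns=["sample_id", "population_id", "regime", "profile",
                 "hi_obs", "hi_exp", "deviation", "n_snps"],
    )
    return EstimateResult(per_snp=per_snp, population=population, verified=verified)


def run_validation(
    estimates: EstimateResult,
    design: pd.DataFrame,
    config: QcConfig | None = None,
) -> dict[str, object]:
    """All validation statistics on a set of HI estimates.

    Returns a dict of result tables / dataclasses keyed by analysis name.
    Analyses whose preconditions fail (too few groups, no mixed profiles)
    yield untestable entries rather than raising.
    """
    config = config or QcConfig()
    rng = np.random.default_rng(config.rng_seed)
    out: dict[str, object] = {}

    swab = estimates.per_snp[estimates.per_snp["dataset"] == "swab"]
    devs = {
        snp: grp["deviation"].to_numpy()
        for snp, grp in swab.groupby("snp_id", sort=True)
    }
    out["snp_bias"] = _stats.snp_bias(
        devs, B=config.bootstrap_reps, tol=config.bias_tolerance, seed=rng
    )

    edna = estimates.per_snp[estimates.per_snp["dataset"] == "edna"]
    out["concordance"] = _stats.concordance(
        edna["hi_obs"], edna["hi_exp"], edna["regime"]
    )
    if edna["regime"].nunique() == 2:
        out["ancova"] = _stats.permutation_ancova(
            edna["hi_obs"], edna["hi_exp"], edna["regime"],
            n_perm=config.permutations, seed=rng,
        )
    else:
        out["ancova"] = None

    kw, wilcoxon = _stats.profile_bias_tests(edna)
    out["kruskal_wallis"] = kw
    out["profile_wilcoxon"] = wilcoxon

    fligner_frames = []
    for regime, grp in edna.groupby("regime", sort=True):
        f = _stats.variance_homogeneity(grp)
        f.insert(0, "regime", regime)
        fligner_frames.append(f)
    out["fligner"] = (
        pd.concat(fligner_frames, ignore_index=True) if fligner_frames else pd.DataFrame()
    )

    pop = estimates.population
    ba = {}
    for regime, grp in pop.groupby("regime", sort=True):
        if len(grp) >= 2:
            ba[regime] = _stats.bland_altman(grp["deviation"], z=config.loa_z)
    out["bland_altman_regime"] = ba

    wide = pop.pivot_table(index="population_id", columns="regime", values="hi_obs")
    if {"low_conc", "high_conc"} <= set(wide.columns):
        paired = (wide["low_conc"] - wide["high_conc"]).dropna()
        out["bland_altman_between"] = (
            _stats.bland_altman(paired, z=config.loa_z) if len(paired) >= 2 else None
        )
    else:
        out["bland_altman_between"] = None

    # Biomass correction: mixed-genotype profiles only.
    designs = designs_from_frame(design)
    bio_exp = {
        (d.population_id, d.regime): _hi.biomass_corrected_hi(d) for d in designs
    }
    pairs: dict[float, tuple[list[float], list[float]]] = {}
    for r in pop.itertuples():
        if r.profile not in (0.25, 0.75):
            continue
        corrected = bio_exp.get((r.population_id, r.regime))
        if corrected is None:
            continue
        unc, cor = pairs.setdefault(r.profile, ([], []))
        unc.append(abs(r.hi_obs - r.hi_exp))
        cor.append(abs(r.hi_obs - corrected))
    out["biomass_effect"] = _stats.biomass_effect_test(pairs) if pairs else None
    return out
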
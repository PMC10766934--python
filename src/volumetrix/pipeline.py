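"""End-to-end experiments: the phantom threshold study and the cohort comparison.

`run_phantom_experiment` reproduces the phantom workflow: build the digital
butterfly phantom, fill it at each target-to-background ratio, emulate the
planar and tomographic acquisitions for the three count/time replicate
settings, measure planar (Allen) volumes and run the iso-contour threshold
sweep, then compare groups by ANOVA with LSD post-hoc tests and select the
optimal threshold fraction.

`run_cohort_experiment` generates the synthetic 40-patient cohort and compares
the three measurement channels (ultrasound, planar, 25%-threshold SPECT) with
paired t-tests, correlation/regression and Bland–Altman agreement.

`reproduce_printed_numbers` re-derives every closed-form quantity of the study
from its printed inputs (dilution arithmetic, volume errors, mean errors,
formula examples) and checks them against the printed values.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, cohort_frame, generate_cohort
from .emulator import AcquisitionConfig, emulate_planar, emulate_tomo, poissonize_tomo
from .errors import InvalidParameterError
from .phantom import Arrangement, ElbowSpec, assemble_phantom, assign_activity
from .planar import (allen_volume, default_background_roi, delineate_planar_roi,
                     measure_area_and_length, planar_tb, split_merged_lobes)
from .stats import bland_altman, one_way_anova, pearson_and_slope, summarize_errors
from .tomo import (ThresholdSweepTable, default_search_region, select_optimal_threshold,
                   threshold_sweep, volume_error)

__all__ = [
    "ExperimentConfig",
    "RunManifest",
    "PhantomExperimentResult",
    "CohortExperimentResult",
    "run_phantom_experiment",
    "run_cohort_experiment",
    "reproduce_printed_numbers",
]

log = logging.getLogger("volumetrix")

TRUE_BILATERAL_VOLUME_ML = 53.0  # nominal lumen volume of the physical part
DEFAULT_FRACTIONS = (0.20, 0.25, 0.30, 0.40, 0.50, 0.60)
DEFAULT_TB_RATIOS = (200.0, 600.0, 1000.0)
DEFAULT_PLANAR_KCTS = (300.0, 500.0, 800.0)
DEFAULT_TOMO_SECONDS = (12.0, 15.0, 18.0)
DEFAULT_TARGET_CONC = 142_857.0  # Bq/mL in the lobes


@dataclass(frozen=True)
class ExperimentConfig:
    """Full configuration of both experiments (YAML-roundtrippable)."""

    seed: int = 0
    voxel_size: float = 1.0  # mm, phantom + imaging grid
    tank_volume: float = 10_122.0  # mL
    gap: float = 5.0  # mm between lobes
    anterior_depth: float = 20.0  # mm below tank surface
    target_concentration: float = DEFAULT_TARGET_CONC
    tb_ratios: tuple[float, ...] = DEFAULT_TB_RATIOS
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS
    planar_kcts: tuple[float, ...] = DEFAULT_PLANAR_KCTS
    tomo_seconds: tuple[float, ...] = DEFAULT_TOMO_SECONDS
    noisy: bool = True
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        phantom = raw.get("phantom", {})
        sweep = raw.get("sweep", {})
        acq = AcquisitionConfig(**raw.get("acquisition", {}))
        cohort = CohortConfig(**raw.get("cohort", {}))
        return cls(seed=raw.get("seed", 0),
                   voxel_size=phantom.get("voxel_size", 1.0),
                   tank_volume=phantom.get("tank_volume", 10_122.0),
                   gap=phantom.get("gap", 5.0),
                   anterior_depth=phantom.get("anterior_depth", 20.0),
                   target_concentration=sweep.get("target_concentration", DEFAULT_TARGET_CONC),
                   tb_ratios=tuple(sweep.get("tb_ratios", DEFAULT_TB_RATIOS)),
                   fractions=tuple(sweep.get("fractions", DEFAULT_FRACTIONS)),
                   planar_kcts=tuple(sweep.get("planar_kcts", DEFAULT_PLANAR_KCTS)),
                   tomo_seconds=tuple(sweep.get("tomo_seconds", DEFAULT_TOMO_SECONDS)),
                   noisy=sweep.get("noisy", True),
                   acquisition=acq, cohort=cohort)

    def config_hash(self) -> str:
        blob = json.dumps({**asdict(self)}, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    seed: int
    started: float
    version: str = __version__
    outputs: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


@dataclass
class PhantomExperimentResult:
    planar_table: pd.DataFrame  # Table 1 analog: per (tb, replicate) S, L, V, error, planar T/B
    sweep: ThresholdSweepTable
    volume_summary: pd.DataFrame  # Table 2 analog (mean ± SD volumes)
    error_summary: pd.DataFrame  # Table 3 analog (mean ± SD errors)
    anova_across_thresholds: pd.DataFrame  # per tb_ratio: F, p over threshold groups
    anova_across_tb: pd.DataFrame  # per threshold: F, p over tb groups
    optimal_threshold: float
    manifest: RunManifest

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.planar_table.to_csv(outdir / "table1_planar.csv", index=False)
        self.sweep.rows.to_csv(outdir / "sweep_rows.csv", index=False)
        self.volume_summary.to_csv(outdir / "table2_volumes.csv", index=False)
        self.error_summary.to_csv(outdir / "table3_errors.csv", index=False)
        self.anova_across_thresholds.to_csv(outdir / "anova_across_thresholds.csv", index=False)
        self.anova_across_tb.to_csv(outdir / "anova_across_tb.csv", index=False)
        self.manifest.outputs = {"optimal_threshold": self.optimal_threshold}
        self.manifest.save(outdir / "manifest.json")


def _replicate_seed(base: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((base, *indices)))


def run_phantom_experiment(cfg: ExperimentConfig | None = None) -> PhantomExperimentResult:
    cfg = cfg or ExperimentConfig()
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed, started=time.time())
    n_rep = len(cfg.planar_kcts)
    if len(cfg.tomo_seconds) != n_rep:
        raise InvalidParameterError("planar_kcts and tomo_seconds must have equal length")

    t0 = time.time()
    model = assemble_phantom(ElbowSpec(), Arrangement(gap=cfg.gap, anterior_depth=cfg.anterior_depth),
                             tank_volume=cfg.tank_volume, voxel_size=cfg.voxel_size)
    search = default_search_region(model.lobe_mask, cfg.acquisition.tomo_fwhm, cfg.voxel_size)
    log.info("phantom assembled in %.1f s (grid %s)", time.time() - t0, model.label_grid.shape)

    planar_rows, tomo_items = [], []
    for ti, tb in enumerate(cfg.tb_ratios):
        t0 = time.time()
        activity = assign_activity(model, cfg.target_concentration, tb)
        tomo_noiseless = emulate_tomo(activity, cfg.acquisition, noisy=False)
        for rep in range(n_rep):
            acq = replace(cfg.acquisition,
                          planar_target_counts=cfg.planar_kcts[rep],
                          tomo_seconds_per_frame=cfg.tomo_seconds[rep])
            if cfg.noisy:
                tomo_img = poissonize_tomo(tomo_noiseless, acq,
                                           rng=_replicate_seed(cfg.seed, ti, rep, 0))
                acq_p = replace(acq, rng_seed=int(_replicate_seed(cfg.seed, ti, rep, 1)
                                                  .integers(2**31)))
                planar_img = emulate_planar(activity, acq_p, noisy=True)
            else:
                tomo_img = tomo_noiseless
                planar_img = emulate_planar(activity, acq, noisy=False)

            rois = delineate_planar_roi(planar_img, boundary_fraction=0.20)
            if len(rois) < 2:  # blur bridges the inter-lobe gap at 20%
                rois = split_merged_lobes(planar_img, rois[0])
            S, L = measure_area_and_length(rois, planar_img.pixel_size)
            v_allen = allen_volume(S, L)
            target_roi = np.logical_or.reduce([np.asarray(r) for r in rois])
            tb_planar = planar_tb(planar_img, target_roi, default_background_roi(planar_img))
            planar_rows.append({"tb_ratio": tb, "replicate": rep,
                                "planar_kcts": cfg.planar_kcts[rep],
                                "S_cm2": S, "L_cm": L, "V_ml": v_allen,
                                "error_pct": volume_error(v_allen, TRUE_BILATERAL_VOLUME_ML),
                                "planar_tb": tb_planar})
            tomo_items.append({"image": tomo_img, "true_volume": TRUE_BILATERAL_VOLUME_ML,
                               "tb_ratio": tb, "replicate": rep, "search_region": search,
                               "max_bias_model": cfg.acquisition.max_bias_model,
                               "hottest_n": cfg.acquisition.hottest_n})
        log.info("T/B %g emulated + measured in %.1f s", tb, time.time() - t0)

    planar_table = pd.DataFrame(planar_rows)
    sweep = threshold_sweep(tomo_items, list(cfg.fractions))

    rows = sweep.rows

    def _cell(tb, f):
        sel = (rows["tb_ratio"] == tb) & (rows["threshold"] == f)
        return rows.loc[sel, "volume_ml"].to_numpy()

    across_thr = []
    if len(cfg.fractions) >= 2:
        for tb in cfg.tb_ratios:
            groups = [_cell(tb, f) for f in cfg.fractions]
            if min(len(g) for g in groups) >= 2:
                res = one_way_anova(groups)
                across_thr.append({"tb_ratio": tb, "F": res.F, "p": res.p})
    across_tb = []
    if len(cfg.tb_ratios) >= 2:
        for f in cfg.fractions:
            groups = [_cell(tb, f) for tb in cfg.tb_ratios]
            if min(len(g) for g in groups) >= 2:
                res = one_way_anova(groups)
                across_tb.append({"threshold": f, "F": res.F, "p": res.p})

    summary = sweep.summary()
    volume_summary = summary[["tb_ratio", "threshold", "volume_mean", "volume_sd"]]
    error_summary = summary[["tb_ratio", "threshold", "error_mean", "error_sd"]]

    return PhantomExperimentResult(
        planar_table=planar_table, sweep=sweep,
        volume_summary=volume_summary, error_summary=error_summary,
        anova_across_thresholds=pd.DataFrame(across_thr),
        anova_across_tb=pd.DataFrame(across_tb),
        optimal_threshold=select_optimal_threshold(sweep),
        manifest=manifest)


@dataclass
class CohortExperimentResult:
    cohort: pd.DataFrame
    method_summary: pd.DataFrame  # Table 4 analog: mean ± SD per method
    paired_tests: pd.DataFrame  # paired t-tests between method pairs
    correlation_table: pd.DataFrame  # Table 5 analog: r and b per method pair
    agreement_spect_us: "object"
    agreement_planar_us: "object"
    unstable: bool
    manifest: RunManifest

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(outdir / "cohort.csv", index=False)
        self.method_summary.to_csv(outdir / "table4_methods.csv", index=False)
        self.paired_tests.to_csv(outdir / "paired_tests.csv", index=False)
        self.correlation_table.to_csv(outdir / "table5_correlations.csv", index=False)
        for name, ag in (("spect_us", self.agreement_spect_us),
                         ("planar_us", self.agreement_planar_us)):
            if ag is not None:
                pd.DataFrame({"mean": ag.means, "diff": ag.diffs}).to_csv(
                    outdir / f"bland_altman_{name}.csv", index=False)
        self.manifest.save(outdir / "manifest.json")


def run_cohort_experiment(cfg: ExperimentConfig | None = None) -> CohortExperimentResult:
    from scipy import stats as sps

    cfg = cfg or ExperimentConfig()
    manifest = RunManifest(config_hash=cfg.config_hash(), seed=cfg.seed, started=time.time())
    ccfg = replace(cfg.cohort, rng_seed=cfg.seed)
    frame = cohort_frame(generate_cohort(ccfg))
    unstable = ccfg.n < 5
    if unstable:
        log.warning("cohort size n=%d: statistics will be unstable", ccfg.n)

    channels = {"ultrasound": frame["v_ultrasound"], "planar": frame["v_planar"],
                "spect25": frame["v_spect25"]}
    method_summary = pd.DataFrame(
        [{"method": k, "mean_ml": v.mean(), "sd_ml": v.std(ddof=1)} for k, v in channels.items()])

    pairs = [("planar", "ultrasound"), ("spect25", "ultrasound"), ("planar", "spect25")]
    paired = []
    for a, b in pairs:
        t = sps.ttest_rel(channels[a], channels[b])
        paired.append({"a": a, "b": b, "t": float(t.statistic), "p": float(t.pvalue)})

    corr, ag_spect, ag_planar = [], None, None
    if ccfg.n >= 3:  # correlation and agreement need at least three pairs
        for a in ("spect25", "planar"):
            r, slope = pearson_and_slope(channels["ultrasound"], channels[a])
            corr.append({"method": a, "reference": "ultrasound", "r": r, "b": slope})
        ag_spect = bland_altman(channels["spect25"], channels["ultrasound"])
        ag_planar = bland_altman(channels["planar"], channels["ultrasound"])

    return CohortExperimentResult(
        cohort=frame, method_summary=method_summary,
        paired_tests=pd.DataFrame(paired), correlation_table=pd.DataFrame(corr),
        agreement_spect_us=ag_spect, agreement_planar_us=ag_planar,
        unstable=unstable, manifest=manifest)


def reproduce_printed_numbers() -> pd.DataFrame:
    """Re-derive every closed-form printed quantity of the study and check it.

    Pure arithmetic on in-study constants: activity dilution, target-to-
    background bookkeeping, the volume-error formula applied to the printed
    volumes, the mean-error summaries, and the formula examples.  Returns a
    DataFrame with one row per check (computed, printed, tolerance, pass).
    """
    from .cohort import ellipsoid_volume

    checks = []

    def add(name, computed, printed, tol):
        checks.append({"check": name, "computed": computed, "printed": printed,
                       "tol": tol, "pass": abs(computed - printed) <= tol})

    # activity preparation arithmetic: 142,857 Bq/mL stock, 50.6 mL into 10,122 mL
    add("tank_dilution_bq_per_ml", 142_857.0 * 50.6 / 10_122.0, 714.0, 0.5)
    add("tomographic_tb_ratio", 142_857.0 / 714.285, 200.0, 0.5)

    # volume errors recomputed from printed planar volumes (true volume 53 mL)
    for name, vol, printed in (("table1_error_tb6", 67.50, 27.37),
                               ("table1_error_tb16", 62.98, 18.83),
                               ("table1_error_tb24", 64.79, 22.24)):
        add(name, volume_error(vol, TRUE_BILATERAL_VOLUME_ML), printed, 0.02)

    # mean planar overestimation and mean 25%-threshold error
    add("mean_planar_error_pct", summarize_errors([27.37, 18.83, 22.24]), 22.81, 0.02)
    add("mean_spect25_error_pct", summarize_errors([3.71, 4.21, 3.27]), 3.73, 0.02)

    # patient-cohort overestimation of the planar channel vs ultrasound
    add("patient_planar_overestimation_pct", volume_error(39.64, 31.68), 25.0, 0.5)

    # formula spot checks
    add("allen_volume_example_ml", allen_volume(34.18, 6.07, 0.32), 66.39, 0.01)
    add("ellipsoid_volume_example_ml", ellipsoid_volume(6, 3, 2, 6, 3, 2), 37.699, 0.001)

    return pd.DataFrame(checks)
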
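"""End-to-end orchestration of the analysis chain.

One seeded configuration drives: cohort simulation (or loading) -> QC
-> bin integration with water exclusion -> CRS representative-bin
selection -> exogenous-metabolite removal -> total-area normalization
and Pareto scaling -> PCA with one-pass 95%-ellipse outlier exclusion
-> univariate battery -> per-comparison PLS-DA cross-validation and
VIP -> ORA pathway analysis.  Every stage's exclusions are recorded
with a reason, every written file is checksummed, and a rerun with the
same configuration and seed reproduces all outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import (
    DEFAULT_EXCLUSION,
    DEFAULT_EXOGENOUS,
    bin_snr,
    break_ties,
    crs_scores,
    drop_exogenous,
    integrate_bins,
    to_metabolite_table,
)
from .errors import ValidationError
from .multivariate import cross_validate, pca_outlier_pass, plsda_fit, vip
from .pathways import PathwayLibrary, ora_test, select_pathways
from .spectra_qc import qc_filter
from .stats_univariate import preprocess, univariate_battery
from .synthdata import CohortConfig, generate_cohort, generate_pathway_library

log = logging.getLogger(__name__)

DEFAULT_COMPARISONS = (("MUO", "SRMA"), ("MUO", "IE"), ("SRMA", "IE"))


@dataclass
class QCParams:
    ref_ppm: float = 5.24
    spectrometer_mhz: float = 700.0
    k_sd: float = 1.0
    water_window: tuple = (4.52, 5.18)
    water_max_width: float = 0.4
    action: str = "flag"           # "flag" (record only) or "exclude"


@dataclass
class CVParams:
    k: int = 5
    max_ncomp: int = 8
    repeats: int = 10
    positive_class: str | None = None


@dataclass
class ORAParams:
    alpha: float = 0.05
    impact_min: float = 0.1
    vip_min: float = 1.0
    n_pathways: int = 12
    library_path: str | None = None


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    qc: QCParams = field(default_factory=QCParams)
    exclusion_window: tuple = DEFAULT_EXCLUSION
    exogenous: tuple = DEFAULT_EXOGENOUS
    comparisons: tuple = DEFAULT_COMPARISONS
    cv: CVParams = field(default_factory=CVParams)
    ora: ORAParams = field(default_factory=ORAParams)
    pca_alpha: float = 0.05
    alpha: float = 0.05
    outdir: str = "csfnmr_run"
    seed: int = 0
    save_spectra: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for name, sub_cls in (("cohort", CohortConfig), ("qc", QCParams),
                              ("cv", CVParams), ("ora", ORAParams)):
            if name in raw:
                sub = dict(raw.pop(name))
                for key in ("bins_per_metabolite", "water_window"):
                    if key in sub and isinstance(sub[key], list):
                        sub[key] = tuple(sub[key])
                kwargs[name] = sub_cls(**sub)
        if "comparisons" in raw:
            raw["comparisons"] = tuple(tuple(c) for c in raw.pop("comparisons"))
        if "exclusion_window" in raw:
            raw["exclusion_window"] = tuple(raw["exclusion_window"])
        if "exogenous" in raw:
            raw["exogenous"] = tuple(raw["exogenous"])
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class RunReport:
    """Per-stage record of parameters, exclusions and output files."""

    config: dict
    stages: list = field(default_factory=list)
    exclusions: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)   # path -> sha256
    n_samples_in: int = 0
    n_samples_final: int = 0
    comparisons: dict = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return sum(len(v) for k, v in self.exclusions.items()
                   if k.endswith("samples"))

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "stages": self.stages,
            "exclusions": self.exclusions,
            "manifest": self.manifest,
            "n_samples_in": self.n_samples_in,
            "n_samples_final": self.n_samples_final,
            "comparisons": self.comparisons,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _config_dict(config: RunConfig) -> dict:
    def conv(obj):
        if dataclasses.is_dataclass(obj):
            return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [conv(v) for v in obj]
        if isinstance(obj, list):
            return [conv(v) for v in obj]
        return obj
    return conv(config)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full chain and persist all intermediates.

    Raises :class:`ValidationError` before any compute when a declared
    comparison references an unknown group.
    """
    declared = set(config.cohort.group_sizes)
    for pair in config.comparisons:
        unknown = set(pair) - declared
        if unknown:
            raise ValidationError(
                f"comparison {pair} references undeclared group(s) {unknown}")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=_config_dict(config))
    written: list[Path] = []

    def emit(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    # --- stage 1: cohort -------------------------------------------
    cohort_cfg = replace(config.cohort, seed=config.seed)
    sset, bins, truth = generate_cohort(cohort_cfg)
    report.n_samples_in = sset.n_samples
    emit("bins.csv", bins.to_csv)
    emit("sample_meta.csv", lambda p: sset.sample_meta.to_csv(p, index=False))
    if config.save_spectra:
        emit("spectra.csv", lambda p: sset.to_files(p, outdir / "sample_meta.csv"))
    report.stages.append({"stage": "simulate",
                          "n_samples": sset.n_samples, "n_bins": len(bins),
                          "spectra_sha256": hashlib.sha256(
                              sset.intensities.tobytes()).hexdigest()})

    # --- stage 2: QC -------------------------------------------------
    qc = config.qc
    qc_report = qc_filter(sset, ref_center=qc.ref_ppm,
                          spectrometer_mhz=qc.spectrometer_mhz, k_sd=qc.k_sd,
                          water_window=qc.water_window,
                          water_max_width=qc.water_max_width)
    emit("qc_report.csv", lambda p: qc_report.to_files(p, outdir / "qc_report.json"))
    written.append(outdir / "qc_report.json")
    if qc.action == "exclude":
        report.exclusions["qc_failed_samples"] = qc_report.failed_ids
        sset = sset.subset(qc_report.passed_ids)
    else:
        report.exclusions["qc_failed_samples"] = []
    report.stages.append({"stage": "qc", "n_flagged": len(qc_report.failed_ids),
                          "window_hz": list(qc_report.window_hz)})

    # --- stage 3: binning + CRS --------------------------------------
    binned = integrate_bins(sset, bins, exclusion=config.exclusion_window)
    report.exclusions["water_bins"] = [b for b, _ in binned.excluded_bins]
    snr = bin_snr(sset, binned)
    crs = break_ties(crs_scores(binned), binned, snr)
    emit("binned.csv", lambda p: binned.values.to_csv(p))
    emit("crs.csv", crs.to_csv)
    mtab = to_metabolite_table(binned, crs)
    before = set(mtab.metabolites)
    mtab = drop_exogenous(mtab, config.exogenous)
    report.exclusions["exogenous_metabolites"] = sorted(
        before - set(mtab.metabolites))
    emit("metabolites.csv", mtab.to_csv)
    report.stages.append({"stage": "binning",
                          "n_bins_retained": binned.values.shape[1],
                          "n_metabolites": len(mtab.metabolites)})

    # --- stage 4: preprocessing + PCA outlier pass --------------------
    proc = preprocess(mtab)
    ncomp = min(10, proc.values.shape[0] - 1, proc.values.shape[1])
    pca_model, pca_outliers = pca_outlier_pass(proc.values, ncomp=ncomp,
                                               alpha=config.pca_alpha)
    report.exclusions["pca_ellipse_samples"] = list(pca_outliers)
    if pca_outliers:
        keep = [s for s in mtab.values.index if s not in set(pca_outliers)]
        mtab = mtab.subset_samples(keep)
        proc = preprocess(mtab)
    scores = pd.DataFrame(pca_model.scores,
                          index=pca_model.sample_ids,
                          columns=[f"PC{a + 1}" for a in range(pca_model.ncomp)])
    emit("pca_scores.csv", lambda p: scores.to_csv(p))
    evf = pd.Series(pca_model.explained_variance_fraction,
                    index=[f"PC{a + 1}" for a in
                           range(pca_model.explained_variance_fraction.size)],
                    name="explained_variance_fraction")
    emit("pca_variance.csv", lambda p: evf.to_csv(p))
    report.stages.append({
        "stage": "pca",
        "n_outliers": len(pca_outliers),
        "pc1_pct": float(100 * pca_model.explained_variance_fraction[0]),
        "pc2_pct": float(100 * pca_model.explained_variance_fraction[1]),
    })
    report.n_samples_final = proc.values.shape[0]

    # --- stage 5: univariate -----------------------------------------
    uni = univariate_battery(proc, alpha=config.alpha)
    emit("univariate.csv",
         lambda p: uni.to_files(p, outdir / "univariate.json"))
    written.append(outdir / "univariate.json")
    n_sig = len(uni.significant("kruskal"))
    report.stages.append({"stage": "univariate",
                          "n_kw_fdr_significant": n_sig})

    # --- stage 6: pathway library ------------------------------------
    if config.ora.library_path:
        library = PathwayLibrary.from_json(config.ora.library_path)
    else:
        background = mtab.metabolites
        planted = [m for m in sorted(truth.differential_metabolites)
                   if m in set(background)][:8]
        library = generate_pathway_library(
            config.ora.n_pathways, background, seed=config.seed + 500,
            include_set=planted or None)
    emit("pathway_library.json", library.to_json)

    # --- stage 7: per-comparison PLS-DA + ORA -------------------------
    groups = proc.sample_meta.set_index("sample_id")["group"]
    for idx, (a, b) in enumerate(config.comparisons):
        tag = f"{a}_vs_{b}"
        pair_ids = [s for s in mtab.values.index if groups[s] in (a, b)]
        sub = mtab.subset_samples(pair_ids)
        proc_ab = preprocess(sub)
        y = proc_ab.sample_meta.set_index("sample_id")["group"] \
            .loc[proc_ab.values.index]
        cv = cross_validate(proc_ab.values, y,
                            max_ncomp=config.cv.max_ncomp, k=config.cv.k,
                            repeats=config.cv.repeats,
                            seed=config.seed + 101 + idx,
                            positive_class=config.cv.positive_class)
        model = plsda_fit(proc_ab.values, y, cv.chosen_ncomp,
                          positive_class=cv.positive_class, strict=False)
        v = vip(model, threshold=config.ora.vip_min)
        emit(f"cv_{tag}.json", cv.to_json)
        emit(f"vip_{tag}.csv", v.to_csv)
        hits = v.above_threshold
        ora = ora_test(hits, library)
        chosen = select_pathways(ora, alpha=config.ora.alpha,
                                 impact_min=config.ora.impact_min)
        emit(f"ora_{tag}.csv", lambda p, t=ora: t.to_csv(p, index=False))
        emit(f"ora_selected_{tag}.csv",
             lambda p, t=chosen: t.to_csv(p, index=False))
        report.comparisons[tag] = {
            "chosen_ncomp": int(cv.chosen_ncomp),
            "r2": float(cv.r2[cv.chosen_ncomp - 1]),
            "q2": float(cv.q2[cv.chosen_ncomp - 1]),
            "balanced_accuracy": float(cv.balanced_accuracy),
            "sensitivity": float(cv.sensitivity),
            "specificity": float(cv.specificity),
            "n_vip_hits": len(hits),
            "n_pathways_selected": int(len(chosen)),
        }

    report.manifest = {str(p.name): _sha256(p) for p in written}
    report.to_json(outdir / "run_report.json")
    return report
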
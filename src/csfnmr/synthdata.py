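"""Synthetic CSF NMR cohorts with known ground truth.

Generates three-group cohorts (default MUO / SRMA / IE, sized 20/14/22)
of 1D proton spectra together with the matching bin-definition table
and the ground truth needed for recovery tests.  The forward model:

* each metabolite gets a fixed set of 1..k chemical shifts shared by
  all samples (spectra are assumed aligned), one variable-width bin per
  peak, and a log-normal concentration per sample with group-specific
  log-fold-changes taken from an effect table (by default 29 of the 53
  endogenous metabolites are differential, mostly elevated in SRMA and
  depressed in IE relative to MUO);
* peaks are Lorentzian; bin intensities of one metabolite share the
  metabolite's concentration plus independent per-bin log-normal
  jitter, tuned so same-metabolite bins correlate across samples at a
  configured level;
* a broad residual-water hump sits inside the 4.52-5.18 ppm exclusion
  window, a reference singlet at 5.24 ppm supports line-width QC,
  additive Gaussian noise forms the baseline, and optional
  "high-protein" outlier samples get a broad elevated baseline and
  doubled line widths;
* three exogenous contaminants (ethanol, isopropyl alcohol, mannitol)
  receive concentrations independent of group.

Pathway libraries are generated as random connected graphs over a
metabolite background, optionally forcing one pathway to contain a
chosen metabolite set (for end-to-end enrichment-recovery tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .binning import BinDefinitionTable
from .errors import InvalidParameterError, ValidationError
from .pathways import Pathway, PathwayLibrary
from .spectra import SpectrumSet, make_sample_meta

DEFAULT_GROUP_SIZES = {"MUO": 20, "SRMA": 14, "IE": 22}
EXOGENOUS_NAMES = ("ethanol", "isopropyl_alcohol", "mannitol")

# Endogenous CSF metabolites; the first 29 are differential by default,
# predominantly SRMA-up / IE-down relative to MUO (myo-inositol and
# ascorbate run the other way).
ENDOGENOUS_NAMES = (
    "mannose", "dimethyl_sulfone", "alanine", "4_hydroxybenzoate",
    "3_hydroxyisovalerate", "valine", "choline", "isoleucine", "glycolate",
    "pyruvate", "leucine", "benzoate", "2_hydroxy_3_methylbutyrate",
    "arginine", "3_hydroxybutyrate", "2_aminobutyrate", "2_hydroxybutyrate",
    "isobutyrate", "lactate", "allantoin", "carnitine", "acetoacetate",
    "formate", "acetamide", "histidine", "dimethylglycine", "phenylalanine",
    "myo_inositol", "ascorbate",
    "glucose", "glutamine", "glycine", "serine", "threonine", "creatine",
    "4_pyridoxate", "citrate", "acetate", "creatinine", "tyrosine",
    "methionine", "lysine", "glutamate", "aspartate", "taurine", "succinate",
    "fumarate", "betaine", "urea", "tryptophan", "pyroglutamate", "acetone",
    "methanol",
)
DEFAULT_N_DIFFERENTIAL = 29
_REVERSED_DEFAULTS = ("myo_inositol", "ascorbate")

WATER_CENTER = 4.85
REFERENCE_PPM = 5.24


def lorentzian(ppm_axis, center: float, fwhm: float, area: float) -> np.ndarray:
    """Lorentzian line shape with the given integrated area.

    L(x) = (2 area / (pi fwhm)) / (1 + ((x - center) / (fwhm/2))^2)
    """
    if fwhm <= 0:
        raise InvalidParameterError(f"fwhm must be positive, got {fwhm}")
    x = np.asarray(ppm_axis, dtype=float)
    if not (x.min() <= center <= x.max()):
        raise InvalidParameterError(
            f"center {center} outside axis [{x.min()}, {x.max()}]")
    half = fwhm / 2.0
    return (2.0 * area / (math.pi * fwhm)) / (1.0 + ((x - center) / half) ** 2)


def default_effect_table(metabolites=ENDOGENOUS_NAMES,
                         n_differential: int = DEFAULT_N_DIFFERENTIAL,
                         lfc: float = 0.5,
                         up_group: str = "SRMA",
                         down_group: str = "IE"):
    """Effect table mirroring the predominant SRMA-up / IE-down pattern."""
    table = []
    for met in list(metabolites)[:n_differential]:
        sign = -1.0 if met in _REVERSED_DEFAULTS else 1.0
        table.append((met, up_group, sign * lfc))
        table.append((met, down_group, -sign * lfc))
    return table


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    ``effect_table`` holds (metabolite, group, log-fold-change) triples
    applied on the natural-log concentration scale; ``None`` selects
    the default 29-metabolite SRMA-up / IE-down pattern.  ``noise_sd``
    is the additive baseline noise SD in intensity units; peak heights
    are a few hundred on the same scale.  ``log_conc_sd`` is the
    within-group SD of log concentrations, so an effect of 1.5 *
    ``log_conc_sd`` separates two groups by 1.5 SD.
    """

    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_metabolites: int = 56
    n_exogenous: int = 3
    bins_per_metabolite: tuple = (1, 13)
    effect_table: list | None = None
    noise_sd: float = 1.0
    within_metabolite_bin_correlation: float = 0.9
    outlier_fraction: float = 0.0
    seed: int = 0
    ppm_min: float = 0.5
    ppm_max: float = 10.0
    n_points: int = 2**15
    log_conc_sd: float = 0.25
    peak_fwhm_ppm: float = 0.002
    reference_fwhm_ppm: float = 0.00243   # 1.70 Hz at 700 MHz
    linewidth_jitter: float = 0.0
    water_fwhm_ppm: float = 0.25
    n_water_bins: int = 3

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValidationError("group_sizes must be non-empty")
        for g, c in self.group_sizes.items():
            if c < 2:
                raise ValidationError(f"group {g} needs >= 2 samples, got {c}")
        if self.n_exogenous < 0 or self.n_exogenous > self.n_metabolites:
            raise ValidationError("n_exogenous must lie in [0, n_metabolites]")
        kmin, kmax = self.bins_per_metabolite
        if kmin < 1 or kmax < kmin:
            raise ValidationError("bins_per_metabolite must satisfy 1 <= min <= max")
        if not 0.0 <= self.within_metabolite_bin_correlation <= 1.0:
            raise ValidationError("within_metabolite_bin_correlation must be in [0, 1]")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ValidationError("outlier_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        names = self.metabolite_names()
        exo = set(self.exogenous_names())
        groups = set(self.group_sizes)
        for met, grp, _ in self.effects():
            if met not in names:
                raise ValidationError(f"effect references unknown metabolite {met!r}")
            if grp not in groups:
                raise ValidationError(f"effect references unknown group {grp!r}")
            if met in exo:
                raise ValidationError(
                    f"effect on exogenous metabolite {met!r}: exogenous "
                    "concentrations are group-independent by construction")

    # -- name bookkeeping --------------------------------------------
    def endogenous_names(self) -> list:
        n_endo = self.n_metabolites - self.n_exogenous
        names = list(ENDOGENOUS_NAMES[:n_endo])
        names += [f"met{i:03d}" for i in range(len(names) + 1, n_endo + 1)]
        return names

    def exogenous_names(self) -> list:
        names = list(EXOGENOUS_NAMES[: self.n_exogenous])
        names += [f"exo{i:02d}" for i in range(len(names) + 1, self.n_exogenous + 1)]
        return names

    def metabolite_names(self) -> list:
        return self.endogenous_names() + self.exogenous_names()

    def effects(self) -> list:
        if self.effect_table is not None:
            return list(self.effect_table)
        endo = self.endogenous_names()
        groups = list(self.group_sizes)
        up = "SRMA" if "SRMA" in groups else groups[min(1, len(groups) - 1)]
        down = "IE" if "IE" in groups else groups[-1]
        return default_effect_table(endo, min(DEFAULT_N_DIFFERENTIAL, len(endo)),
                                    up_group=up, down_group=down)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    true_concentrations: pd.DataFrame        # samples x metabolites
    differential_metabolites: dict           # met -> {(a, b): "up"/"down"}
    true_bin_map: dict                       # bin_id -> metabolite
    outlier_samples: set
    effect_table: list

    def directions_for(self, pair) -> dict:
        """metabolite -> direction of pair[1] relative to pair[0].

        Accepts either orientation of the pair (directions flip).
        """
        fwd, rev = tuple(pair), (pair[1], pair[0])
        flip = {"up": "down", "down": "up"}
        out = {}
        for met, dirs in self.differential_metabolites.items():
            if fwd in dirs:
                out[met] = dirs[fwd]
            elif rev in dirs:
                out[met] = flip[dirs[rev]]
        return out


def _allocate_slots(total: int, regions, rng) -> tuple[np.ndarray, float]:
    """Evenly spaced candidate peak positions across the allowed regions."""
    lengths = np.array([hi - lo for lo, hi in regions])
    counts = np.maximum(1, np.round(total * lengths / lengths.sum()).astype(int))
    while counts.sum() > total:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < total:
        counts[np.argmax(lengths / counts)] += 1
    slots, spacing = [], np.inf
    for (lo, hi), c in zip(regions, counts):
        step = (hi - lo) / c
        slots.append(lo + (np.arange(c) + 0.5) * step)
        spacing = min(spacing, step)
    slots = np.concatenate(slots)
    return slots[rng.permutation(slots.size)], float(spacing)


def generate_cohort(config: CohortConfig):
    """Render a full synthetic cohort.

    Returns ``(SpectrumSet, BinDefinitionTable, GroundTruth)``;
    byte-identical on rerun with the same config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = config.metabolite_names()
    endo = config.endogenous_names()
    n_mets = len(names)
    groups = list(config.group_sizes)
    meta = make_sample_meta(config.group_sizes)
    n = len(meta)
    group_of = meta["group"].to_numpy()

    # --- bin layout -------------------------------------------------
    kmin, kmax = config.bins_per_metabolite
    k_bins = rng.integers(kmin, kmax + 1, size=n_mets)
    total_peaks = int(k_bins.sum())
    regions = [(config.ppm_min + 0.1, 4.50), (5.30, config.ppm_max - 0.4)]
    slots, spacing = _allocate_slots(total_peaks, regions, rng)
    half = min(0.45 * spacing, 0.012)

    bin_rows, centers, rel_area, met_of_peak = [], [], [], []
    peak = 0
    for m, met in enumerate(names):
        for _ in range(int(k_bins[m])):
            slot = slots[peak]
            center = slot + rng.uniform(-0.3, 0.3) * half
            bin_rows.append({"bin_id": f"b{peak + 1:04d}",
                             "ppm_low": slot - half, "ppm_high": slot + half,
                             "metabolite": met})
            centers.append(center)
            rel_area.append(rng.uniform(0.3, 1.0))
            met_of_peak.append(m)
            peak += 1
    for w in range(config.n_water_bins):
        lo = 4.60 + w * 0.15
        bin_rows.append({"bin_id": f"w{w + 1:02d}", "ppm_low": lo,
                         "ppm_high": lo + 0.10, "metabolite": "residual_water"})
    bins = BinDefinitionTable(pd.DataFrame(bin_rows))
    centers = np.array(centers)
    rel_area = np.array(rel_area)
    met_of_peak = np.array(met_of_peak)

    # --- concentrations --------------------------------------------
    mu = rng.uniform(math.log(0.5), math.log(5.0), size=n_mets)
    lfc = np.zeros((len(groups), n_mets))
    for met, grp, value in config.effects():
        lfc[groups.index(grp), names.index(met)] += value
    gidx = np.array([groups.index(g) for g in group_of])

    sigma = config.log_conc_sd
    rho = config.within_metabolite_bin_correlation
    z_shared = rng.standard_normal((n, n_mets))
    z_bin = rng.standard_normal((n, total_peaks))
    log_shared = mu + lfc[gidx] + sigma * math.sqrt(rho) * z_shared
    true_conc = pd.DataFrame(np.exp(log_shared),
                             index=meta["sample_id"], columns=names)
    log_area = (np.log(rel_area)[None, :] + log_shared[:, met_of_peak]
                + sigma * math.sqrt(1.0 - rho) * z_bin)
    areas = np.exp(log_area)

    # --- outliers and per-sample line widths ------------------------
    n_out = int(round(config.outlier_fraction * n))
    outlier_idx = rng.choice(n, size=n_out, replace=False) if n_out else np.array([], int)
    lw = np.ones(n)
    if config.linewidth_jitter > 0:
        lw *= np.exp(rng.normal(0.0, config.linewidth_jitter, size=n))
    lw[outlier_idx] *= 2.2

    # --- render ------------------------------------------------------
    ppm = np.linspace(config.ppm_min, config.ppm_max, config.n_points)
    X = rng.normal(0.0, config.noise_sd, size=(n, config.n_points)) \
        if config.noise_sd > 0 else np.zeros((n, config.n_points))

    uniq = np.unique(lw)
    row_groups = [(f, np.nonzero(lw == f)[0]) for f in uniq]
    for b in range(total_peaks):
        for factor, rows in row_groups:
            fwhm = config.peak_fwhm_ppm * factor
            lo = np.searchsorted(ppm, centers[b] - 20 * fwhm)
            hi = np.searchsorted(ppm, centers[b] + 20 * fwhm)
            shape = lorentzian(ppm[lo:hi], centers[b], fwhm, 1.0)
            X[rows, lo:hi] += np.outer(areas[rows, b], shape)

    water_area = 20.0 * np.exp(0.15 * rng.standard_normal(n))
    ref_area = 5.0 * np.exp(0.10 * rng.standard_normal(n))
    for i in range(n):
        X[i] += lorentzian(ppm, WATER_CENTER, config.water_fwhm_ppm,
                           water_area[i])
        X[i] += lorentzian(ppm, REFERENCE_PPM,
                           config.reference_fwhm_ppm * lw[i], ref_area[i])
    for i in outlier_idx:   # broad elevated baseline ("high protein")
        X[i] += lorentzian(ppm, (config.ppm_min + config.ppm_max) / 2.0,
                           8.0, 800.0)

    sset = SpectrumSet(ppm, X, meta)

    differential = {}
    for met, _, _ in config.effects():
        m = names.index(met)
        dirs = {}
        for i, a in enumerate(groups):
            for j, b in enumerate(groups):
                if i < j and lfc[j, m] != lfc[i, m]:
                    dirs[(a, b)] = "up" if lfc[j, m] > lfc[i, m] else "down"
        if dirs:
            differential[met] = dirs
    truth = GroundTruth(
        true_concentrations=true_conc,
        differential_metabolites=differential,
        true_bin_map={r["bin_id"]: r["metabolite"] for r in bin_rows},
        outlier_samples={meta["sample_id"].iloc[i] for i in outlier_idx},
        effect_table=config.effects(),
    )
    return sset, bins, truth


def generate_pathway_library(n_pathways: int, background, seed: int = 0,
                             size_range: tuple = (4, 12),
                             extra_edge_prob: float = 0.3,
                             include_set=None) -> PathwayLibrary:
    """Random connected pathway graphs over a metabolite background.

    Each pathway is a random spanning tree over a metabolite subset
    plus occasional extra edges; node sets may overlap across pathways.
    ``include_set`` forces the first pathway's nodes, enabling planted
    enrichment.  Deterministic under ``seed``.
    """
    background = list(background)
    if not background:
        raise ValidationError("background must be non-empty")
    if n_pathways < 1:
        raise ValidationError("n_pathways must be >= 1")
    if include_set is not None:
        stray = set(include_set) - set(background)
        if stray:
            raise ValidationError(f"include_set outside background: {sorted(stray)}")
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    pathways = []
    for i in range(n_pathways):
        if i == 0 and include_set is not None:
            nodes = list(include_set)
        else:
            size = int(rng.integers(min(lo, len(background)),
                                    min(hi, len(background)) + 1))
            nodes = [background[j]
                     for j in rng.choice(len(background), size, replace=False)]
        edges = []
        for j in range(1, len(nodes)):
            edges.append((nodes[int(rng.integers(0, j))], nodes[j]))
        for j in range(len(nodes)):
            for k in range(j + 1, len(nodes)):
                if (rng.random() < extra_edge_prob
                        and (nodes[j], nodes[k]) not in edges
                        and (nodes[k], nodes[j]) not in edges):
                    edges.append((nodes[j], nodes[k]))
        pathways.append(Pathway(id=f"pw{i + 1:03d}", name=f"pathway_{i + 1}",
                                nodes=nodes, edges=edges))
    return PathwayLibrary(pathways=pathways, background=background)
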
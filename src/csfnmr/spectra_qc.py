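"""Spectral quality control.

Implements the acceptance rules applied to 1D CPMG spectra before
binning: line width at half height of a reference peak (the glucose
anomeric doublet region near 5.24 ppm serves as reference in CSF work),
expressed in Hz via the spectrometer frequency and gated by a cohort
mean +/- k.SD window; residual-water half-height width below a ppm
ceiling; and a signal-to-noise comparability check against a declared
signal-free region.

Spectra failing any check are flagged with an explicit reason.  The
filter marks for exclusion rather than triggering reacquisition, since
no instrument is in the loop; callers may treat the flags as advisory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    InsufficientCohortError,
    InvalidParameterError,
    NoPeakError,
    WindowTooNarrowError,
)
from .spectra import SpectrumSet

log = logging.getLogger(__name__)

#: default reference peak position (ppm) — glucose anomeric proton
DEFAULT_REF_PPM = 5.24
#: default spectrometer frequency in MHz
DEFAULT_MHZ = 700.0
#: default residual-water search window (ppm)
DEFAULT_WATER_WINDOW = (4.52, 5.18)
#: default ceiling on residual-water half-height width (ppm)
DEFAULT_WATER_MAX_WIDTH = 0.4
#: default signal-free region used for noise estimation (ppm)
DEFAULT_NOISE_REGION = (9.5, 10.0)


def _half_height_width_ppm(ppm: np.ndarray, intensity: np.ndarray,
                           low: float, high: float,
                           min_peak_ratio: float | None = 2.0,
                           base: float | None = None) -> float:
    """Full width at half maximum (ppm) of the tallest peak in [low, high].

    The local baseline is the window minimum; half-maximum crossings are
    located by linear interpolation between the bracketing grid points.
    With ``min_peak_ratio`` set, a maximum not exceeding that multiple of
    the window median raises :class:`NoPeakError` (narrow-peak heuristic;
    disabled for broad humps that fill their window).
    """
    mask = (ppm >= low) & (ppm <= high)
    if mask.sum() < 5:
        raise WindowTooNarrowError(
            f"window [{low}, {high}] covers only {int(mask.sum())} grid points")
    x = ppm[mask]
    y = intensity[mask]
    peak = float(y.max())
    if min_peak_ratio is not None and peak <= min_peak_ratio * float(np.median(y)):
        raise NoPeakError(
            f"no peak above local baseline in [{low}, {high}] "
            f"(max {peak:.4g} <= {min_peak_ratio} x median {np.median(y):.4g})")
    base = float(y.min()) if base is None else float(base)
    if peak <= base:
        raise NoPeakError(f"flat signal in [{low}, {high}]")
    ipk = int(np.argmax(y))
    half = base + (peak - base) / 2.0

    left = np.nonzero(y[: ipk + 1] < half)[0]
    if left.size == 0:
        raise WindowTooNarrowError("left half-maximum crossing outside window")
    i = int(left[-1])
    x_left = x[i] + (x[i + 1] - x[i]) * (half - y[i]) / (y[i + 1] - y[i])

    right_rel = np.nonzero(y[ipk:] < half)[0]
    if right_rel.size == 0:
        raise WindowTooNarrowError("right half-maximum crossing outside window")
    j = ipk + int(right_rel[0])
    x_right = x[j - 1] + (x[j] - x[j - 1]) * (half - y[j - 1]) / (y[j] - y[j - 1])
    return float(x_right - x_left)


def estimate_linewidth(ppm: np.ndarray, intensity: np.ndarray,
                       ref_center: float = DEFAULT_REF_PPM,
                       search_halfwidth: float = 0.02,
                       spectrometer_mhz: float = DEFAULT_MHZ) -> float:
    """Line width at half height of the reference peak, in Hz.

    Locates the maximum within ``ref_center +/- search_halfwidth``, finds
    both half-maximum crossings by linear interpolation and converts the
    ppm width with the spectrometer frequency (Hz = ppm x MHz).

    Raises
    ------
    NoPeakError
        If the window maximum does not exceed twice the window median.
    WindowTooNarrowError
        If a half-maximum crossing falls outside the window.
    """
    if spectrometer_mhz <= 0:
        raise InvalidParameterError("spectrometer_mhz must be positive")
    ppm = np.asarray(ppm, float)
    low, high = ref_center - search_halfwidth, ref_center + search_halfwidth
    if low < ppm.min() or high > ppm.max():
        raise InvalidParameterError(
            f"reference window [{low}, {high}] outside axis "
            f"[{ppm.min()}, {ppm.max()}]")
    width_ppm = _half_height_width_ppm(ppm, np.asarray(intensity, float), low, high)
    return width_ppm * spectrometer_mhz


def water_width_ppm(ppm: np.ndarray, intensity: np.ndarray,
                    window: tuple[float, float] = DEFAULT_WATER_WINDOW) -> float:
    """Half-height width (ppm) of the residual-water hump; 0 if absent.

    A maximum sitting at the window boundary is the tail of a peak
    outside the window, not a contained hump, and reports width 0.
    """
    ppm = np.asarray(ppm, float)
    intensity = np.asarray(intensity, float)
    mask = (ppm >= window[0]) & (ppm <= window[1])
    if mask.sum() < 5:
        return 0.0
    y = intensity[mask]
    ipk = int(np.argmax(y))
    if ipk <= 1 or ipk >= y.size - 2:
        return 0.0
    # baseline from a widened window so a hump filling the search window
    # is measured against its true tails, not its truncated edges
    span = window[1] - window[0]
    wide = (ppm >= window[0] - 0.5 * span) & (ppm <= window[1] + 0.5 * span)
    base = float(intensity[wide].min())
    try:
        return _half_height_width_ppm(ppm, intensity, window[0], window[1],
                                      min_peak_ratio=None, base=base)
    except NoPeakError:
        return 0.0
    except WindowTooNarrowError:
        # hump wider than the search window: report the window span,
        # guaranteed to exceed any sane ceiling
        return float(window[1] - window[0])


def snr_estimate(ppm: np.ndarray, intensity: np.ndarray,
                 noise_region: tuple[float, float] = DEFAULT_NOISE_REGION) -> float:
    """Max peak intensity over the SD of a declared signal-free region."""
    ppm = np.asarray(ppm, float)
    y = np.asarray(intensity, float)
    mask = (ppm >= noise_region[0]) & (ppm <= noise_region[1])
    noise = float(np.std(y[mask], ddof=1)) if mask.sum() >= 3 else np.nan
    if not np.isfinite(noise) or noise == 0:
        return np.inf
    return float(y.max()) / noise


@dataclass
class QCReport:
    """Per-sample QC metrics plus the cohort acceptance window.

    ``table`` has one row per sample: ``sample_id``, ``linewidth_hz``,
    ``water_width_ppm``, ``snr``, ``passed`` and a semicolon-joined
    ``reason`` (empty when passed).  A spectrum passes iff every
    individual check passes.
    """

    table: pd.DataFrame
    linewidth_mean_hz: float
    linewidth_sd_hz: float
    window_hz: tuple[float, float]
    params: dict = field(default_factory=dict)

    @property
    def passed_ids(self) -> list[str]:
        return list(self.table.loc[self.table["passed"], "sample_id"])

    @property
    def failed_ids(self) -> list[str]:
        return list(self.table.loc[~self.table["passed"], "sample_id"])

    def to_files(self, csv_path, json_path=None) -> None:
        with open(csv_path, "w") as fh:
            fh.write("# csfnmr QC report; dialect: csv\n")
            self.table.to_csv(fh, index=False)
        if json_path is not None:
            import json
            payload = {
                "linewidth_mean_hz": self.linewidth_mean_hz,
                "linewidth_sd_hz": self.linewidth_sd_hz,
                "window_hz": list(self.window_hz),
                "params": self.params,
                "failed": self.failed_ids,
            }
            with open(json_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def qc_filter(sset: SpectrumSet,
              ref_center: float = DEFAULT_REF_PPM,
              spectrometer_mhz: float = DEFAULT_MHZ,
              k_sd: float = 1.0,
              water_window: tuple[float, float] = DEFAULT_WATER_WINDOW,
              water_max_width: float = DEFAULT_WATER_MAX_WIDTH,
              search_halfwidth: float = 0.02,
              noise_region: tuple[float, float] = DEFAULT_NOISE_REGION,
              snr_k_sd: float = 2.0) -> QCReport:
    """Apply the cohort QC rules and flag failing spectra.

    The line-width acceptance window is ``mean +/- k_sd * SD`` over the
    cohort's reference-peak line widths (1-SD rule by default).  Spectra
    are additionally flagged when the residual-water half-height width
    exceeds ``water_max_width`` or the SNR falls outside the cohort mean
    +/- ``snr_k_sd`` SD.
    """
    if sset.n_samples < 3:
        raise InsufficientCohortError(
            f"QC needs >= 3 samples, got {sset.n_samples}")

    widths = np.array([
        estimate_linewidth(sset.ppm, row, ref_center, search_halfwidth,
                           spectrometer_mhz)
        for row in sset.intensities
    ])
    waters = np.array([
        water_width_ppm(sset.ppm, row, water_window) for row in sset.intensities
    ])
    snrs = np.array([
        snr_estimate(sset.ppm, row, noise_region) for row in sset.intensities
    ])

    mean, sd = float(widths.mean()), float(widths.std(ddof=1))
    lo, hi = mean - k_sd * sd, mean + k_sd * sd
    finite_snr = snrs[np.isfinite(snrs)]
    if finite_snr.size >= 3 and np.std(finite_snr, ddof=1) > 0:
        snr_lo = finite_snr.mean() - snr_k_sd * finite_snr.std(ddof=1)
        snr_hi = finite_snr.mean() + snr_k_sd * finite_snr.std(ddof=1)
    else:
        snr_lo, snr_hi = -np.inf, np.inf

    rows = []
    for sid, w, ww, s in zip(sset.sample_ids, widths, waters, snrs):
        reasons = []
        if not (lo <= w <= hi):
            reasons.append("linewidth-outside-window")
        if ww > water_max_width:
            reasons.append("water-too-wide")
        if np.isfinite(s) and not (snr_lo <= s <= snr_hi):
            reasons.append("snr-outlier")
        rows.append({
            "sample_id": sid,
            "linewidth_hz": w,
            "water_width_ppm": ww,
            "snr": s,
            "passed": not reasons,
            "reason": ";".join(reasons),
        })
    table = pd.DataFrame(rows)
    n_fail = int((~table["passed"]).sum())
    if n_fail:
        log.info("QC flagged %d/%d spectra", n_fail, sset.n_samples)
    return QCReport(
        table=table,
        linewidth_mean_hz=mean,
        linewidth_sd_hz=sd,
        window_hz=(lo, hi),
        params={
            "ref_center": ref_center,
            "spectrometer_mhz": spectrometer_mhz,
            "k_sd": k_sd,
            "water_window": list(water_window),
            "water_max_width": water_max_width,
            "noise_region": list(noise_region),
            "snr_k_sd": snr_k_sd,
        },
    )
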
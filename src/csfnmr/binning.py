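"""Variable-width spectral binning and representative-bin selection.

Annotated ppm intervals ("bins") are integrated by the trapezoid rule,
bins intersecting the residual-water exclusion window are dropped, and
where several bins carry the same metabolite annotation a correlation
reliability score (CRS) picks the single most representative bin: for a
metabolite with k >= 2 bins the Pearson correlation matrix of its bin
columns across samples is computed and each bin is scored by the mean
of its k-1 off-diagonal correlations.  Ties (two-bin metabolites are
always tied) and low-scoring metabolites fall back to signal-to-noise
ratio, then to the lexicographically smallest bin id, so selection is
deterministic end to end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientCohortError, OutOfRangeBinError, ValidationError
from .spectra import SpectrumSet
from .spectra_qc import DEFAULT_NOISE_REGION

log = logging.getLogger(__name__)

#: residual-water region excluded from binning (ppm)
DEFAULT_EXCLUSION = (4.52, 5.18)
#: metabolites of exogenous origin excluded from statistics
DEFAULT_EXOGENOUS = ("ethanol", "isopropyl_alcohol", "mannitol")
#: CRS below which selection falls back to SNR
DEFAULT_LOW_CRS = 0.3

BIN_COLUMNS = ("bin_id", "ppm_low", "ppm_high", "metabolite")


@dataclass
class BinDefinitionTable:
    """Ordered, non-overlapping ppm intervals annotated with metabolites."""

    table: pd.DataFrame  # bin_id, ppm_low, ppm_high, metabolite

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.table).reset_index(drop=True)
        missing = [c for c in BIN_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"bin table missing columns {missing}")
        if t["bin_id"].duplicated().any():
            raise ValidationError("bin ids must be unique")
        if not (t["ppm_low"] < t["ppm_high"]).all():
            bad = t.loc[t["ppm_low"] >= t["ppm_high"], "bin_id"].tolist()
            raise ValidationError(f"bins with ppm_low >= ppm_high: {bad}")
        t = t.sort_values("ppm_low", kind="mergesort").reset_index(drop=True)
        overlap = t["ppm_low"].to_numpy()[1:] < t["ppm_high"].to_numpy()[:-1]
        if overlap.any():
            i = int(np.nonzero(overlap)[0][0])
            raise ValidationError(
                f"bins {t['bin_id'][i]} and {t['bin_id'][i + 1]} overlap")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.table["metabolite"].unique())

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# csfnmr bin definitions; dialect: csv\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "BinDefinitionTable":
        return cls(pd.read_csv(path, comment="#"))


@dataclass
class BinnedMatrix:
    """Samples x bins integrals plus carried-through metadata."""

    values: pd.DataFrame          # index sample_id, columns bin_id
    bins: pd.DataFrame            # retained rows of the bin table
    sample_meta: pd.DataFrame
    excluded_bins: list = field(default_factory=list)  # (bin_id, reason)

    def bin_ids_for(self, metabolite: str) -> list[str]:
        sel = self.bins.loc[self.bins["metabolite"] == metabolite, "bin_id"]
        return sorted(sel)

    @property
    def metabolites(self) -> list[str]:
        return sorted(self.bins["metabolite"].unique())


def integrate_bins(sset: SpectrumSet, bins: BinDefinitionTable,
                   exclusion: tuple[float, float] = DEFAULT_EXCLUSION) -> BinnedMatrix:
    """Trapezoidal bin integrals with water-region exclusion.

    Bin boundaries are half-open ``[low, high)`` on the ppm grid so that
    adjacent bins never double-count a grid point.  Bins intersecting
    the exclusion window are dropped and recorded; a bin outside the
    axis range raises :class:`OutOfRangeBinError` naming the bin.
    """
    lo_ex, hi_ex = sorted(exclusion)
    ppm = sset.ppm
    kept_rows, excluded, columns = [], [], {}
    for row in bins.table.itertuples(index=False):
        if row.ppm_high > lo_ex and row.ppm_low < hi_ex:
            excluded.append((row.bin_id, "intersects-exclusion-window"))
            continue
        if row.ppm_low < ppm[0] or row.ppm_high > ppm[-1]:
            raise OutOfRangeBinError(
                f"bin {row.bin_id} [{row.ppm_low}, {row.ppm_high}] outside "
                f"axis [{ppm[0]}, {ppm[-1]}]")
        mask = (ppm >= row.ppm_low) & (ppm < row.ppm_high)
        if mask.sum() < 2:
            excluded.append((row.bin_id, "fewer-than-2-grid-points"))
            continue
        columns[row.bin_id] = np.trapezoid(sset.intensities[:, mask],
                                           ppm[mask], axis=1)
        kept_rows.append(row)
    if excluded:
        log.info("dropped %d bins (%s)", len(excluded),
                 "; ".join(f"{b}:{r}" for b, r in excluded[:5]))
    values = pd.DataFrame(columns, index=pd.Index(sset.sample_ids, name="sample_id"))
    return BinnedMatrix(values=values,
                        bins=pd.DataFrame(kept_rows).reset_index(drop=True),
                        sample_meta=sset.sample_meta.copy(),
                        excluded_bins=excluded)


@dataclass
class CRSTable:
    """Per-bin correlation reliability scores and the selection flags."""

    table: pd.DataFrame  # metabolite, bin_id, crs, selected, tie_broken_manually

    @property
    def selected(self) -> pd.Series:
        """metabolite -> selected bin_id."""
        sel = self.table.loc[self.table["selected"]]
        return sel.set_index("metabolite")["bin_id"]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# csfnmr CRS table; dialect: csv\n")
            self.table.to_csv(fh, index=False)


def crs_scores(binned: BinnedMatrix) -> CRSTable:
    """Correlation reliability score per bin, argmax selection per metabolite.

    Single-bin metabolites score 1 by convention.  Zero-variance bin
    columns have undefined correlations; their CRS is the mean over the
    defined entries only, or -inf when none are defined (such a bin is
    never selected unless it is the sole candidate).
    """
    if binned.values.shape[0] < 3:
        raise InsufficientCohortError("CRS needs >= 3 samples")
    rows = []
    for met in binned.metabolites:
        bin_ids = binned.bin_ids_for(met)
        if len(bin_ids) == 1:
            rows.append({"metabolite": met, "bin_id": bin_ids[0], "crs": 1.0,
                         "selected": True, "tie_broken_manually": False})
            continue
        cols = binned.values[bin_ids].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(cols, rowvar=False)
        np.fill_diagonal(corr, np.nan)
        crs = np.full(len(bin_ids), -np.inf)
        for i in range(len(bin_ids)):
            defined = corr[i][np.isfinite(corr[i])]
            if defined.size:
                crs[i] = float(defined.mean())
            else:
                log.warning("bin %s of %s: all correlations undefined "
                            "(zero-variance column)", bin_ids[i], met)
        best = int(np.argmax(crs))
        for i, b in enumerate(bin_ids):
            rows.append({"metabolite": met, "bin_id": b, "crs": crs[i],
                         "selected": i == best, "tie_broken_manually": False})
    return CRSTable(pd.DataFrame(rows))


def bin_snr(sset: SpectrumSet, binned: BinnedMatrix,
            noise_region: tuple[float, float] = DEFAULT_NOISE_REGION) -> pd.Series:
    """Per-bin SNR: mean over samples of (max in-bin intensity / noise SD)."""
    ppm = sset.ppm
    nz = (ppm >= noise_region[0]) & (ppm <= noise_region[1])
    noise = np.std(sset.intensities[:, nz], axis=1, ddof=1)
    noise = np.where(noise > 0, noise, np.inf)
    out = {}
    for row in binned.bins.itertuples(index=False):
        mask = (ppm >= row.ppm_low) & (ppm < row.ppm_high)
        peak = sset.intensities[:, mask].max(axis=1)
        out[row.bin_id] = float(np.mean(peak / noise))
    return pd.Series(out, name="snr")


def break_ties(crs: CRSTable, binned: BinnedMatrix,
               snr: pd.Series | None = None,
               tolerance: float = 1e-6,
               low_crs_threshold: float = DEFAULT_LOW_CRS) -> CRSTable:
    """Resolve tied or low-confidence CRS selections deterministically.

    Where the top scores of a metabolite are within ``tolerance`` of each
    other, or the top score falls below ``low_crs_threshold``, the
    candidate bin with the highest SNR is selected instead (among the
    tied bins, or among all of the metabolite's bins in the low-score
    case).  Remaining ties fall back to the lexicographically smallest
    bin id.  Affected rows are marked ``tie_broken_manually``.
    """
    t = crs.table.copy()
    if snr is None:
        snr = pd.Series(0.0, index=t["bin_id"].unique())
    for met, grp in t.groupby("metabolite", sort=False):
        if len(grp) == 1:
            continue
        top = grp["crs"].max()
        tied = grp.loc[grp["crs"] >= top - tolerance]
        if np.isfinite(top) and top < low_crs_threshold:
            candidates = grp  # selection unreliable: rank every bin by SNR
        elif len(tied) > 1:
            candidates = tied
        else:
            continue
        cand = candidates.assign(_snr=candidates["bin_id"].map(snr).fillna(0.0))
        cand = cand.sort_values(["_snr", "bin_id"],
                                ascending=[False, True], kind="mergesort")
        winner = cand.iloc[0]["bin_id"]
        t.loc[grp.index, "selected"] = t.loc[grp.index, "bin_id"] == winner
        t.loc[grp.index, "tie_broken_manually"] = True
    return CRSTable(t)


@dataclass
class MetaboliteTable:
    """Samples x metabolites matrix (one selected bin integral each)."""

    values: pd.DataFrame          # index sample_id, columns metabolite
    provenance: dict              # metabolite -> selected bin_id
    sample_meta: pd.DataFrame

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids) -> "MetaboliteTable":
        keep = [s for s in self.values.index if s in set(sample_ids)]
        meta = self.sample_meta[self.sample_meta["sample_id"].isin(keep)]
        return MetaboliteTable(self.values.loc[keep].copy(), dict(self.provenance),
                               meta.reset_index(drop=True))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# csfnmr metabolite table; dialect: csv\n")
            self.values.to_csv(fh)


def to_metabolite_table(binned: BinnedMatrix, crs: CRSTable) -> MetaboliteTable:
    """Assemble the samples x metabolites matrix from the selected bins."""
    sel = crs.selected
    counts = crs.table.groupby("metabolite")["selected"].sum()
    bad = counts[counts != 1]
    if len(bad):
        raise ValidationError(
            f"metabolites without a unique selected bin: {list(bad.index)}")
    values = binned.values[list(sel.values)].copy()
    values.columns = list(sel.index)
    values = values[sorted(values.columns)]
    return MetaboliteTable(values=values, provenance=dict(sel),
                           sample_meta=binned.sample_meta.copy())


def drop_exogenous(table: MetaboliteTable,
                   names=DEFAULT_EXOGENOUS) -> MetaboliteTable:
    """Remove exogenous metabolites (tolerant of absent names)."""
    present = [n for n in names if n in table.values.columns]
    absent = [n for n in names if n not in table.values.columns]
    if absent:
        log.warning("exogenous metabolites not in table, ignored: %s", absent)
    values = table.values.drop(columns=present)
    prov = {m: b for m, b in table.provenance.items() if m not in set(present)}
    return MetaboliteTable(values=values, provenance=prov,
                           sample_meta=table.sample_meta.copy())
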
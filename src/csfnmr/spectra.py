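"""Container and text I/O for sets of 1D NMR spectra.

A :class:`SpectrumSet` holds a shared chemical-shift (ppm) axis, one
intensity row per sample, and a sample-metadata table with the sample id,
diagnostic group label and collection site.  Spectra travel as plain
delimited text: one wide table (first column ``ppm``, one column per
sample) plus a metadata table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

META_COLUMNS = ("sample_id", "group", "site")


@dataclass
class SpectrumSet:
    """A cohort of 1D spectra on a common ppm axis.

    Parameters
    ----------
    ppm : ndarray, shape (n_points,)
        Strictly increasing chemical-shift axis in ppm.
    intensities : ndarray, shape (n_samples, n_points)
        One intensity row per sample, arbitrary units.
    sample_meta : DataFrame
        Columns ``sample_id`` (unique), ``group``, ``site``; row order
        matches the intensity rows.
    """

    ppm: np.ndarray
    intensities: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.ppm.ndim != 1:
            raise ValidationError("ppm axis must be one-dimensional")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValidationError("ppm axis must be strictly monotone")
        if np.all(d < 0):  # store ascending internally
            self.ppm = self.ppm[::-1].copy()
            self.intensities = self.intensities[:, ::-1].copy()
        if self.intensities.shape[1] != self.ppm.size:
            raise ValidationError(
                f"intensity rows have {self.intensities.shape[1]} points, "
                f"axis has {self.ppm.size}"
            )
        meta = pd.DataFrame(self.sample_meta).reset_index(drop=True)
        missing = [c for c in META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValidationError(f"sample_meta missing columns {missing}")
        if meta.shape[0] != self.intensities.shape[0]:
            raise ValidationError("sample_meta rows do not match intensity rows")
        if meta["sample_id"].duplicated().any():
            raise ValidationError("sample ids must be unique")
        self.sample_meta = meta

    # -- convenience -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta["sample_id"])

    @property
    def groups(self) -> pd.Series:
        return self.sample_meta.set_index("sample_id")["group"]

    def subset(self, sample_ids) -> "SpectrumSet":
        """Return a new set restricted to ``sample_ids`` (order preserved)."""
        wanted = set(sample_ids)
        mask = self.sample_meta["sample_id"].isin(wanted).to_numpy()
        return SpectrumSet(
            self.ppm.copy(),
            self.intensities[mask].copy(),
            self.sample_meta.loc[mask].reset_index(drop=True),
        )

    # -- text I/O ----------------------------------------------------
    def to_files(self, spectra_path, meta_path, float_format: str = "%.8g") -> None:
        """Write the wide spectra table and the metadata table as CSV."""
        wide = pd.DataFrame({"ppm": self.ppm})
        for i, sid in enumerate(self.sample_ids):
            wide[sid] = self.intensities[i]
        with open(spectra_path, "w") as fh:
            fh.write("# csfnmr SpectrumSet; dialect: csv; first column ppm\n")
            wide.to_csv(fh, index=False, float_format=float_format)
        with open(meta_path, "w") as fh:
            fh.write("# csfnmr sample metadata; dialect: csv\n")
            self.sample_meta.to_csv(fh, index=False)

    @classmethod
    def from_files(cls, spectra_path, meta_path) -> "SpectrumSet":
        wide = pd.read_csv(spectra_path, comment="#")
        meta = pd.read_csv(meta_path, comment="#")
        ppm = wide["ppm"].to_numpy()
        ids = [c for c in wide.columns if c != "ppm"]
        meta = meta.set_index("sample_id").loc[ids].reset_index()
        intensities = wide[ids].to_numpy().T
        return cls(ppm, intensities, meta)


def make_sample_meta(group_sizes: dict[str, int], site: str = "site1") -> pd.DataFrame:
    """Build a metadata table from ``{group: count}``, ids ``s001``.."""
    rows = []
    i = 0
    for group, count in group_sizes.items():
        for _ in range(int(count)):
            i += 1
            rows.append({"sample_id": f"s{i:03d}", "group": group, "site": site})
    return pd.DataFrame(rows, columns=list(META_COLUMNS))
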
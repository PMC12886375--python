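"""Bin integration, CRS selection, tie-breaking and exogenous removal."""

import logging

import numpy as np
import pandas as pd
import pytest

from csfnmr.binning import (
    BinDefinitionTable,
    BinnedMatrix,
    CRSTable,
    break_ties,
    crs_scores,
    drop_exogenous,
    integrate_bins,
    to_metabolite_table,
)
from csfnmr.errors import OutOfRangeBinError, ValidationError
from csfnmr.spectra import SpectrumSet, make_sample_meta
from csfnmr.synthdata import lorentzian


def _set(axis, rows, groups={"MUO": 2, "SRMA": 2}):
    n = sum(groups.values())
    data = np.tile(rows, (n, 1)) if np.ndim(rows) == 1 else rows
    return SpectrumSet(axis, data, make_sample_meta(groups))


def _bins(rows):
    return BinDefinitionTable(pd.DataFrame(
        rows, columns=["bin_id", "ppm_low", "ppm_high", "metabolite"]))


class TestIntegrateBins:
    def test_constant_intensity_rectangle(self):
        axis = np.linspace(0.0, 10.0, 10_001)
        sset = _set(axis, np.full(axis.size, 3.0))
        bins = _bins([("b1", 2.0, 2.5, "x")])
        out = integrate_bins(sset, bins)
        # half-open grid coverage loses at most one grid cell at the edge
        assert out.values["b1"].to_numpy() == pytest.approx(3.0 * 0.5, rel=5e-3)

    def test_water_window_bin_dropped_and_recorded(self):
        axis = np.linspace(0.0, 10.0, 1001)
        sset = _set(axis, np.ones(axis.size))
        bins = _bins([("b1", 4.60, 4.90, "x"), ("b2", 2.0, 2.2, "y")])
        out = integrate_bins(sset, bins, exclusion=(4.52, 5.18))
        assert list(out.values.columns) == ["b2"]
        assert ("b1", "intersects-exclusion-window") in out.excluded_bins

    def test_isolated_peak_area_recovered(self):
        axis = np.linspace(0.0, 10.0, 2**16)
        y = lorentzian(axis, 3.0, 0.002, 3.0)
        sset = _set(axis, y)
        out = integrate_bins(sset, _bins([("b1", 2.9, 3.1, "x")]))
        assert out.values["b1"].to_numpy() == pytest.approx(3.0, rel=0.05)

    def test_bin_outside_axis_named_in_error(self):
        axis = np.linspace(1.0, 9.0, 101)
        sset = _set(axis, np.ones(axis.size))
        with pytest.raises(OutOfRangeBinError, match="b9"):
            integrate_bins(sset, _bins([("b9", 9.5, 9.8, "x")]))

    def test_half_open_bins_never_double_count(self):
        axis = np.linspace(0.0, 10.0, 1001)
        sset = _set(axis, np.ones(axis.size))
        bins = _bins([("b1", 2.0, 2.5, "x"), ("b2", 2.5, 3.0, "x")])
        out = integrate_bins(sset, bins)
        total = np.trapezoid(np.ones(axis.size)[(axis >= 2.0) & (axis <= 3.0)],
                             axis[(axis >= 2.0) & (axis <= 3.0)])
        assert float(out.values.iloc[0].sum()) <= total + 1e-9

    def test_retained_integrals_bounded_by_whole_spectrum(self, small_cohort):
        sset, bins, _ = small_cohort
        clean = SpectrumSet(sset.ppm, np.clip(sset.intensities, 0, None),
                            sset.sample_meta)
        out = integrate_bins(clean, bins)
        whole = np.trapezoid(clean.intensities, clean.ppm, axis=1)
        assert (out.values.sum(axis=1).to_numpy() <= whole + 1e-9).all()


def _binned_from_values(values: pd.DataFrame, met_of: dict) -> BinnedMatrix:
    bins = pd.DataFrame({
        "bin_id": list(values.columns),
        "ppm_low": np.arange(len(values.columns), dtype=float),
        "ppm_high": np.arange(len(values.columns), dtype=float) + 0.5,
        "metabolite": [met_of[b] for b in values.columns],
    })
    meta = pd.DataFrame({"sample_id": values.index, "group": "g",
                         "site": "s"})
    return BinnedMatrix(values=values, bins=bins, sample_meta=meta)


def _brute_force_crs(cols: np.ndarray) -> np.ndarray:
    """Independent oracle: full Pearson matrix, explicit row means."""
    k = cols.shape[1]
    out = np.empty(k)
    for i in range(k):
        vals = []
        for j in range(k):
            if j == i:
                continue
            xi, xj = cols[:, i], cols[:, j]
            num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
            den = np.sqrt(np.sum((xi - xi.mean())**2)
                          * np.sum((xj - xj.mean())**2))
            vals.append(num / den)
        out[i] = np.mean(vals)
    return out


class TestCRS:
    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            k = int(rng.integers(3, 9))
            n = int(rng.integers(10, 61))
            cols = rng.standard_normal((n, k)) \
                + rng.standard_normal((n, 1)) * rng.uniform(0, 2)
            values = pd.DataFrame(cols, columns=[f"b{i}" for i in range(k)],
                                  index=[f"s{i}" for i in range(n)])
            binned = _binned_from_values(values, {f"b{i}": "m" for i in range(k)})
            got = crs_scores(binned).table.set_index("bin_id")
            expected = _brute_force_crs(cols)
            assert got["crs"].to_numpy() == pytest.approx(expected, abs=1e-10)
            assert got.index[got["selected"]][0] == f"b{int(np.argmax(expected))}"

    def test_single_bin_metabolite_scores_one(self):
        values = pd.DataFrame({"b1": [1.0, 2.0, 3.0]}, index=list("abc"))
        crs = crs_scores(_binned_from_values(values, {"b1": "m"}))
        row = crs.table.iloc[0]
        assert row["crs"] == 1.0 and row["selected"]

    def test_two_bins_always_tied(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.standard_normal((8, 2)),
                              columns=["b1", "b2"], index=range(8))
        crs = crs_scores(_binned_from_values(values, {"b1": "m", "b2": "m"}))
        a, b = crs.table["crs"]
        assert a == pytest.approx(b, abs=1e-15)

    def test_correlated_pair_beats_noise_bin(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(30)
        values = pd.DataFrame({
            "b1": x, "b2": x + 0.01 * rng.standard_normal(30),
            "b3": rng.standard_normal(30)})
        crs = crs_scores(_binned_from_values(
            values, {b: "m" for b in values.columns}))
        assert crs.selected["m"] in {"b1", "b2"}

    def test_zero_variance_column_never_selected(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(10)
        values = pd.DataFrame({"b1": x, "b2": x * 2, "b3": np.zeros(10)})
        crs = crs_scores(_binned_from_values(
            values, {b: "m" for b in values.columns}))
        t = crs.table.set_index("bin_id")
        assert t.loc["b3", "crs"] == -np.inf
        assert crs.selected["m"] != "b3"


class TestBreakTies:
    def _crs(self, rows):
        return CRSTable(pd.DataFrame(
            rows, columns=["metabolite", "bin_id", "crs", "selected",
                           "tie_broken_manually"]))

    def test_tied_pair_resolved_by_snr(self):
        crs = self._crs([("m", "b1", 0.7, True, False),
                         ("m", "b2", 0.7, False, False)])
        snr = pd.Series({"b1": 10.0, "b2": 50.0})
        out = break_ties(crs, binned=None, snr=snr)
        assert out.selected["m"] == "b2"
        assert out.table["tie_broken_manually"].all()

    def test_tied_snr_falls_back_to_bin_id(self):
        crs = self._crs([("m", "b2", 0.7, True, False),
                         ("m", "b1", 0.7, False, False)])
        snr = pd.Series({"b1": 5.0, "b2": 5.0})
        assert break_ties(crs, None, snr).selected["m"] == "b1"

    def test_clear_winner_untouched(self):
        crs = self._crs([("m", "b1", 0.9, True, False),
                         ("m", "b2", 0.2, False, False),
                         ("m", "b3", 0.1, False, False)])
        out = break_ties(crs, None, pd.Series({"b1": 1.0, "b2": 99.0,
                                               "b3": 99.0}))
        assert out.selected["m"] == "b1"
        assert not out.table["tie_broken_manually"].any()

    def test_low_score_reselects_by_snr(self):
        crs = self._crs([("m", "b1", 0.25, True, False),
                         ("m", "b2", 0.10, False, False)])
        out = break_ties(crs, None, pd.Series({"b1": 1.0, "b2": 40.0}))
        assert out.selected["m"] == "b2"


class TestMetaboliteTable:
    def test_crs_selection_recovers_annotated_metabolite(self, small_cohort):
        sset, bins, truth = small_cohort
        binned = integrate_bins(sset, bins)
        crs = break_ties(crs_scores(binned), binned)
        table = to_metabolite_table(binned, crs)
        hits = sum(truth.true_bin_map[b] == m
                   for m, b in table.provenance.items())
        assert hits / len(table.provenance) >= 0.95

    def test_drop_exogenous_default_three(self, small_cohort):
        sset, bins, _ = small_cohort
        binned = integrate_bins(sset, bins)
        table = to_metabolite_table(binned, break_ties(crs_scores(binned),
                                                       binned))
        assert len(table.metabolites) == 56
        out = drop_exogenous(table)
        assert len(out.metabolites) == 53
        assert not {"ethanol", "isopropyl_alcohol", "mannitol"} \
            & set(out.metabolites)

    def test_drop_exogenous_tolerant(self, caplog):
        values = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]},
                              index=["s1", "s2"])
        meta = pd.DataFrame({"sample_id": ["s1", "s2"], "group": "g",
                             "site": "x"})
        from csfnmr.binning import MetaboliteTable
        table = MetaboliteTable(values, {"a": "b1", "b": "b2"}, meta)
        assert drop_exogenous(table, []).values.equals(values)
        with caplog.at_level(logging.WARNING):
            out = drop_exogenous(table, ["zzz"])
        assert out.values.equals(values)
        assert "zzz" in caplog.text


def test_overlapping_bins_rejected():
    with pytest.raises(ValidationError):
        _bins([("b1", 2.0, 2.6, "x"), ("b2", 2.5, 3.0, "y")])
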
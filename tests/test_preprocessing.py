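"""CSV ingestion, unit-interval truncation and zero-dose handling."""

import io
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import betadose as bd
from betadose.preprocessing import (DatasetFormatError, read_dataset,
                                    read_dataset_from_text)


def _csv(text):
    return io.StringIO(text)


class TestReadDataset:
    def test_well_formed_file(self):
        ds = read_dataset(_csv("conc,effect,agent\n1,0.2,A\n2,0.5,A\n4,0.8,A\n"))
        assert ds.n_obs == 3
        assert list(ds.data["flag"]) == ["raw"] * 3
        assert ds.groups == ["A"]

    def test_out_of_range_response_flagged(self):
        ds = read_dataset(_csv(
            "c,e,g\n1,0.2,A\n2,0.5,A\n4,1.2,A\n8,0.9,A\n"))
        row = ds.data[ds.data["dose"] == 4.0].iloc[0]
        assert row["flag"] == "truncated"
        assert 0.0 < row["response"] < 1.0

    def test_non_numeric_dose_names_row(self):
        with pytest.raises(DatasetFormatError, match="row"):
            read_dataset(_csv(
                "c,e,g\n1,0.2,A\n2,0.5,A\n4,0.8,A\noops,0.9,A\n"))

    def test_empty_and_narrow_files(self):
        with pytest.raises(DatasetFormatError):
            read_dataset(_csv(""))
        with pytest.raises(DatasetFormatError, match="3 columns"):
            read_dataset(_csv("a,b\n1,2\n"))

    def test_percentage_rescale(self):
        with pytest.warns(UserWarning, match="percent"):
            ds = read_dataset(_csv(
                "c,e,g\n1,20,A\n2,50,A\n4,80,A\n"))
        np.testing.assert_allclose(ds.data["response"], [0.2, 0.5, 0.8])

    def test_round_trips_to_csv(self):
        ds = read_dataset(_csv("c,e,g\n1,0.2,A\n2,0.5,A\n4,0.8,A\n"))
        buf = io.StringIO()
        ds.to_csv(buf)
        ds2 = read_dataset_from_text(buf.getvalue())
        np.testing.assert_allclose(ds.data["response"], ds2.data["response"])


class TestTruncation:
    def test_conventional_formula(self):
        out, flags = bd.truncate_unit_interval([1.0], method="conventional", n=10)
        assert out[0] == pytest.approx(0.95)
        assert flags.all()

    def test_conventional_bounds(self):
        for n in (1, 4, 50):
            y = np.linspace(0.0, 1.0, 11)
            out, _ = bd.truncate_unit_interval(y, method="conventional", n=n)
            assert out.min() == pytest.approx(0.5 / n)
            assert out.max() == pytest.approx((n - 0.5) / n)

    def test_sequential_interior_noop(self):
        y = np.array([0.1, 0.4, 0.9])
        out, flags = bd.truncate_unit_interval(y, method="sequential")
        np.testing.assert_array_equal(out, y)
        assert not flags.any()

    def test_sequential_hand_trace(self):
        # values (0.0, 0.5, 1.0, 1.01), n=4: delta = min(gap/2, 1/8, 1e-3)
        # = 1e-3; most extreme upper offender 1.01 -> 1-delta, then 1.0 ->
        # 1-2*delta; 0.0 -> delta
        y = np.array([0.0, 0.5, 1.0, 1.01])
        out, flags = bd.truncate_unit_interval(y, method="sequential", n=4)
        delta = 1e-3
        np.testing.assert_allclose(out, [delta, 0.5, 1 - 2 * delta, 1 - delta])
        assert list(flags) == [True, False, True, True]

    def test_sequential_idempotent(self):
        y = np.array([0.0, 0.5, 1.0, 1.01, -0.2])
        once, _ = bd.truncate_unit_interval(y, method="sequential")
        twice, flags = bd.truncate_unit_interval(once, method="sequential")
        np.testing.assert_array_equal(once, twice)
        assert not flags.any()

    @given(st.lists(st.integers(min_value=-5000, max_value=15000),
                    min_size=2, max_size=30, unique=True))
    @settings(max_examples=200, deadline=None)
    def test_sequential_preserves_rank_order(self, ys):
        y = np.array(ys, dtype=float) / 10_000.0
        out, _ = bd.truncate_unit_interval(y, method="sequential")
        assert np.all((out > 0) & (out < 1))
        assert np.array_equal(np.argsort(out, kind="stable"),
                              np.argsort(y, kind="stable"))


class TestZeroDose:
    def test_identity_without_zero_doses(self):
        ds = read_dataset(_csv("c,e,g\n1,0.2,A\n2,0.5,A\n4,0.8,A\n"))
        out = bd.handle_zero_dose(ds)
        assert out.n_obs == 3

    def test_drops_with_warning(self):
        with pytest.warns(UserWarning, match="nonpositive"):
            ds = read_dataset(_csv(
                "c,e,g\n0,0.1,A\n1,0.2,A\n2,0.5,A\n4,0.8,A\n"))
        assert ds.n_obs == 3
        assert any("dropped" in line for line in ds.log)

    def test_error_when_group_collapses(self):
        with pytest.raises(DatasetFormatError, match="distinct"):
            with pytest.warns(UserWarning):
                read_dataset(_csv("c,e,g\n0,0.1,A\n0,0.3,A\n1,0.5,A\n"))
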
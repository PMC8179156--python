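"""Feature-table data model, I/O round trips, group means."""

import numpy as np
import pandas as pd
import pytest

from tracerscreen.feature_table import (
    FeatureTable,
    FeatureTableError,
    group_means,
    read_feature_table,
    write_feature_table,
)
from tracerscreen.simulate import write_simulation

from conftest import make_table


def test_roundtrip_preserves_everything(tmp_path, small_sim):
    table, truth = small_sim
    write_simulation(table, truth, tmp_path)
    back = read_feature_table(tmp_path / "matrix.csv", tmp_path / "design.csv")
    pd.testing.assert_frame_equal(back.features, table.features)
    pd.testing.assert_frame_equal(
        back.design, table.design, check_dtype=False)
    pd.testing.assert_frame_equal(back.intensities, table.intensities)


def test_reader_small_fixture(tmp_path):
    (tmp_path / "m.csv").write_text(
        "id,mz,rt,ion_mode,S1,S2,S3,S4\n"
        "f1,200.1,1.5,positive,100,200,,400\n"
        "f2,300.2,2.5,negative,10,20,30,40\n"
    )
    (tmp_path / "d.csv").write_text(
        "sample_id,treatment,time_h,replicate,batch\n"
        "S1,control,3,1,b1\nS2,unlabeled_tracer,3,1,b1\n"
        "S3,labeled_tracer,3,1,b1\nS4,control,9,1,b1\n"
    )
    t = read_feature_table(tmp_path / "m.csv", tmp_path / "d.csv")
    assert t.n_features == 2 and t.n_samples == 4
    assert np.isnan(t.intensities.loc["f1", "S3"])  # missing, not zero


def test_reader_errors(tmp_path):
    (tmp_path / "d.csv").write_text(
        "sample_id,treatment,time_h,replicate,batch\nS1,control,3,1,b1\n"
    )
    (tmp_path / "extra.csv").write_text(
        "id,mz,rt,ion_mode,S1,S13\nf1,200.1,1.5,positive,1,2\n"
    )
    with pytest.raises(FeatureTableError, match="S13"):
        read_feature_table(tmp_path / "extra.csv", tmp_path / "d.csv")

    (tmp_path / "dupe.csv").write_text(
        "id,mz,rt,ion_mode,S1\nf1,200.1,1.5,positive,1\nf1,201.1,1.6,positive,2\n"
    )
    with pytest.raises(FeatureTableError, match="duplicate"):
        read_feature_table(tmp_path / "dupe.csv", tmp_path / "d.csv")

    (tmp_path / "bad.csv").write_text(
        "id,mz,rt,ion_mode,S1\nf1,200.1,1.5,positive,oops\n"
    )
    with pytest.raises(FeatureTableError, match="S1"):
        read_feature_table(tmp_path / "bad.csv", tmp_path / "d.csv")


def test_reader_column_map(tmp_path):
    (tmp_path / "m.csv").write_text(
        "Feature,MZ,RT,Mode,S1\nf1,200.1,1.5,positive,7\n"
    )
    (tmp_path / "d.csv").write_text(
        "sample_id,treatment,time_h,replicate,batch\nS1,control,3,1,b1\n"
    )
    t = read_feature_table(
        tmp_path / "m.csv", tmp_path / "d.csv",
        column_map={"Feature": "id", "MZ": "mz", "RT": "rt", "Mode": "ion_mode"},
    )
    assert t.feature_ids() == ["f1"]


def test_validation_rejects_negative_intensity():
    with pytest.raises(FeatureTableError, match="negative"):
        make_table([[-1.0] + [1.0] * 8])


def test_validation_rejects_duplicate_design_cell():
    t = make_table([[1.0] * 9])
    bad = t.design.copy()
    bad.loc[1, ["treatment", "time_h", "replicate"]] = bad.loc[0, ["treatment", "time_h", "replicate"]]
    with pytest.raises(FeatureTableError):
        FeatureTable(t.features, bad, t.intensities)


class TestGroupMeans:
    def test_simple_means(self):
        # 3 replicates per (treatment, time); one time point
        t = make_table([[500, 500, 500, 1000, 2000, 3000, 5, 10, 15]],
                       times=(3.0,), replicates=3)
        m = group_means(t)
        assert m.loc["F0", ("control", 3.0)] == 500
        assert m.loc["F0", ("unlabeled_tracer", 3.0)] == 2000
        assert m.loc["F0", ("labeled_tracer", 3.0)] == 10

    def test_matches_per_cell_loop(self, small_sim):
        table, _ = small_sim
        m = group_means(table)
        design = table.design
        rng = np.random.default_rng(0)
        for fid in rng.choice(table.feature_ids(), size=10, replace=False):
            for (trt, t), expected in m.loc[fid].items():
                vals = []
                for _, row in design.iterrows():
                    if row["treatment"] == trt and row["time_h"] == t:
                        vals.append(table.intensities.loc[fid, row["sample_id"]])
                manual = sum(v for v in vals if not np.isnan(v)) / max(
                    1, sum(0 if np.isnan(v) else 1 for v in vals))
                if all(np.isnan(v) for v in vals):
                    assert np.isnan(expected)
                else:
                    assert expected == pytest.approx(manual)

    def test_permutation_invariance_over_replicates(self):
        t = make_table([[1, 2, 3, 4, 5, 6, 7, 8, 9]], times=(3.0,), replicates=3)
        perm = make_table([[3, 1, 2, 6, 4, 5, 9, 7, 8]], times=(3.0,), replicates=3)
        pd.testing.assert_frame_equal(group_means(t), group_means(perm))
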
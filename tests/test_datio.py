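import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import tilp
from tilp.datio import LogRatioMatrix, read_profile, write_profile


def matrix(values, proteins=None, conditions=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    proteins = proteins or [f"p{i}" for i in range(arr.shape[0])]
    conditions = conditions or [f"k{i}" for i in range(arr.shape[1])]
    return LogRatioMatrix(pd.DataFrame(arr, index=proteins, columns=conditions))


@pytest.mark.parametrize(
    "rho, expected",
    [
        (0.5, 1),  # 0.5 >= log2(1.2) ~ 0.263
        (0.0, 0),
        (-1.0, -1),
        (math.log2(1.2), 1),  # boundary is inclusive
        (-math.log2(1.2), -1),
        (0.2, 0),  # inside the dead zone
    ],
)
def test_ternarize_rule_at_default_threshold(rho, expected):
    profile = tilp.ternarize(matrix([[rho]]), threshold=1.2)
    assert profile.state("p0", "k0") == expected


def test_ternarize_rejects_threshold_at_or_below_one():
    with pytest.raises(ValueError):
        tilp.ternarize(matrix([[0.5]]), threshold=1.0)
    with pytest.raises(ValueError):
        tilp.ternarize(matrix([[0.5]]), threshold=0.9)


def test_ternarize_keeps_missing_entries():
    profile = tilp.ternarize(matrix([[np.nan, 0.5]]))
    assert profile.state("p0", "k0") is None
    assert profile.state("p0", "k1") == 1


@settings(deadline=None, derandomize=True, max_examples=60)
@given(
    rho=st.floats(-4, 4, allow_nan=False),
    threshold=st.floats(1.01, 3.0),
)
def test_ternarize_odd_symmetry_and_sign(rho, threshold):
    up = tilp.ternarize(matrix([[rho]]), threshold).state("p0", "k0")
    down = tilp.ternarize(matrix([[-rho]]), threshold).state("p0", "k0")
    assert up == -down
    if up != 0:
        assert up == (1 if rho > 0 else -1)


def test_ternarize_monotone_in_rho():
    rhos = np.linspace(-2, 2, 41)
    states = tilp.ternarize(matrix([rhos.tolist()]), 1.2).values.to_numpy()[0]
    assert (np.diff(states) >= 0).all()


def test_threshold_near_one_maps_every_nonzero_to_its_sign():
    profile = tilp.ternarize(matrix([[0.01, -0.01, 0.0]]), threshold=1.0000001)
    assert list(profile.values.iloc[0]) == [1, -1, 0]


def test_select_deps():
    prof = tilp.ternarize(matrix([[0.5, 0.0], [0.1, -0.1], [0.0, -0.9]]))
    assert tilp.select_deps(prof) == ["p0", "p2"]
    zero = tilp.ternarize(matrix([[0.0, 0.0]]))
    assert tilp.select_deps(zero) == []


def test_read_matrix_tsv_and_csv(tmp_path):
    tsv = tmp_path / "m.tsv"
    tsv.write_text("id\tk1\tk2\nA\t0.5\t-0.3\nB\t1.0\t0.0\n")
    m = tilp.read_matrix(tsv)
    assert m.values.shape == (2, 2)
    assert m.values.at["A", "k2"] == -0.3
    csv = tmp_path / "m.csv"
    csv.write_text("id,k1\nA,0.25\n")
    assert tilp.read_matrix(csv).values.at["A", "k1"] == 0.25


def test_read_matrix_rejects_duplicate_rows(tmp_path):
    csv = tmp_path / "dup.csv"
    csv.write_text("id,k1\nA,0.1\nA,0.2\n")
    with pytest.raises(ValueError, match="duplicate protein rows"):
        tilp.read_matrix(csv)


def test_read_matrix_averages_replicate_columns(tmp_path):
    tsv = tmp_path / "rep.tsv"
    tsv.write_text("id\tk1\tk1\nA\t0.2\t0.4\n")
    m = tilp.read_matrix(tsv)
    assert m.conditions == ["k1"]
    assert m.values.at["A", "k1"] == pytest.approx(0.3)


def test_read_gct_skips_metadata(tmp_path):
    gct = tmp_path / "m.gct"
    gct.write_text(
        "#1.3\n2\t2\t1\t1\n"
        "id\tdesc\tk1\tk2\n"
        "meta\t-\tx\ty\n"
        "A\tfoo\t0.5\t-0.5\n"
        "B\tbar\t1.5\t0.0\n"
    )
    m = tilp.read_matrix(gct, format="gct")
    assert m.values.shape == (2, 2)
    assert m.values.at["B", "k1"] == 1.5


def test_read_gct_dimension_mismatch(tmp_path):
    gct = tmp_path / "bad.gct"
    gct.write_text("#1.3\n3\t2\t0\t0\nid\tk1\tk2\nA\t1\t2\n")
    with pytest.raises(ValueError, match="dimension mismatch"):
        tilp.read_matrix(gct, format="gct")


def test_read_prior(tmp_path):
    prior_file = tmp_path / "prior.tsv"
    prior_file.write_text(
        "condition\tnode\tdirection\n"
        "fulvestrant\tER\tdown\n"
        "staurosporine\tPKC\t-1\n"
        "paclitaxel\tJNK\tup\n"
    )
    prior = tilp.read_prior(prior_file)
    assert prior.for_condition("fulvestrant") == {"ER": -1}
    assert prior.for_condition("staurosporine") == {"PKC": -1}
    assert prior.for_condition("paclitaxel") == {"JNK": 1}


def test_read_prior_rejects_bad_direction_and_duplicates(tmp_path):
    f = tmp_path / "p.tsv"
    f.write_text("condition\tnode\tdirection\nc\tA\tsideways\n")
    with pytest.raises(ValueError, match="direction token"):
        tilp.read_prior(f)
    f.write_text("condition\tnode\tdirection\nc\tA\tup\nc\tA\tdown\n")
    with pytest.raises(ValueError, match="duplicate prior"):
        tilp.read_prior(f)


def test_read_prior_empty_with_header(tmp_path):
    f = tmp_path / "p.tsv"
    f.write_text("condition\tnode\tdirection\n")
    assert len(tilp.read_prior(f)) == 0


def test_packaged_prior_table():
    from importlib import resources

    with resources.as_file(
        resources.files("tilp.data") / "mcf7_prior.tsv"
    ) as path:
        prior = tilp.read_prior(path)
    assert prior.for_condition("fulvestrant") == {"ER": -1}
    assert prior.for_condition("staurosporine") == {"PKC": -1}
    assert all(r.direction in (-1, 1) for r in prior.records)


def test_profile_round_trip(tmp_path):
    prof = tilp.ternarize(matrix([[0.5, np.nan], [-0.9, 0.0]]))
    path = tmp_path / "prof.tsv"
    write_profile(prof, path)
    back = read_profile(path)
    assert back.state("p0", "k0") == 1
    assert back.state("p0", "k1") is None
    assert back.state("p1", "k0") == -1
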
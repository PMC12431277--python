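"""Phenotype-table IO, design inference, QC and descriptive statistics."""

import numpy as np
import pandas as pd
import pytest

from ncii import (
    PhenotypeTable,
    compare_populations,
    descriptive_stats,
    flag_outliers,
    read_phenotype_table,
    validate_design,
)
from ncii.errors import (
    DesignError,
    InsufficientDataError,
    SchemaError,
    ValidationError,
)

from conftest import COLS, make_table


def _toy_csv(tmp_path):
    rows = [
        ("P1", "parent", None, None, 2019, 1, "Zn", 50.0),
        ("P2", "parent", None, None, 2019, 1, "Zn", 60.0),
        ("P1xP2", "hybrid", "P1", "P2", 2019, 1, "Zn", 70.0),
        ("P1xP2", "hybrid", "P1", "P2", 2019, 2, "Zn", 72.0),
    ]
    path = tmp_path / "toy.csv"
    pd.DataFrame(rows, columns=COLS).to_csv(path, index=False)
    return path


def test_read_write_roundtrip(tmp_path):
    table = read_phenotype_table(_toy_csv(tmp_path))
    assert len(table) == 4
    assert set(table.hybrids["genotype"]) == {"P1xP2"}
    out = tmp_path / "out.csv"
    table.write_csv(out)
    again = read_phenotype_table(out)
    pd.testing.assert_frame_equal(table.frame, again.frame)
    # normalized tables round-trip bit-identically
    out2 = tmp_path / "out2.csv"
    again.write_csv(out2)
    assert out.read_bytes() == out2.read_bytes()


def test_schema_map_and_missing_file(tmp_path):
    path = tmp_path / "alien.csv"
    pd.DataFrame(
        {
            "geno": ["P1", "P2"],
            "gen": ["parent", "parent"],
            "mum": [None, None],
            "dad": [None, None],
            "yr": [2019, 2019],
            "block": [1, 1],
            "element": ["zinc", "Zn"],
            "conc": [50.0, 60.0],
        }
    ).to_csv(path, index=False)
    schema = dict(
        genotype="geno", generation="gen", female="mum", male="dad",
        year="yr", rep="block", trait="element", value="conc",
    )
    table = read_phenotype_table(path, schema=schema)
    assert table.traits == ("Zn",)
    with pytest.raises(SchemaError):
        read_phenotype_table(tmp_path / "nope.csv")
    with pytest.raises(SchemaError):
        read_phenotype_table(path, schema={**schema, "value": "missing_col"})


@pytest.mark.parametrize(
    "mutate, err",
    [
        (lambda df: df.drop(columns=["value"]), SchemaError),
        (lambda df: pd.concat([df, df.iloc[[0]]]), ValidationError),  # dup key
        (lambda df: df.assign(value=[-3.0] + list(df["value"][1:])), ValidationError),
        (lambda df: df.assign(value=["abc"] + list(df["value"][1:])), ValidationError),
        # hybrid referencing an unknown parent
        (
            lambda df: df.assign(female=["P9" if f == "P1" else f for f in df["female"]]),
            ValidationError,
        ),
        (lambda df: df.assign(generation=df["generation"].replace("parent", "elite")),
         ValidationError),
    ],
)
def test_validation_errors(tmp_path, mutate, err):
    base = pd.read_csv(_toy_csv(tmp_path))
    with pytest.raises(err):
        PhenotypeTable(mutate(base))


def test_validate_design_paper_shape(paper_shaped_table):
    design = validate_design(paper_shaped_table)
    assert len(design.females) == 12
    assert len(design.males) == 14
    assert design.n_crosses == 118
    assert design.is_connected()
    assert sum(design.cross_counts().values()) == 2 * 118


def test_validate_design_full_factorial():
    rows = []
    for f in ("F1", "F2"):
        for m in ("M1", "M2"):
            rows.append((f"{f}x{m}", "hybrid", f, m, 2019, 1, "Ca", 10.0))
    for p in ("F1", "F2", "M1", "M2"):
        rows.append((p, "parent", None, None, 2019, 1, "Ca", 9.0))
    design = validate_design(make_table(rows))
    assert design.n_crosses == 4
    assert all(c == 2 for c in design.cross_counts().values())


def test_validate_design_both_sex_token():
    rows = [
        ("A", "parent", None, None, 2019, 1, "Ca", 9.0),
        ("B", "parent", None, None, 2019, 1, "Ca", 9.0),
        ("C", "parent", None, None, 2019, 1, "Ca", 9.0),
        ("AxB", "hybrid", "A", "B", 2019, 1, "Ca", 10.0),
        ("BxC", "hybrid", "B", "C", 2019, 1, "Ca", 10.0),  # B on both sides
    ]
    with pytest.raises(DesignError):
        validate_design(make_table(rows))


def _clean_qc_table(seed=7, n_geno=25, shift=None):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_geno):
        for k in (1, 2, 3, 4):
            rows.append(
                (f"G{i:02d}", "parent", None, None, 2019, k, "Ca",
                 20.0 + rng.normal(0, 1.0))
            )
    df = pd.DataFrame(rows, columns=COLS)
    if shift is not None:
        idx, sd_mult = shift
        df.loc[idx, "value"] = df["value"].mean() + sd_mult * df["value"].std()
    return PhenotypeTable(df)


def test_flag_outliers_clean_data_no_flags():
    report = flag_outliers(_clean_qc_table(seed=7))
    assert report.n_flagged == 0


def test_flag_outliers_gross_error_detected():
    table = _clean_qc_table(seed=7, shift=(17, 10.0))
    report = flag_outliers(table)
    assert report.n_flagged == 1
    assert report.flags.iloc[0]["row"] == 17
    assert report.flags.iloc[0]["p_adj"] < 0.05


def test_flag_outliers_alpha_zero_never_flags():
    table = _clean_qc_table(seed=7, shift=(17, 10.0))
    assert flag_outliers(table, alpha=0.0).n_flagged == 0


def test_flag_outliers_insufficient_data():
    rows = [
        ("A", "parent", None, None, 2019, 1, "Ca", 10.0),
        ("A", "parent", None, None, 2019, 2, "Ca", 11.0),
    ]
    with pytest.raises(InsufficientDataError):
        flag_outliers(make_table(rows))


def test_descriptive_stats_values_and_pooling():
    const = make_table(
        [("A", "parent", None, None, 2019, k, "Ca", 5.0) for k in range(1, 5)]
    )
    row = descriptive_stats(const).loc[("parent", "Ca")]
    assert row["mean"] == 5.0 and row["cv_pct"] == 0.0 and row["se"] == 0.0

    vec = make_table(
        [("A", "parent", None, None, 2019, k, "Ca", float(v))
         for k, v in enumerate([1, 2, 3, 4], start=1)]
    )
    row = descriptive_stats(vec).loc[("parent", "Ca")]
    assert row["mean"] == pytest.approx(2.5)
    assert row["se"] == pytest.approx(0.6455, abs=1e-4)
    assert row["cv_pct"] == pytest.approx(51.64, abs=0.01)


def test_descriptive_stats_balanced_year_pooling(paper_shaped_table):
    """On balanced data the pooled mean equals the average of per-year means."""
    stats_all = descriptive_stats(paper_shaped_table)
    sub = paper_shaped_table.frame
    per_year = sub.groupby(["generation", "trait", "year"])["value"].mean()
    for (gen, trait), row in stats_all.iterrows():
        yearly = per_year.loc[gen, trait]
        assert row["mean"] == pytest.approx(yearly.mean(), rel=1e-12)
    # invariant to row order
    shuffled = PhenotypeTable(
        paper_shaped_table.frame.sample(frac=1, random_state=0).reset_index(drop=True)
    )
    pd.testing.assert_frame_equal(stats_all, descriptive_stats(shuffled))


def test_descriptive_stats_empty_group():
    single = make_table([("A", "parent", None, None, 2019, 1, "Ca", 5.0)])
    with pytest.raises(InsufficientDataError):
        descriptive_stats(single)


def test_compare_populations_no_difference():
    rng = np.random.default_rng(0)
    vals = rng.normal(10, 1, 30)
    rows = [("P%d" % i, "parent", None, None, 2019, 1, "Ca", v)
            for i, v in enumerate(vals)]
    rows += [("AxB%d" % i, "hybrid", "P0", "P1", 2019, 1, "Ca", v)
             for i, v in enumerate(vals)]
    # hybrids need valid parents; reuse P0/P1 as parents of all
    c = compare_populations(make_table(rows), "Ca")
    assert c.p > 0.9
    assert c.stars == ""


def test_compare_populations_large_shift():
    rng = np.random.default_rng(1)
    rows = [(f"P{i}", "parent", None, None, 2019, 1, "Ca", max(v, 0))
            for i, v in enumerate(rng.normal(10, 1, 200))]
    rows += [(f"H{i}", "hybrid", "P0", "P1", 2019, 1, "Ca", max(v, 0))
             for i, v in enumerate(rng.normal(11, 1, 200))]
    c = compare_populations(make_table(rows), "Ca")
    assert c.p < 0.001
    assert c.stars == "***"


def test_compare_populations_too_few():
    rows = [("P1", "parent", None, None, 2019, 1, "Ca", 10.0),
            ("P2", "parent", None, None, 2019, 1, "Ca", 11.0),
            ("H1", "hybrid", "P1", "P2", 2019, 1, "Ca", 12.0)]
    with pytest.raises(InsufficientDataError):
        compare_populations(make_table(rows), "Ca")
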
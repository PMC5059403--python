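"""Model/results interface, full pipeline and report rendering."""

import numpy as np
import pandas as pd
import pytest

import lastsight as ls
from lastsight.errors import UsageError
from lastsight.pipeline import AnalysisConfig, render_report, report_from_json, run_full_analysis


@pytest.fixture(scope="module")
def fast_config():
    return AnalysisConfig(iters=400, seed=1)


@pytest.fixture(scope="module")
def full_report(reference_records, fast_config):
    return run_full_analysis(reference_records, config=fast_config)


def test_model_fit_runs_all_methods(variants):
    res = ls.ExtinctionModel.from_records(variants["include_poz"]).fit(iters=300, seed=0)
    assert set(res.estimates) == set(ls.METHODS)
    assert not res.errors
    assert res["solow_roberts"].bound95 == pytest.approx(9_462.0, abs=1e-6)
    df = res.to_frame()
    assert len(df) == len(ls.METHODS)


def test_model_from_dataframe_matches_from_records(variants):
    df = variants["include_gda"].to_frame()
    a = ls.ExtinctionModel.from_dataframe(df).fit(methods=["strauss_sadler"])
    b = ls.ExtinctionModel.from_records(variants["include_gda"]).fit(methods=["strauss_sadler"])
    assert a["strauss_sadler"].bound95 == b["strauss_sadler"].bound95


def test_model_summary_mentions_methods_and_flags(variants):
    res = ls.ExtinctionModel.from_records(variants["include_poz"]).fit(
        methods=["solow_roberts", "griwm"], iters=200, seed=0
    )
    text = res.summary()
    assert "solow_roberts" in text and "griwm" in text
    assert "9,462" in text


def test_per_method_failures_are_captured_not_raised():
    s = ls.SightingSeries(np.array([1_000.0, 1_001.0]))  # saturates McInerny-type rates
    res = ls.ExtinctionModel(s).fit(methods=["mcinerny", "strauss_sadler"])
    assert "mcinerny" in res.errors
    assert "strauss_sadler" in res.estimates


def test_pipeline_solow_roberts_row(full_report):
    sr = {r["variant"]: r["bound95"] for r in full_report.rows if r["method"] == "solow_roberts"}
    assert sr["include_poz"] == pytest.approx(9_462.0, abs=1e-6)
    assert sr["include_gda"] == pytest.approx(25_474.0, abs=1e-6)
    assert sr["conservative"] == pytest.approx(8_788.0, abs=1e-6)


def test_pipeline_rows_cover_all_cells(full_report):
    assert len(full_report.rows) == len(ls.METHODS) * 3
    assert all(r["error"] is None for r in full_report.rows)
    assert full_report.density["include_poz"]["family"] in ls.density.FAMILIES
    assert "argmax" in full_report.density["averaged"]


def test_pipeline_deterministic(reference_records, fast_config):
    a = run_full_analysis(reference_records, config=fast_config)
    b = run_full_analysis(reference_records, config=fast_config)
    assert render_report(a, "json") == render_report(b, "json")


def test_pipeline_empty_records_yields_diagnostic():
    rep = run_full_analysis(ls.RecordSet([]))
    assert rep.rows == []
    assert "diagnostic" in rep.metadata


def test_pipeline_requires_curve_for_uncalibrated_records():
    rs = ls.RecordSet([ls.SightingRecord(lab_code="U-1", c14_age=20_000.0, c14_err=100.0)])
    with pytest.raises(UsageError):
        run_full_analysis(rs)


def test_pipeline_calibrates_with_curve(identity_curve):
    rs = ls.RecordSet(
        [
            ls.SightingRecord(lab_code=f"U-{i}", c14_age=20_000.0 + 500.0 * i, c14_err=100.0)
            for i in range(6)
        ]
    )
    cfg = AnalysisConfig(methods=("strauss_sadler",), variants=("include_poz",), iters=10)
    rep = run_full_analysis(rs, curve=identity_curve, config=cfg)
    row = rep.rows[0]
    assert row["error"] is None
    assert row["bound95"] < 20_000.0


def test_solow_roberts_cell_ignores_older_record_changes(reference_records, fast_config):
    mutated = []
    for r in reference_records:
        if r.cal_mean > 27_000.0:
            mutated.append(ls.records._replace(r, cal_mean=r.cal_mean + 333.0))
        else:
            mutated.append(r)
    mrs = ls.RecordSet(mutated)
    cfg = AnalysisConfig(methods=("solow_roberts",), iters=10)
    a = run_full_analysis(reference_records, config=cfg)
    b = run_full_analysis(mrs, config=cfg)
    cell = lambda rep, v: [
        r["bound95"] for r in rep.rows if r["method"] == "solow_roberts" and r["variant"] == v
    ][0]
    for v in ("include_poz", "include_gda"):
        assert cell(a, v) == cell(b, v)


def test_render_tsv_shape_and_formatting(full_report):
    tsv = render_report(full_report, "tsv")
    lines = tsv.strip().split("\n")
    assert lines[0].split("\t") == ["method", "include_poz", "include_gda", "conservative"]
    assert len(lines) == 1 + len(ls.METHODS)
    cells = dict(zip(lines[0].split("\t"), [l.split("\t") for l in lines if l.startswith("solow_roberts")][0]))
    assert cells["include_poz"] == "9,462"
    griwm_line = [l for l in lines if l.startswith("griwm")][0]
    assert "(" in griwm_line and "–" in griwm_line  # median (hi–lo) formatting


def test_render_json_roundtrip(full_report):
    text = render_report(full_report, "json")
    back = report_from_json(text)
    assert back == full_report


def test_render_unknown_format(full_report):
    with pytest.raises(UsageError):
        render_report(full_report, "xml")


def test_pipeline_correlation_with_synthetic_proxy(reference_records):
    # proxy on a wide window so coverage is guaranteed
    t = np.arange(45_000.0, 4_000.0, -20.0)
    rng = np.random.default_rng(0)
    proxy = ls.ProxySeries(t[::-1], rng.standard_normal(len(t))[::-1])
    cfg = AnalysisConfig(methods=("solow_roberts",), iters=10, window=(34_510.0, 25_250.0))
    rep = run_full_analysis(reference_records, proxy=proxy, config=cfg)
    assert len(rep.correlations) == 1
    assert rep.correlations[0]["n"] == 464
    assert -1.0 <= rep.correlations[0]["r"] <= 1.0
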
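"""Paired Wilcoxon, BH-FDR, network comparison, and the pipeline."""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cardionet as cn
from cardionet.network import CausalityNetwork


def test_wilcoxon_identical_samples_degenerate():
    x = np.arange(10.0)
    with pytest.warns(UserWarning, match="zero"):
        _w, p = cn.wilcoxon_signed_rank(x, x)
    assert p == 1.0


def test_wilcoxon_exact_enumeration_oracle():
    """n=6, all differences positive and distinct: p = 2/64 exactly."""
    x = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
    y = np.array([1.0, 1.5, 2.0, 2.5, 3.0, 3.5])
    _w, p = cn.wilcoxon_signed_rank(x, y)
    assert p == pytest.approx(2.0 / 64.0)


@pytest.mark.parametrize("n", [8, 15, 25])
def test_wilcoxon_matches_scipy_exact(n):
    rng = np.random.default_rng(n)
    x = rng.standard_normal(n)
    y = x + 0.5 * rng.standard_normal(n) + 0.3
    w, p = cn.wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(x, y, zero_method="wilcox", method="exact")
    assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_wilcoxon_large_n_normal_approximation():
    rng = np.random.default_rng(1)
    x = rng.standard_normal(60)
    y = x + 0.4 * rng.standard_normal(60) + 0.2
    _w, p = cn.wilcoxon_signed_rank(x, y)
    ref = sps.wilcoxon(x, y, zero_method="wilcox", method="approx", correction=True)
    assert p == pytest.approx(ref.pvalue, rel=0.02)


def test_bh_fdr_worked_example():
    reject, p_adj = cn.bh_fdr([0.001, 0.01, 0.02, 0.04, 0.2], q=0.05)
    assert reject.sum() == 4
    assert list(reject) == [True, True, True, True, False]
    assert np.all(np.diff(p_adj[np.argsort([0.001, 0.01, 0.02, 0.04, 0.2])]) >= 0)


def test_bh_fdr_edge_cases():
    reject, _ = cn.bh_fdr([1.0] * 5)
    assert reject.sum() == 0
    reject, _ = cn.bh_fdr([0.04])
    assert reject.sum() == 1
    with pytest.raises(ValueError):
        cn.bh_fdr([0.5, 1.5])


def _toy_networks(seed=0, shift=0.0, n_subjects=12):
    """Two 4-node cohort networks with an M->H offset in the second."""
    rng = np.random.default_rng(seed)
    nodes = ("R", "H", "M", "C")
    rows_a, rows_b = [], []
    for s in range(n_subjects):
        for tgt in nodes:
            for src in nodes:
                if src == tgt:
                    continue
                base = rng.uniform(0.01, 0.2)
                rows_a.append(
                    {"subject": f"S{s:02d}", "condition": "REST", "estimator": "mb",
                     "source": src, "target": tgt, "T": base}
                )
                rows_b.append(
                    {"subject": f"S{s:02d}", "condition": "HUT", "estimator": "mb",
                     "source": src, "target": tgt,
                     "T": base + rng.normal(0, 0.01)
                     + (shift if (src, tgt) == ("M", "H") else 0.0)}
                )
    net_a = CausalityNetwork("mb", "REST", nodes, pd.DataFrame(rows_a))
    net_b = CausalityNetwork("mb", "HUT", nodes, pd.DataFrame(rows_b))
    return net_a, net_b


def test_compare_networks_identical_cohorts_no_rejections():
    net_a, net_b = _toy_networks(seed=3, shift=0.0)
    # identical values -> all-zero differences -> degenerate p = 1
    net_b.links["T"] = net_a.links["T"].values
    with pytest.warns(UserWarning):
        comp = cn.compare_networks(net_a, net_b)
    assert comp.table["reject"].sum() == 0


def test_compare_networks_detects_shift_with_direction():
    net_a, net_b = _toy_networks(seed=4, shift=0.15)
    comp = cn.compare_networks(net_a, net_b)
    row = comp.table[(comp.table.source == "M") & (comp.table.target == "H")].iloc[0]
    assert row.reject and row.direction == "HUT>REST"
    # the shifted link dominates the family (BH may drag a few small noise
    # p-values along with a true positive; that is expected step-up behaviour)
    assert row.p == comp.table["p"].min()


def test_compare_networks_antisymmetry():
    net_a, net_b = _toy_networks(seed=5, shift=0.12)
    fwd = cn.compare_networks(net_a, net_b)
    net_a.condition, net_b.condition = "HUT", "REST"
    rev = cn.compare_networks(net_b, net_a)
    merged = fwd.table.merge(rev.table, on=["source", "target"], suffixes=("_f", "_r"))
    assert np.allclose(merged["p_f"], merged["p_r"])
    for _i, r in merged.iterrows():
        if r.direction_f == "HUT>REST":
            assert r.direction_r == "HUT<REST"
        elif r.direction_f == "HUT<REST":
            assert r.direction_r == "HUT>REST"


def test_bh_adjusted_p_monotone_in_raw_order():
    rng = np.random.default_rng(9)
    p = rng.uniform(0, 1, 12)
    _rej, p_adj = cn.bh_fdr(p)
    order = np.argsort(p)
    assert np.all(np.diff(p_adj[order]) >= -1e-15)


def test_run_pipeline_mb_only_writes_outputs(tmp_path):
    cfg = cn.PipelineConfig(
        seed=77,
        output_dir=str(tmp_path / "run1"),
        n_subjects=6,
        estimators=("mb",),
        n_surrogates=20,
    )
    result = cn.run_pipeline(cfg)
    out = Path(result["output_dir"])
    for fname in [
        "markers.csv",
        "links_mb_REST.csv",
        "links_mb_HUT.csv",
        "significance_mb_REST.csv",
        "summary_mb_REST.csv",
        "comparison_mb.csv",
        "network_mb_REST.json",
        "run_log.json",
        "cohort/manifest.json",
        "cohort/ground_truth.json",
    ]:
        assert (out / fname).exists(), fname
    links = pd.read_csv(out / "links_mb_REST.csv")
    assert len(links) == 6 * 12
    net = json.loads((out / "network_mb_REST.json").read_text())
    assert len(net["links"]) == 12 and all("s" in l for l in net["links"])


def test_run_pipeline_rerun_is_byte_identical(tmp_path):
    base = dict(seed=11, n_subjects=6, estimators=("mb",), n_surrogates=10)
    cfg1 = cn.PipelineConfig(output_dir=str(tmp_path / "a"), **base)
    cfg2 = cn.PipelineConfig(output_dir=str(tmp_path / "b"), **base)
    out1 = Path(cn.run_pipeline(cfg1)["output_dir"])
    out2 = Path(cn.run_pipeline(cfg2)["output_dir"])
    for f1 in sorted(out1.rglob("*")):
        if f1.is_dir():
            continue
        f2 = out2 / f1.relative_to(out1)
        b1, b2 = f1.read_bytes(), f2.read_bytes()
        if f1.name == "run_log.json":
            # differs only in the configured output path
            b1 = b1.replace(str(out1).encode(), b"X")
            b2 = b2.replace(str(out2).encode(), b"X")
        assert b1 == b2, f1.name


def test_pipeline_config_rejects_unknown_fields(tmp_path):
    path = tmp_path / "cfg.yaml"
    path.write_text("seed: 1\nbogus_field: 2\n")
    with pytest.raises(ValueError, match="bogus_field"):
        cn.PipelineConfig.from_file(path)


def test_series_roundtrip(tmp_path, rest_subject):
    p = rest_subject.to_csv(tmp_path / "s.csv")
    back = cn.BeatSeries.from_csv(p)
    assert back.nodes == rest_subject.nodes
    assert np.allclose(back.values, rest_subject.values, atol=1e-9)


def test_cli_simulate_and_estimate_roundtrip(tmp_path):
    from click.testing import CliRunner

    from cardionet.cli import main

    runner = CliRunner()
    out = tmp_path / "cohort"
    r = runner.invoke(main, ["simulate", "--n-subjects", "2", "--seed", "3",
                             "--out", str(out)])
    assert r.exit_code == 0, r.output
    assert (out / "manifest.json").exists()
    links = tmp_path / "links.csv"
    r = runner.invoke(main, ["estimate", str(out / "manifest.json"),
                             "--estimator", "mb", "--out", str(links)])
    assert r.exit_code == 0, r.output
    table = pd.read_csv(links)
    assert len(table) == 2 * 2 * 12  # subjects x conditions x links
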
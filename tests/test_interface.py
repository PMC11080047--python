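"""File formats, pipeline orchestration and the command-line interface."""

import json
import warnings

import numpy as np
import pytest
from click.testing import CliRunner

from glasspharm import io
from glasspharm.cli import main
from glasspharm.pipeline import analyze_bds, build_relaxation_report
from glasspharm.relaxation_map import arrhenius_tau, ArrheniusParams, vft_tau, VFTParams
from glasspharm.synthetic_data import BDSScenario, DSCScenario, simulate_bds, simulate_dsc


@pytest.fixture(scope="module")
def small_bds(tmp_path_factory):
    path = tmp_path_factory.mktemp("bds") / "loss.csv"
    sc = BDSScenario(noise_rel=0.0, compositions=(0.0,))
    io.write_loss_table(simulate_bds(sc, seed=1), path)
    return path


class TestLossTableRoundTrip:
    def test_lossless(self, tmp_path):
        sc = BDSScenario(compositions=(0.0, 30.0))
        spectra = simulate_bds(sc, seed=2)
        path = tmp_path / "loss.csv"
        io.write_loss_table(spectra, path)
        back = io.read_loss_table(path)
        assert len(back) == len(spectra)
        key = lambda s: (s.sample_id, s.temperature)
        for a, b in zip(sorted(spectra, key=key), sorted(back, key=key)):
            assert a.temperature == b.temperature
            assert a.silica_wt_pct == b.silica_wt_pct
            np.testing.assert_allclose(a.loss, b.loss, rtol=1e-12)

    def test_missing_column_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("sample_id,temperature_K\nx,300\n")
        with pytest.raises(io.ParseError, match="missing required column"):
            io.read_loss_table(p)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "sample_id,silica_wt_pct,temperature_K,frequency_Hz,eps_loss\n"
            "x,0,300,1.0,0.5\nx,0,300,2.0,oops\n"
        )
        with pytest.raises(io.ParseError, match="line 3"):
            io.read_loss_table(p)


class TestDSCTableRoundTrip:
    def test_lossless_with_metadata(self, tmp_path):
        trace = simulate_dsc(DSCScenario(silica_wt_pct=10.0), seed=1)
        path = tmp_path / "dsc.csv"
        io.write_dsc_table([trace], path)
        (back,) = io.read_dsc_table(path)
        np.testing.assert_allclose(back.heat_flow, trace.heat_flow, rtol=1e-12)
        assert back.heating_rate == trace.heating_rate
        assert back.drug_mass_fraction == pytest.approx(trace.drug_mass_fraction)

    def test_endo_up_flag_flips_sign(self, tmp_path):
        trace = simulate_dsc(DSCScenario(), seed=1)
        path = tmp_path / "dsc.csv"
        io.write_dsc_table([trace], path)
        (flipped,) = io.read_dsc_table(path, exo_up=False)
        np.testing.assert_allclose(flipped.heat_flow, -trace.heat_flow)


def test_config_hash_is_stable_and_order_insensitive():
    h1 = io.config_hash({"a": 1, "b": [1, 2]})
    h2 = io.config_hash({"b": [1, 2], "a": 1})
    assert h1 == h2 and len(h1) == 12


class TestPipeline:
    def test_default_scenario_report_reaches_printed_glass_metrics(self):
        # end-to-end: synthetic spectra at the study conditions -> Tg = 303 K
        sc = BDSScenario(noise_rel=0.0, compositions=(0.0,))
        spectra = simulate_bds(sc, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = analyze_bds(spectra)
        assert round(report["Tg_K"]) == 303
        assert report["vft"]["T0"] == pytest.approx(248.0, abs=0.5)
        assert report["beta"]["Ea_kJ_per_mol"] == pytest.approx(80.4, abs=0.5)
        assert report["gamma"]["Ea_kJ_per_mol"] == pytest.approx(23.8, abs=0.5)

    def test_report_from_point_table(self):
        vft = VFTParams(-15.73, 248.0, 2257.0)
        T_l = np.arange(310.0, 342.1, 2.0)
        T_g = np.arange(153.0, 303.1, 10.0)
        import pandas as pd

        rows = [("alpha", T, vft_tau(vft, T)) for T in T_l]
        rows += [("beta", T, arrhenius_tau(ArrheniusParams(-17.57, 80.4), T)) for T in T_g]
        rows += [("gamma", T, arrhenius_tau(ArrheniusParams(-12.39, 23.8), T)) for T in T_g]
        points = pd.DataFrame(rows, columns=["label", "T_K", "tau_s"])
        report = build_relaxation_report(points, beta_kww=0.55)
        assert round(report["Tg_K"]) == 303
        assert report["m_p"] == pytest.approx(97.3, abs=0.5)
        assert report["beta"]["Ea_kJ_per_mol"] == pytest.approx(80.4, abs=0.1)


class TestCLI:
    def test_simulate_and_fit_dsc(self, tmp_path):
        runner = CliRunner()
        dsc = tmp_path / "dsc.csv"
        events = tmp_path / "events.json"
        r = runner.invoke(main, ["simulate-dsc", "--seed", "7", "--out", str(dsc)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["fit-dsc", "--input", str(dsc), "--out", str(events)])
        assert r.exit_code == 0, r.output
        (entry,) = json.loads(events.read_text())
        assert round(entry["glass_transition"]["Tg_mid"]) == 307
        assert round(entry["exotherm"]["onset"]) == 357
        onsets = sorted(round(c["onset"]) for c in entry["melting_components"])
        assert onsets == [406, 410, 414, 421]

    def test_fit_dsc_on_empty_file_fails(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("")
        r = CliRunner().invoke(
            main, ["fit-dsc", "--input", str(empty), "--out", str(tmp_path / "x.json")]
        )
        assert r.exit_code != 0

    def test_masterplot_command(self, small_bds, tmp_path):
        out = tmp_path / "mp"
        r = CliRunner().invoke(
            main,
            ["masterplot", "--input", str(small_bds), "--t-ref", "312", "--out-dir", str(out)],
        )
        assert r.exit_code == 0, r.output
        fit = json.loads((out / "kww_fit.json").read_text())
        assert 0.4 < fit["beta_kww"] < 0.7
        assert (out / "master_curve.tsv").exists() and (out / "shifts.tsv").exists()

    def test_stability_command(self, tmp_path):
        sc = DSCScenario()
        entries = [
            {"silica_wt_pct": w, "delta_cp": sc.delta_cp(w), "tc_onset": sc.tc_onset(w)}
            for w in (0.0, 10.0, 20.0, 30.0, 40.0, 50.0)
        ]
        inp = tmp_path / "series.json"
        inp.write_text(json.dumps(entries))
        out = tmp_path / "stability.json"
        r = CliRunner().invoke(main, ["stability", "--input", str(inp), "--out", str(out)])
        assert r.exit_code == 0, r.output
        rep = json.loads(out.read_text())
        assert rep["mlc"]["w_mlc"] == pytest.approx(65.0, abs=0.1)
        assert rep["crystallization_trend"]["w_critical"] == pytest.approx(27.3, abs=0.5)

    def test_identical_runs_identical_reports(self, tmp_path):
        runner = CliRunner()
        outs = []
        for name in ("a", "b"):
            p = tmp_path / f"{name}.csv"
            runner.invoke(main, ["simulate-dsc", "--seed", "3", "--out", str(p)])
            e = tmp_path / f"{name}.json"
            runner.invoke(main, ["fit-dsc", "--input", str(p), "--out", str(e)])
            outs.append(e.read_text())
        assert outs[0] == outs[1]
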
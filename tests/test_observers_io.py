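import numpy as np
import pytest

from circgenome.model_core import make_default_parameters
from circgenome.observers_io import (RunManifest, build_snapshot, cli,
                                     config_to_dict, load_config,
                                     read_snapshot, read_timeseries,
                                     save_config, write_genome_lengths,
                                     write_snapshot, write_timeseries,
                                     TIMESERIES_COLUMNS)
from circgenome.scenario_runner import (InoculationEvent, ScenarioConfig,
                                        preset, run)
from circgenome.species_classifier import CATEGORY_NAMES, census


@pytest.fixture(scope="module")
def tiny_result():
    cfg = ScenarioConfig(
        parameters=make_default_parameters().replace(N=3, T_NPB=400),
        steps=300, observe_every=100, seed=3,
        inoculations=[InoculationEvent(
            10, [("GAGUCUCU", "linear", 5), ("GAGUCUCU", "circular", 2)])],
        snapshot_steps=[200])
    return run(cfg)


class TestTimeseries:
    def test_row_count_and_header(self, tiny_result, tmp_path):
        path = write_timeseries(tiny_result.censuses, tmp_path / "ts.tsv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + len(tiny_result.censuses)
        header = lines[0].split("\t")
        assert header == list(TIMESERIES_COLUMNS)
        assert "cir_rep" in header and "cir_repcom" in header

    def test_round_trip_values(self, tiny_result, tmp_path):
        path = write_timeseries(tiny_result.censuses, tmp_path / "ts.tsv")
        df = read_timeseries(path)
        last = tiny_result.censuses[-1]
        for cat in CATEGORY_NAMES:
            assert df[cat].iloc[-1] == last.counts[cat]

    def test_empty_stream_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_timeseries([], tmp_path / "ts.tsv")

    def test_genome_lengths_long_format(self, tiny_result, tmp_path):
        path = write_genome_lengths(tiny_result.censuses, tmp_path / "gl.tsv")
        df = read_timeseries(path)
        assert list(df.columns) == ["step", "length", "count"]
        # inoculated 8-nt rings appear at the first observation after step 10
        sub = df[df.step == 100]
        if len(sub):
            assert (sub["length"] >= 8).all()


class TestSnapshots:
    def test_matrix_shape_and_round_trip(self, tiny_result, tmp_path):
        snap = tiny_result.snapshots[0]
        assert snap.precursors.shape == (3, 3)
        path = write_snapshot(snap, tmp_path / "snap.tsv")
        back = read_snapshot(path)
        assert back.step == snap.step
        assert np.array_equal(back.precursors, snap.precursors)
        for name, grid in snap.channels.items():
            assert np.array_equal(back.channels[name], grid)

    def test_channel_sums_equal_global_census(self, tiny_result):
        snap = tiny_result.snapshots[0]
        # rebuild the census at the snapshot step from the stored series
        c = next(x for x in tiny_result.censuses if x.step == snap.step)
        for cat in CATEGORY_NAMES:
            assert int(snap.channels[cat].sum()) == c.counts[cat]

    def test_snapshot_consistency_with_live_state(self, tiny_result):
        p = tiny_result.config.parameters
        snap = build_snapshot(tiny_result.state, p)
        c = census(tiny_result.state, p)
        for cat in CATEGORY_NAMES:
            assert int(snap.channels[cat].sum()) == c.counts[cat]


class TestConfigFiles:
    def test_save_and_load(self, tmp_path):
        cfg = preset("fig7b")
        path = save_config(cfg, tmp_path / "cfg.yaml")
        cfg2 = load_config(path)
        assert config_to_dict(cfg2) == config_to_dict(cfg)


class TestManifest:
    def test_contains_replay_information(self, tmp_path):
        cfg = preset("fig2a_scaled")
        m = RunManifest(config=config_to_dict(cfg), seed=cfg.seed,
                        version="0.1.0", start_step=0, end_step=100,
                        outputs={"timeseries": "timeseries.tsv"})
        path = m.write(tmp_path / "manifest.yaml")
        import yaml
        data = yaml.safe_load(path.read_text())
        assert data["seed"] == cfg.seed
        assert data["config"]["parameters"]["P_SP"] == 0.5
        assert data["outputs"]["timeseries"] == "timeseries.tsv"


class TestCli:
    def test_run_writes_outputs(self, tmp_path):
        out = tmp_path / "d"
        rc = cli(["run", "--preset", "fig2a_scaled", "--seed", "1",
                  "--steps", "300", "--observe-every", "100",
                  "--snapshot-at", "200", "--out", str(out)])
        assert rc == 0
        assert (out / "timeseries.tsv").exists()
        assert (out / "genome_lengths.tsv").exists()
        assert (out / "manifest.yaml").exists()
        assert (out / "snapshot_200.tsv").exists()

    def test_presets_listing(self, capsys):
        assert cli(["presets"]) == 0
        text = capsys.readouterr().out
        for name in ("fig2a", "fig7b", "s2", "fig2a_scaled"):
            assert name in text

    def test_validate_config(self):
        assert cli(["validate", "--preset", "fig4b"]) == 0

    def test_replicates_summary(self, tmp_path, capsys):
        out = tmp_path / "reps"
        rc = cli(["replicates", "--preset", "fig2a_scaled", "--seeds",
                  "1..2", "--steps", "200", "--observe-every", "100",
                  "--out", str(out)])
        assert rc == 0
        assert (out / "summary.tsv").exists()
        assert (out / "seed_1" / "timeseries.tsv").exists()
        text = capsys.readouterr().out
        assert "modal final genome length" in text

    def test_bad_flags_fail(self):
        assert cli(["run", "--out", "/tmp/x"]) != 0
        assert cli(["nonsense"]) != 0
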
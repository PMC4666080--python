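"""Built-in fixtures, file formats, the pipeline and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import rnabd as rb
from rnabd import io as rio
from rnabd.cli import main as cli_main


class TestFixtures:
    def test_trna_architecture(self):
        ss, arms = rb.load_fixture("trna_phe")
        assert ss.n_residues == 76
        assert [h.n_bp for h in ss.helices] == [7, 4, 5, 5]
        faces = ss.loop_faces()
        assert sum(f["kind"] == "hairpin" for f in faces) == 3
        assert sum(f["kind"] == "multiloop" for f in faces) == 1
        assert arms is not None
        # acceptor stem beads are the terminal 7-bp duplex
        assert set(arms.stem_a) == set(range(0, 7)) | set(range(65, 72))
        # anticodon stem beads flank the anticodon loop
        assert set(arms.stem_b) == set(range(26, 31)) | set(range(38, 43))

    def test_5s_architecture(self):
        ss, arms = rb.load_fixture("5s_rrna")
        assert ss.n_residues == 120
        assert ss.n_helices == 5
        faces = ss.loop_faces()
        assert sum(f["kind"] == "hairpin" for f in faces) == 2
        assert sum(f["kind"] == "internal" for f in faces) == 2
        assert sum(f["kind"] == "multiloop" for f in faces) == 1
        assert arms is None

    def test_fixture_roundtrip_preserves_pairing(self, tmp_path):
        for name in rb.FIXTURES:
            ss, _ = rb.load_fixture(name)
            path = tmp_path / f"{name}.tsv"
            rb.write_helix_table(ss, path)
            assert rb.read_helix_table(path).pair_table().tolist() == \
                ss.pair_table().tolist()

    def test_unknown_fixture(self):
        with pytest.raises(KeyError, match="trna_phe"):
            rb.load_fixture("nope")


class TestIO:
    def test_xyz_roundtrip_at_printed_precision(self, tmp_path, rng):
        conf = rb.Conformation(rng.uniform(-50, 50, (20, 3)))
        path = tmp_path / "c.xyz"
        rio.write_xyz(conf, path)
        back = rio.read_xyz(path)
        assert np.allclose(back.coords, np.round(conf.coords, 3), atol=1e-9)

    def test_pdb_roundtrip(self, tmp_path, rng):
        from Bio.PDB import PDBParser

        conf = rb.Conformation(rng.uniform(-50, 50, (15, 3)))
        path = tmp_path / "c.pdb"
        rio.write_pdb(conf, path)
        struct = PDBParser(QUIET=True).get_structure("x", str(path))
        atoms = list(struct.get_atoms())
        assert len(atoms) == 15
        coords = np.array([a.coord for a in atoms])
        assert np.allclose(coords, np.round(conf.coords, 3), atol=1e-3)

    def test_trajectory_npz_roundtrip(self, tmp_path, hairpin_ff):
        ff, conf = hairpin_ff
        traj = rb.run(ff, conf, rb.BDConfig(n_steps=5000, snapshot_every=500,
                                            seed=2))
        path = tmp_path / "t.npz"
        traj.save_npz(path)
        back = rb.Trajectory.load_npz(path)
        assert np.array_equal(back.snapshots, traj.snapshots)
        assert np.array_equal(back.times, traj.times)
        assert back.config["seed"] == 2


class TestPipeline:
    def test_dry_run_validates_and_stops(self):
        ss, arms = rb.load_fixture("trna_phe")
        report = rb.run_pipeline(ss, arms=arms,
                                 config=rb.PipelineConfig(dry_run=True, seed=0),
                                 log=lambda *a: None)
        assert report["dry_run"] and report["n_springs"] > 0
        assert "solution_properties" not in report

    @pytest.fixture(scope="class")
    def small_run(self, tmp_path_factory):
        ss = rb.parse_dot_bracket("((((....))))")
        cfg = rb.PipelineConfig(seed=4, equilibration_ps=2000,
                                production_ps=30_000, snapshot_every_ps=50,
                                hydro_snapshots=100)
        out = tmp_path_factory.mktemp("run")
        report = rb.run_pipeline(ss, config=cfg, out_dir=out, log=lambda *a: None)
        return ss, cfg, out, report

    def test_fixed_seed_is_reproducible(self, small_run):
        ss, cfg, _, report = small_run
        again = rb.run_pipeline(ss, config=cfg, log=lambda *a: None)
        assert again["solution_properties"] == report["solution_properties"]

    def test_report_matches_direct_reanalysis(self, small_run):
        ss, cfg, out, report = small_run
        traj = rb.Trajectory.load_npz(out / "trajectory.npz")
        stride = max(1, traj.n_snapshots // cfg.hydro_snapshots)
        props, _ = rb.ensemble_properties(traj, stride=stride)
        sp = report["solution_properties"]
        assert sp["tau_h_ns"] == props.tau_h
        assert sp["D_t_cm2_s"] == props.D_t
        assert sp["R_g_A"] == props.R_g
        with open(out / "report.json") as fh:
            assert json.load(fh)["solution_properties"]["R_g_A"] == sp["R_g_A"]

    def test_resumed_analysis_skips_simulation(self, small_run):
        ss, cfg, out, report = small_run
        traj = rb.Trajectory.load_npz(out / "trajectory.npz")
        re_report = rb.run_pipeline(ss, config=cfg, trajectory=traj,
                                    log=lambda *a: None)
        assert re_report["solution_properties"] == report["solution_properties"]


class TestCLI:
    def test_fixtures_listing(self):
        result = CliRunner().invoke(cli_main, ["fixtures"])
        assert result.exit_code == 0
        assert "trna_phe" in result.output and "5s_rrna" in result.output

    def test_build_writes_artifacts(self, tmp_path):
        result = CliRunner().invoke(
            cli_main, ["build", "--topology", "trna_phe", "--seed", "0",
                       "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "initial.xyz").exists()
        assert (tmp_path / "initial.pdb").exists()
        assert (tmp_path / "springs.tsv").exists()

    def test_dry_run_pipeline(self, tmp_path):
        result = CliRunner().invoke(
            cli_main, ["run", "--topology", "trna_phe", "--dry-run",
                       "--out", str(tmp_path)])
        assert result.exit_code == 0, result.output

    def test_hydro_on_xyz(self, tmp_path):
        conf = rb.build_a_form_duplex(5)
        path = tmp_path / "d.xyz"
        rio.write_xyz(conf, path)
        result = CliRunner().invoke(cli_main, ["hydro", "--conformation",
                                               str(path)])
        assert result.exit_code == 0, result.output
        out = json.loads(result.output)
        assert out["D_t_cm2_s"] > 0 and out["tau_h_ns"] > 0
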
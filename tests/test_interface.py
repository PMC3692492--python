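"""CSV I/O, CLI subcommands, dot-plots, fixture generation."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from tadpole.cli import main
from tadpole.io import (
    GroupedDataFile,
    generate_fixture,
    read_two_group_csv,
    write_study_csv,
)
from tadpole.manipulations import TwoGroupStudy
from tadpole.plotting import render_dotplot


@pytest.fixture
def runner():
    return CliRunner()


class TestCsvRoundTrip:
    def test_write_then_read_is_value_identical(self, tmp_path, rng):
        study = TwoGroupStudy(
            rng.standard_normal(30) + 1.0, rng.standard_normal(30), labels=("T", "C")
        )
        path = write_study_csv(study, tmp_path / "data.csv")
        back = read_two_group_csv(path).study
        np.testing.assert_allclose(np.sort(back.group_high), np.sort(study.group_high))
        np.testing.assert_allclose(np.sort(back.group_low), np.sort(study.group_low))

    def test_orientation_is_by_observed_mean(self, tmp_path):
        (tmp_path / "d.csv").write_text(
            "group,value\nA,1\nA,2\nB,10\nB,11\n"
        )
        data = read_two_group_csv(tmp_path / "d.csv")
        assert data.study.labels == ("B", "A")
        assert data.study.group_high.mean() > data.study.group_low.mean()

    def test_tiny_file(self, tmp_path):
        (tmp_path / "d.csv").write_text("group,value\nx,1\nx,2\ny,3\ny,4\n")
        data = read_two_group_csv(tmp_path / "d.csv")
        assert data.study.group_high.size == data.study.group_low.size == 2

    def test_three_labels_rejected_with_labels_listed(self, tmp_path):
        (tmp_path / "d.csv").write_text("group,value\na,1\nb,2\nc,3\n")
        with pytest.raises(ValueError, match=r"\['a', 'b', 'c'\]"):
            read_two_group_csv(tmp_path / "d.csv")

    def test_non_numeric_values_named_by_row(self, tmp_path):
        (tmp_path / "d.csv").write_text("group,value\na,1\na,oops\nb,2\nb,3\n")
        with pytest.raises(ValueError, match=r"rows \[3\]"):
            read_two_group_csv(tmp_path / "d.csv")

    def test_missing_rows_dropped_and_counted(self, tmp_path):
        (tmp_path / "d.csv").write_text("group,value\na,1\na,2\na,\nb,3\nb,4\n")
        data = read_two_group_csv(tmp_path / "d.csv")
        assert data.n_dropped == 1


class TestFixtures:
    def test_same_seed_gives_identical_files(self, tmp_path):
        f1 = generate_fixture("reclassify", 50, 4, seed=11, path=tmp_path / "a.csv")
        f2 = generate_fixture("reclassify", 50, 4, seed=11, path=tmp_path / "b.csv")
        assert (tmp_path / "a.csv").read_text() == (tmp_path / "b.csv").read_text()
        assert f1.path != f2.path

    def test_sidecar_metadata_regenerates_fixture(self, tmp_path):
        generate_fixture("remove", 40, 3, seed=5, path=tmp_path / "a.csv")
        meta = json.loads((tmp_path / "a.csv.meta.json").read_text())
        generate_fixture(
            meta["kind"], meta["n_per_group"], meta["k"], meta["seed"],
            tmp_path / "again.csv", icc=meta["icc"],
        )
        assert (tmp_path / "a.csv").read_text() == (tmp_path / "again.csv").read_text()

    def test_null_fixture_rarely_tadpole_significant(self, tmp_path, runner):
        hits = 0
        for seed in range(40):
            generate_fixture("none", 100, 0, seed=seed, path=tmp_path / "f.csv")
            out = runner.invoke(main, ["test", str(tmp_path / "f.csv")])
            assert out.exit_code == 0
            hits += "tadpole_significant: True" in out.output
        assert hits <= 4  # ~5% level leaves little room in 40 draws

    def test_reclassified_fixture_flagged(self, tmp_path, runner):
        """Reclassifying 10 of 200 imprints the signature strongly enough
        that a majority of seeds are flagged."""
        hits = 0
        for seed in range(20):
            generate_fixture("reclassify", 200, 10, seed=seed, path=tmp_path / "f.csv")
            out = runner.invoke(main, ["test", str(tmp_path / "f.csv")])
            hits += "tadpole_significant: True" in out.output
        assert hits > 10


class TestCli:
    def test_test_reports_identical_groups_not_significant(self, tmp_path, runner):
        x = np.r_[-2.0, -1, 0, 1, 2, -2, -1, 0, 1, 2]
        study = TwoGroupStudy(x, x.copy(), labels=("a", "b"))
        write_study_csv(study, tmp_path / "d.csv")
        out = runner.invoke(main, ["test", str(tmp_path / "d.csv")])
        assert out.exit_code == 0
        assert "z_diff=0.0000" in out.output
        assert "tadpole_significant: False" in out.output
        assert "threshold=2.3193" in out.output

    def test_malformed_file_nonzero_exit(self, tmp_path, runner):
        (tmp_path / "bad.csv").write_text("group,value\nonly_one_label,1\n")
        out = runner.invoke(main, ["test", str(tmp_path / "bad.csv")])
        assert out.exit_code != 0

    def test_sweep_deterministic_output(self, tmp_path, runner):
        args = ["sweep", "--n", "30", "--kind", "remove", "--k-max", "4",
                "--reps", "300", "--seed", "12", "--quiet"]
        o1 = runner.invoke(main, args)
        o2 = runner.invoke(main, args)
        assert o1.exit_code == 0
        assert o1.output == o2.output
        assert "minimal_k (t_pooled):" in o1.output

    def test_sweep_none_reports_not_reached(self, runner):
        out = runner.invoke(
            main,
            ["sweep", "--n", "30", "--kind", "none", "--k-max", "0",
             "--reps", "300", "--quiet"],
        )
        assert out.exit_code == 0
        assert "not reached" in out.output

    def test_sweep_config_file(self, tmp_path, runner):
        (tmp_path / "cfg.yaml").write_text(
            "n: 30\nkind: reclassify\nk_max: 3\nreps: 200\nseed: 2\n"
        )
        out = runner.invoke(
            main, ["sweep", "--config", str(tmp_path / "cfg.yaml"), "--quiet"]
        )
        assert out.exit_code == 0

    def test_sweep_bounds_error_before_compute(self, runner):
        out = runner.invoke(
            main,
            ["sweep", "--n", "20", "--kind", "remove", "--k-max", "19", "--quiet"],
        )
        assert out.exit_code != 0


class TestDotplot:
    def test_writes_nonempty_file_with_all_points(self, tmp_path, rng):
        study = TwoGroupStudy(rng.standard_normal(25), rng.standard_normal(25))
        out = render_dotplot(study, tmp_path / "p.png")
        assert out.exists() and out.stat().st_size > 0

    def test_point_count_matches_data_count(self, tmp_path, rng):
        import matplotlib.pyplot as plt

        study = TwoGroupStudy(rng.standard_normal(12), rng.standard_normal(7))
        render_dotplot(study, tmp_path / "p.png")
        # re-render through the private figure to count plotted points
        from tadpole import plotting

        counted = []
        orig = plt.subplots

        def capture(*a, **k):
            fig, ax = orig(*a, **k)
            counted.append(ax)
            return fig, ax

        plt.subplots = capture
        try:
            render_dotplot(study, tmp_path / "q.png")
        finally:
            plt.subplots = orig
        ax = counted[0]
        n_points = sum(len(line.get_xdata()) for line in ax.lines if line.get_marker() == "o")
        assert n_points == study.group_high.size + study.group_low.size

    def test_empty_group_rejected(self, tmp_path):
        study = TwoGroupStudy(np.array([1.0, 2.0]), np.array([]))
        with pytest.raises(ValueError, match="empty"):
            render_dotplot(study, tmp_path / "p.png")

    def test_cli_dotplot(self, tmp_path, runner):
        generate_fixture("remove", 50, 5, seed=1, path=tmp_path / "d.csv")
        out = runner.invoke(
            main, ["dotplot", str(tmp_path / "d.csv"), "-o", str(tmp_path / "d.svg")]
        )
        assert out.exit_code == 0
        assert (tmp_path / "d.svg").exists()
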
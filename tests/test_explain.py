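"""Pipeline orchestration, adapters, serialization, and the CLI."""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from terp.errors import (
    AdapterContractError,
    ConfigError,
    DegenerateInputError,
    DegenerateNeighborhoodError,
)
from terp.explain import (
    ExplanationRecord,
    RunConfig,
    run_explain,
    subprocess_adapter,
    write_trace_tsv,
)
from terp.fixtures import REFERENCE_ANGLES, angles_to_features, make_dihedral_blackbox, make_text_blackbox
from terp.neighborhood import TrainingStats

CFG = RunConfig(mode="tabular", n_samples=800, seed=42)


@pytest.fixture(scope="module")
def dihedral_setup():
    bb, table = make_dihedral_blackbox(seed=42)
    inst = angles_to_features(np.array(REFERENCE_ANGLES))[0]
    return bb, inst, TrainingStats.from_training_data(table)


class TestRunConfig:
    def test_round_trips_through_json(self):
        cfg = RunConfig(mode="text", n_samples=1000, seed=7, sigma=2.0)
        assert RunConfig.from_json(cfg.to_json()) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(mode="audio"),
            dict(mask_prob=1.5),
            dict(sigma=-1.0),
            dict(similarity_fallback="manhattan"),
            dict(n_samples=3),
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            RunConfig(**kwargs)


class TestRunExplain:
    def test_identical_seeds_give_identical_records(self, dihedral_setup):
        bb, inst, stats = dihedral_setup
        rec1, _, _ = run_explain(CFG, inst, bb.predict, stats=stats)
        rec2, _, _ = run_explain(CFG, inst, bb.predict, stats=stats)
        assert rec1.to_json() == rec2.to_json()

    def test_record_round_trips_through_json(self, dihedral_setup):
        bb, inst, stats = dihedral_setup
        rec, _, _ = run_explain(CFG, inst, bb.predict, stats=stats)
        assert ExplanationRecord.from_json(rec.to_json()) == rec

    def test_out_of_range_prediction_names_the_row(self, dihedral_setup):
        _, inst, stats = dihedral_setup

        def bad_predict(X):
            g = np.full(len(X), 0.4)
            g[17] = 1.2
            return g

        with pytest.raises(AdapterContractError, match="row 17"):
            run_explain(CFG, inst, bad_predict, stats=stats)

    def test_constant_predictions_are_degenerate(self, dihedral_setup):
        _, inst, stats = dihedral_setup
        constant = lambda X: np.full(len(X), 0.5)  # noqa: E731
        with pytest.raises(DegenerateNeighborhoodError):
            run_explain(CFG, inst, constant, stats=stats)
        # the Euclidean fallback survives the one-class neighborhood but
        # must still refuse a constant prediction vector
        cfg = RunConfig(mode="tabular", n_samples=800, seed=42, similarity_fallback="euclidean")
        with pytest.raises(DegenerateInputError):
            run_explain(cfg, inst, constant, stats=stats)

    def test_missing_stats_for_tabular_mode(self, dihedral_setup):
        bb, inst, _ = dihedral_setup
        with pytest.raises(ConfigError):
            run_explain(CFG, inst, bb.predict)

    def test_trace_tsv_round_trips(self, dihedral_setup, tmp_path):
        bb, inst, stats = dihedral_setup
        _, trace, _ = run_explain(CFG, inst, bb.predict, stats=stats)
        path = tmp_path / "trace.tsv"
        write_trace_tsv(path, trace)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame["j"]) == list(range(1, len(trace.U) + 1))
        assert np.allclose(frame["U"], trace.U)
        assert frame["added_feature"].iloc[0] == trace.added_features[0]


def _write_dihedral_script(tmp_path: Path) -> list[str]:
    """External executable scoring a CSV of sin/cos features."""
    script = tmp_path / "bb.py"
    script.write_text(
        "import sys\nimport numpy as np\n"
        "X = np.loadtxt(sys.argv[1], delimiter=',', skiprows=1, ndmin=2)\n"
        "z = 4.0 * X[:, 0] + 0.3 * X[:, 4]\n"
        "for p in 1.0 / (1.0 + np.exp(-z)):\n"
        "    print(p)\n"
    )
    return [sys.executable, str(script)]


class TestSubprocessAdapter:
    def test_matches_in_process_explanation(self, dihedral_setup, tmp_path):
        bb, inst, stats = dihedral_setup
        adapter = subprocess_adapter(_write_dihedral_script(tmp_path), mode="tabular")
        rec_in, _, _ = run_explain(CFG, inst, bb.predict, stats=stats)
        rec_sub, _, _ = run_explain(CFG, inst, adapter, stats=stats)
        assert rec_in.feature_names == rec_sub.feature_names
        assert rec_in.j_opt == rec_sub.j_opt
        assert np.allclose(rec_in.p, rec_sub.p, atol=1e-9)

    def test_line_count_mismatch_rejected(self, tmp_path):
        script = tmp_path / "short.py"
        script.write_text("print(0.5)\nprint(0.5)\n")
        adapter = subprocess_adapter([sys.executable, str(script)], mode="tabular")
        with pytest.raises(AdapterContractError, match="2 lines for 3"):
            adapter(np.zeros((3, 2)))

    def test_nonnumeric_output_rejected(self, tmp_path):
        script = tmp_path / "junk.py"
        script.write_text("print('hello')\n")
        adapter = subprocess_adapter([sys.executable, str(script)], mode="tabular")
        with pytest.raises(AdapterContractError):
            adapter(np.zeros((1, 2)))

    def test_text_batches_one_line_per_sample(self, tmp_path):
        script = tmp_path / "count.py"
        script.write_text(
            "import sys\n"
            "for line in open(sys.argv[1], encoding='utf-8'):\n"
            "    n = len(line.split())\n"
            "    print(min(n / 10.0, 1.0))\n"
        )
        adapter = subprocess_adapter([sys.executable, str(script)], mode="text")
        g = adapter([["a", "b"], ["a"], []])
        assert g == pytest.approx([0.2, 0.1, 0.0])


class TestCli:
    def test_demo_text_writes_explanation_and_trace(self, tmp_path):
        from click.testing import CliRunner

        from terp.cli import main

        runner = CliRunner()
        out = tmp_path / "demo"
        result = runner.invoke(
            main, ["demo", "--case", "text", "--seed", "3", "--n-samples", "1200", "--out", str(out)]
        )
        assert result.exit_code == 0, result.output
        payload = json.loads((out / "explanation.json").read_text())
        assert payload["j_opt"] == 2
        assert set(payload["feature_names"]) == {"science", "species"}
        assert (out / "trace.tsv").exists()

    def test_explain_tabular_via_subprocess_blackbox(self, tmp_path):
        from click.testing import CliRunner

        from terp.cli import main

        bb, table = make_dihedral_blackbox(seed=1)
        names = list(bb.feature_names)
        inst = angles_to_features(np.array(REFERENCE_ANGLES))
        pd.DataFrame(inst, columns=names).to_csv(tmp_path / "instance.csv", index=False)
        pd.DataFrame(table, columns=names).to_csv(tmp_path / "training.csv", index=False)
        cmd = " ".join(_write_dihedral_script(tmp_path))

        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "explain-tabular", str(tmp_path / "instance.csv"),
                "--blackbox-cmd", cmd,
                "--training-csv", str(tmp_path / "training.csv"),
                "--out", str(tmp_path / "out"),
                "--n-samples", "800", "--seed", "1",
            ],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads((tmp_path / "out" / "explanation.json").read_text())
        assert payload["feature_names"][0] == "sin_phi"

    def test_degenerate_adapter_maps_to_exit_code_4(self, tmp_path):
        from click.testing import CliRunner

        from terp.cli import main

        bb, table = make_dihedral_blackbox(seed=1)
        names = list(bb.feature_names)
        inst = angles_to_features(np.array(REFERENCE_ANGLES))
        pd.DataFrame(inst, columns=names).to_csv(tmp_path / "instance.csv", index=False)
        pd.DataFrame(table, columns=names).to_csv(tmp_path / "training.csv", index=False)
        script = tmp_path / "const.py"
        script.write_text(
            "import sys\n"
            "rows = sum(1 for _ in open(sys.argv[1])) - 1\n"
            "print('\\n'.join(['0.5'] * rows))\n"
        )
        runner = CliRunner()
        result = runner.invoke(
            main,
            [
                "explain-tabular", str(tmp_path / "instance.csv"),
                "--blackbox-cmd", f"{sys.executable} {script}",
                "--training-csv", str(tmp_path / "training.csv"),
                "--out", str(tmp_path / "out"),
                "--n-samples", "200", "--seed", "1",
            ],
        )
        assert result.exit_code == 4
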
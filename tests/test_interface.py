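import json

import numpy as np
import pytest
from click.testing import CliRunner

from condld import GenotypeCountTable, PopulationParams, d_bounds, joint_probs
from condld.cli import main
from condld.io import (
    GenotypeMatrix,
    ParseError,
    read_count_table,
    read_genotype_matrix,
    read_sim_config,
    spec_from_config,
    write_count_table,
)
from condld.scan import ld_scan


def make_matrix_file(path, codes, loci, labels=None):
    lines = ["\t".join(["id", *loci] + (["status"] if labels else []))]
    for i, row in enumerate(codes):
        cells = ["." if c < 0 else str(c) for c in row]
        line = "\t".join([f"ind{i}", *cells])
        if labels:
            line += f"\t{labels[i]}"
        lines.append(line)
    path.write_text("\n".join(lines) + "\n")


def simulate_matrix(rng, n_case, n_control, focal_params, n_other=10, p_other=0.4):
    """Case-control genotype matrix: a focal disease locus, one linked marker,
    and unlinked markers; codes count copies of the designated alleles."""
    n = n_case + n_control
    # disease genotype codes: cases AA(2)/Aa(1), controls aa(0)
    q = focal_params.q
    w = np.array([q * q, 2 * q * (1 - q)])
    disease = np.concatenate(
        [rng.choice([2, 1], size=n_case, p=w / w.sum()), np.zeros(n_control, dtype=int)]
    )
    labels = ["case"] * n_case + ["control"] * n_control
    P = joint_probs(focal_params).P

    def marker_codes(disease_codes, P):
        codes = np.empty_like(disease_codes)
        for j, d in ((0, 2), (1, 1), (2, 0)):
            sel = disease_codes == d
            probs = P[:, j] / P[:, j].sum()
            codes[sel] = 2 - rng.choice(3, size=sel.sum(), p=probs)
        return codes

    cols = {"focal": disease, "linked": marker_codes(disease, P)}
    P0 = joint_probs(PopulationParams(p_other, q, 0.0)).P
    for k in range(n_other):
        cols[f"null{k}"] = marker_codes(disease, P0)
    loci = list(cols)
    codes = np.column_stack([cols[name] for name in loci]).astype(np.int8)
    return GenotypeMatrix(list(map(str, range(n))), loci, codes, labels)


class TestCountTableIO:
    def test_round_trip(self, tmp_path, rng):
        table = GenotypeCountTable(rng.integers(0, 50, size=(3, 3)))
        path = tmp_path / "counts.tsv"
        write_count_table(table, path, marker_allele="T", disease_allele="delCTTT")
        back, meta = read_count_table(path)
        assert back == table
        assert meta["marker_allele"] == "T"
        assert meta["disease_allele"] == "delCTTT"

    def test_negative_cell_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "#marker_allele=M #disease_allele=A\n"
            "genotype\tAA\tAa\taa\nMM\t1\t2\t3\nMm\t4\t-5\t6\nmm\t7\t8\t9\n"
        )
        with pytest.raises(ParseError, match="line 4"):
            read_count_table(path)

    @pytest.mark.parametrize(
        "body",
        [
            "genotype\tAA\tAa\taa\nMM\t1\t2\t3\nMm\t4\t5\t6\n",  # missing row
            "genotype\tAA\tAa\taa\nMM\t1\t2\t3\nXX\t4\t5\t6\nmm\t7\t8\t9\n",  # bad label
            "genotype\tAA\tAa\taa\nMM\t1\t2.5\t3\nMm\t4\t5\t6\nmm\t7\t8\t9\n",  # fractional
            "MM\t1\t2\t3\nMm\t4\t5\t6\nmm\t7\t8\t9\n",  # no header
        ],
    )
    def test_malformed_files(self, tmp_path, body):
        path = tmp_path / "bad.tsv"
        path.write_text(body)
        with pytest.raises(ParseError):
            read_count_table(path)


class TestGenotypeMatrixIO:
    def test_read_synthetic(self, tmp_path, rng):
        codes = rng.integers(0, 3, size=(40, 50))
        loci = [f"site{i}" for i in range(50)]
        path = tmp_path / "matrix.tsv"
        make_matrix_file(path, codes, loci)
        m = read_genotype_matrix(path)
        assert m.codes.shape == (40, 50)
        assert m.loci == loci
        assert m.labels is None

    def test_missing_tracked_and_all_missing_warns(self, tmp_path):
        codes = np.array([[0, -1], [1, -1], [2, -1]])
        path = tmp_path / "matrix.tsv"
        make_matrix_file(path, codes, ["a", "b"])
        m = read_genotype_matrix(path)
        assert m.missingness == pytest.approx([0.0, 1.0])
        assert any("entirely missing" in w for w in m.warnings)

    def test_duplicate_locus_rejected(self, tmp_path):
        path = tmp_path / "matrix.tsv"
        path.write_text("id\tx\tx\nind0\t0\t1\n")
        with pytest.raises(ParseError, match="duplicated"):
            read_genotype_matrix(path)

    def test_invalid_code_rejected(self, tmp_path):
        path = tmp_path / "matrix.tsv"
        path.write_text("id\tx\nind0\t3\n")
        with pytest.raises(ParseError, match="invalid code"):
            read_genotype_matrix(path)

    def test_status_labels(self, tmp_path):
        path = tmp_path / "matrix.tsv"
        path.write_text("id\tx\tstatus\nind0\t1\tcase\nind1\t0\tcontrol\n")
        m = read_genotype_matrix(path)
        assert m.labels == ["case", "control"]

    def test_bad_status_rejected(self, tmp_path):
        path = tmp_path / "matrix.tsv"
        path.write_text("id\tx\tstatus\nind0\t1\tmaybe\n")
        with pytest.raises(ParseError, match="status"):
            read_genotype_matrix(path)


class TestLdScan:
    def test_record_count_and_focal_excluded(self, rng):
        m = simulate_matrix(rng, 20, 24, PopulationParams(0.5, 0.03, 0.01), n_other=48)
        records = ld_scan(m, "focal", method="L", q_value=0.03)
        assert len(records) == 49
        assert all(r.locus != "focal" for r in records)

    def test_missing_focal_raises(self, rng):
        m = simulate_matrix(rng, 10, 10, PopulationParams(0.5, 0.03, 0.01))
        with pytest.raises(ValueError):
            ld_scan(m, "nope")

    def test_monomorphic_flagged(self, rng):
        m = simulate_matrix(rng, 10, 10, PopulationParams(0.5, 0.03, 0.01), n_other=1)
        m.codes[:, m.loci.index("null0")] = 2
        records = ld_scan(m, "focal", q_value=0.03)
        rec = next(r for r in records if r.locus == "null0")
        assert rec.status == "monomorphic" and rec.result is None

    def test_method_l_within_bounds_everywhere(self, rng):
        # the estimator's headline contract on ascertained data
        m = simulate_matrix(rng, 16, 24, PopulationParams(0.7, 0.03, 0.008), n_other=30)
        records = ld_scan(m, "focal", method="L", p_source="controls", q_value=0.03)
        assert sum(r.status == "ok" for r in records) > 20
        for rec in records:
            if rec.status != "ok":
                continue
            lo, hi = d_bounds(rec.result.p_used, rec.result.q_used)
            assert lo - 1e-9 <= rec.result.D_hat <= hi + 1e-9

    def test_method_h_replication_exceeds_bounds_somewhere(self, rng):
        m = simulate_matrix(rng, 16, 24, PopulationParams(0.7, 0.03, 0.008), n_other=30)
        records = ld_scan(
            m, "focal", method="H", p_source="controls", q_value=0.03, h_mode="replication"
        )
        assert any(r.status == "ok" and r.result.out_of_bounds for r in records)

    def test_controls_source_requires_labels(self, rng):
        m = simulate_matrix(rng, 10, 10, PopulationParams(0.5, 0.03, 0.01))
        m.labels = None
        with pytest.raises(ValueError):
            ld_scan(m, "focal", p_source="controls")


class TestSimConfig:
    def test_parse_and_spec(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text(
            "scheme = III\np = 0.5\nq = 0.01\nD = 0.004\nn = 200\n"
            "n_case = 100\nn_control = 100\nq_mode = survey\n"
            "reps = 10\nseed = 1\nmethods = L,H\n"
        )
        cfg = read_sim_config(path)
        spec, run = spec_from_config(cfg)
        assert spec.scheme == "III" and spec.n_case == 100
        assert run["reps"] == 10 and run["methods"] == ("L", "H")

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "sim.cfg"
        path.write_text("bogus = 1\n")
        with pytest.raises(ParseError):
            read_sim_config(path)


class TestCli:
    @pytest.fixture
    def counts_file(self, tmp_path, rng):
        table = GenotypeCountTable(
            np.round(200 * joint_probs(PopulationParams(0.5, 0.5, 0.2)).P)
        )
        path = tmp_path / "counts.tsv"
        write_count_table(table, path)
        return path

    def test_estimate(self, counts_file):
        runner = CliRunner()
        result = runner.invoke(main, ["estimate", "--counts", str(counts_file), "--method", "L"])
        assert result.exit_code == 0
        header, row = result.output.strip().splitlines()
        record = dict(zip(header.split("\t"), row.split("\t")))
        assert float(record["D_hat"]) == pytest.approx(0.2, abs=0.02)

    def test_estimate_json(self, counts_file):
        runner = CliRunner()
        result = runner.invoke(
            main, ["estimate", "--counts", str(counts_file), "--method", "H", "--json"]
        )
        assert result.exit_code == 0
        record = json.loads(result.output)
        assert record["method"].startswith("joint")

    def test_estimate_bad_file(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("not a table\n")
        result = CliRunner().invoke(main, ["estimate", "--counts", str(bad)])
        assert result.exit_code == 2

    def test_simulate_deterministic(self, tmp_path):
        cfg = tmp_path / "sim.cfg"
        cfg.write_text(
            "scheme = I\np = 0.5\nq = 0.5\nD = 0.2\nn = 100\nreps = 10\nseed = 1\n"
        )
        runner = CliRunner()
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        assert runner.invoke(main, ["simulate", "--config", str(cfg), "--out", str(out1)]).exit_code == 0
        assert runner.invoke(main, ["simulate", "--config", str(cfg), "--out", str(out2)]).exit_code == 0
        assert out1.read_text() == out2.read_text()

    def test_scan_requires_focal(self, tmp_path):
        result = CliRunner().invoke(main, ["scan", "--matrix", str(tmp_path / "x.tsv")])
        assert result.exit_code == 2

    def test_scan_runs(self, tmp_path, rng):
        m = simulate_matrix(rng, 10, 14, PopulationParams(0.5, 0.1, 0.03), n_other=4)
        path = tmp_path / "matrix.tsv"
        make_matrix_file(path, m.codes, m.loci, m.labels)
        result = CliRunner().invoke(
            main, ["scan", "--matrix", str(path), "--focal", "focal", "--q", "0.1"]
        )
        assert result.exit_code == 0
        lines = [l for l in result.output.splitlines() if l]
        assert len(lines) == 1 + 5  # header + linked + 4 null loci

    def test_profile(self, counts_file, tmp_path):
        out = tmp_path / "profile.tsv"
        result = CliRunner().invoke(
            main,
            ["profile", "--counts", str(counts_file), "--q-grid", "0.3:0.7:0.1", "--out", str(out)],
        )
        assert result.exit_code == 0
        lines = out.read_text().splitlines()
        assert lines[0] == "q\tD_hat\tlod"
        assert lines[-1].startswith("# argmax_q")

    def test_unknown_option(self):
        assert CliRunner().invoke(main, ["estimate", "--bogus"]).exit_code == 2
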
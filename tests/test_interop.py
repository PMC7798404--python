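"""File-format bridges: DIMACS, network text format, SMV export, CLI surface."""

import pytest
from click.testing import CliRunner
from hypothesis import given, settings
from hypothesis import strategies as st

from nbckit.cli import main as cli_main
from nbckit.dimacs import DimacsError, read_dimacs, write_dimacs
from nbckit.netio import read_network_text, write_network_text
from nbckit.network import (
    FaultSpec,
    FaultType,
    apply_fault,
    build_excov_network,
    build_sat_clause_network,
    build_ssp_network,
)
from nbckit.problems import CNFFormula, ExCovInstance, SSPInstance, random_cnf3
from nbckit.smv import write_smv


class TestDimacs:
    def test_basic_parse(self):
        f = read_dimacs("p cnf 2 1\n1 -2 0\n")
        assert f.num_vars == 2
        assert f.clauses == (frozenset({1, -2}),)

    def test_comments_and_multiline_clauses(self):
        f = read_dimacs("c a comment\np cnf 3 1\n1 2\n3 0\n")
        assert f.clauses == (frozenset({1, 2, 3}),)

    @pytest.mark.parametrize(
        "text, match",
        [
            ("p cnf x 1\n1 0\n", "header"),
            ("1 0\n", "header"),
            ("p cnf 2 1\n3 0\n", "exceeds"),
            ("p cnf 2 1\n1 -2\n", "terminator"),
            ("p cnf 2 2\n1 0\n", "declares"),
        ],
    )
    def test_parse_errors_carry_line_numbers(self, text, match):
        with pytest.raises(DimacsError, match=match):
            read_dimacs(text)

    @given(st.integers(3, 8), st.integers(1, 12), st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_round_trip_identity_on_clause_sets(self, m, n, seed):
        f = random_cnf3(m, n, seed=seed)
        g = read_dimacs(write_dimacs(f, comments=["generated"]))
        assert g.num_vars == f.num_vars
        assert set(g.clauses) == set(f.clauses)


class TestNetworkText:
    def test_ssp_round_trip(self):
        net = build_ssp_network(SSPInstance([2, 5, 9]))
        assert read_network_text(write_network_text(net)) == net

    def test_excov_round_trip_preserves_force_down(self, cover_net):
        again = read_network_text(write_network_text(cover_net))
        assert again == cover_net
        assert again.split_row_kinds == cover_net.split_row_kinds

    def test_faults_round_trip(self):
        net = build_ssp_network(SSPInstance([2, 3, 5]))
        faulted = apply_fault(net, FaultSpec((3, 1), FaultType.PASS_FORCED, 0))
        assert read_network_text(write_network_text(faulted)) == faulted

    def test_bad_magic_rejected(self):
        with pytest.raises(ValueError, match="nbc-grid"):
            read_network_text("something else\n")


class TestSmvExport:
    def test_grid_model_names_and_determinism(self):
        net = build_ssp_network(SSPInstance([2, 3, 5]))
        a = write_smv(net, k=9, overall=True)
        b = write_smv(net, k=9, overall=True)
        assert a.text == b.text  # byte-identical
        for name in ("ltl_k", "ctl_k", "csum", "nsum"):
            assert f"NAME {name}" in a.text
        assert "JUSTICE" in a.text  # compassion surrogate

    def test_tagged_option_adds_tag_variables(self):
        net = build_ssp_network(SSPInstance([2, 3]))
        untagged = write_smv(net, k=2)
        tagged = write_smv(net, k=2, tagged=True)
        assert "tag0" not in untagged.text
        assert "tag0 : boolean" in tagged.text

    def test_sat_variants_have_counters_and_differ(self):
        net = build_sat_clause_network(random_cnf3(4, 6, seed=1))
        clause = write_smv(net, sat_variant="clause")
        merged = write_smv(net, sat_variant="no_clause")
        assert "0..3" in clause.text and "NAME ltl_sat" in clause.text
        assert "NAME ctl_sat" in merged.text
        assert clause.text != merged.text

    def test_variable_reordering_permutes_tag_declarations(self):
        f = CNFFormula(3, [[-1, -2, -3], [1, 2, 3]])
        net = build_sat_clause_network(f)
        default = write_smv(net, sat_variant="no_clause")
        reordered = write_smv(net, sat_variant="no_clause", variable_order="reordered")
        # clause 2 (on the TRUE branch of literal 1) is declared first when reordered
        assert default.text.index("tag1 :") < default.text.index("tag2 :")
        assert reordered.text.index("tag2 :") < reordered.text.index("tag1 :")

    def test_option_kind_mismatches_rejected(self):
        grid = build_ssp_network(SSPInstance([2, 3]))
        sat = build_sat_clause_network(random_cnf3(3, 2, seed=0))
        with pytest.raises(ValueError):
            write_smv(grid, sat_variant="clause")
        with pytest.raises(ValueError):
            write_smv(sat, k=1)


class TestCli:
    def test_verify_reachable_output(self):
        result = CliRunner().invoke(
            cli_main, ["verify", "ssp", "--set", "2,5,9", "--k", "11"]
        )
        assert result.exit_code == 0
        assert "reachable: True" in result.output
        assert "[2, 9]" in result.output

    def test_verify_unreachable_output_exits_nonzero(self):
        result = CliRunner().invoke(
            cli_main, ["verify", "ssp", "--set", "2,3,5", "--k", "9"]
        )
        assert result.exit_code == 1
        assert "reachable: False" in result.output

    def test_verify_excov(self):
        result = CliRunner().invoke(
            cli_main,
            ["verify", "excov", "--universe", "4", "--subsets", "2;3;1,4;2,3"],
        )
        assert result.exit_code == 0
        assert "excov_exists: True" in result.output

    def test_encode_inject_verify_pipeline(self, tmp_path):
        runner = CliRunner()
        net_file = tmp_path / "net.txt"
        result = runner.invoke(
            cli_main,
            ["encode", "--problem", "ssp", "--set", "2,3,5", "-o", str(net_file)],
        )
        assert result.exit_code == 0
        faulted_file = tmp_path / "faulted.txt"
        result = runner.invoke(
            cli_main,
            ["inject", "-i", str(net_file), "--fault", "3,1,PASS_FORCED,0",
             "-o", str(faulted_file)],
        )
        assert result.exit_code == 0
        result = runner.invoke(
            cli_main,
            ["verify", "ssp", "--set", "2,3,5", "--all",
             "--network", str(faulted_file)],
        )
        assert result.exit_code == 1
        assert "csum: INVALID" in result.output

    def test_verify_sat_from_dimacs(self, tmp_path):
        cnf = tmp_path / "f.cnf"
        cnf.write_text("p cnf 2 2\n1 2 0\n-1 2 0\n")
        result = CliRunner().invoke(cli_main, ["verify", "sat", "--dimacs", str(cnf)])
        assert result.exit_code == 0
        assert "satisfiable: True" in result.output

    def test_selftest_passes(self):
        result = CliRunner().invoke(cli_main, ["selftest", "--seed", "1", "--batch", "3"])
        assert result.exit_code == 0
        assert "0 disagreements" in result.output

    def test_export_smv_stdout(self):
        result = CliRunner().invoke(
            cli_main, ["export-smv", "--set", "2,3", "--k", "2"]
        )
        assert result.exit_code == 0
        assert result.output.startswith("MODULE main")


class TestYamlInstances:
    def test_each_problem_kind(self):
        from nbckit.netio import instance_from_yaml

        ssp = instance_from_yaml("problem: ssp\nelements: [2, 5, 9]\ntarget: 11\n")
        assert ssp == SSPInstance([2, 5, 9], 11)
        exc = instance_from_yaml(
            "problem: excov\nuniverse: [1, 2, 3, 4]\nsubsets: [[2], [3], [1, 4], [2, 3]]\n"
        )
        assert exc == ExCovInstance([1, 2, 3, 4], [[2], [3], [1, 4], [2, 3]])
        cnf = instance_from_yaml("problem: cnf\nnum_vars: 2\nclauses: [[1, -2]]\n")
        assert cnf.clauses == (frozenset({1, -2}),)

    def test_missing_fields_rejected(self):
        from nbckit.netio import instance_from_yaml

        with pytest.raises(ValueError, match="missing field"):
            instance_from_yaml("problem: ssp\n")
        with pytest.raises(ValueError, match="unknown problem"):
            instance_from_yaml("problem: tsp\n")
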
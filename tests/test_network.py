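import numpy as np
import pytest

from flux13c import network as nw
from conftest import toy_path

LINEAR_TOY = open(toy_path("linear")).read()


class TestLoadNetwork:
    def test_linear_toy_counts(self):
        net = nw.load_network(LINEAR_TOY)
        assert len(net.reactions) == 3
        assert len(net.metabolites) == 4

    def test_bundled_model_matches_declared_count_and_carbon_balance(self, yeast_net):
        assert len(yeast_net.reactions) == yeast_net.declared_reaction_count
        # independent audit: stoichiometric carbon sum per reaction column
        for r in yeast_net.reactions:
            if r.sink:
                continue
            carbon = sum(
                coeff * yeast_net.metabolites[mid].carbon_count
                for mid, coeff in r.stoichiometry.items()
            )
            assert carbon == pytest.approx(0.0, abs=1e-9), r.id

    def test_carbon_count_mismatch_without_co2_sink_is_rejected(self):
        bad = """# METABOLITES
A  a  extracellular  3  no
B  b  cytosol  2  yes
B_ext  bx  extracellular  2  no
# REACTIONS
R1 : 1 A -> 1 B | irr | map A#abc -> B#ab
R2 : 1 B -> 1 B_ext | irr | map B#ab -> B_ext#ab
"""
        with pytest.raises(nw.NetworkError, match="carbon"):
            nw.load_network(bad)

    @pytest.mark.parametrize(
        "text,match",
        [
            ("# METABOLITES\nA a cytosol 2 yes\nA a cytosol 2 yes\n", "duplicate"),
            ("# METABOLITES\nA a nowhere 2 yes\n", "compartment"),
            ("# REACTIONS\nR1 1 A -> 1 B\n", "reaction line"),
            ("stray content\n", "outside"),
        ],
    )
    def test_syntax_errors_carry_line_numbers(self, text, match):
        with pytest.raises(nw.ModelSyntaxError, match=match) as exc:
            nw.load_network(text)
        assert exc.value.line is not None


class TestStoichiometricMatrix:
    def test_linear_pathway_null_space_is_all_ones(self):
        net = nw.load_network(LINEAR_TOY)
        S = nw.stoichiometric_matrix(net)
        from scipy.linalg import null_space

        N = null_space(S)
        assert N.shape[1] == 1
        direction = N[:, 0] / N[0, 0]
        assert np.allclose(direction, 1.0)

    def test_branch_toy_null_space_dimension_two(self):
        net = nw.load_network_file(toy_path("branch"))
        S = nw.stoichiometric_matrix(net)
        # independent rank computation by Gaussian elimination
        A = S.copy()
        rank = 0
        for col in range(A.shape[1]):
            piv = None
            for row in range(rank, A.shape[0]):
                if abs(A[row, col]) > 1e-12:
                    piv = row
                    break
            if piv is None:
                continue
            A[[rank, piv]] = A[[piv, rank]]
            A[rank] /= A[rank, col]
            for row in range(A.shape[0]):
                if row != rank and abs(A[row, col]) > 1e-12:
                    A[row] -= A[row, col] * A[rank]
            rank += 1
        assert S.shape[1] - rank == 2

    def test_yeast_columns_are_carbon_balanced_including_co2(self, yeast_net):
        S = yeast_net.stoichiometric_matrix()
        # brute-force audit over raw stoichiometry (includes unbalanced CO2)
        for r in yeast_net.reactions:
            if r.sink:
                continue
            total = sum(
                coeff * yeast_net.metabolites[m].carbon_count
                for m, coeff in r.stoichiometry.items()
            )
            assert abs(total) < 1e-9, r.id

    def test_column_order_matches_declaration_order(self, yeast_net):
        S = yeast_net.stoichiometric_matrix()
        balanced = yeast_net.balanced_metabolites
        j = yeast_net.reaction_ids().index("PGI")
        i_g6p, i_f6p = balanced.index("g6p"), balanced.index("f6p")
        assert S[i_g6p, j] == -1 and S[i_f6p, j] == 1


class TestAdd3hpPathway:
    def test_mcr_consumes_two_nadph(self, yeast_net):
        ext = nw.add_3hp_pathway(yeast_net)
        assert ext.reaction("MCR").cofactors["NADPH"] == -2

    def test_acc_takes_exactly_one_carbon_from_co2(self, yeast_net):
        ext = nw.add_3hp_pathway(yeast_net)
        amap = ext.reaction("ACC").atom_maps[0]
        from_co2 = [t for t in amap.as_tuples() if t[0] == "co2"]
        assert len(from_co2) == 1
        assert from_co2[0][2:] == ("malcoa", 3)

    def test_extended_network_passes_validation(self, yeast_net):
        ext = nw.add_3hp_pathway(yeast_net)
        assert nw.validate(ext).ok

    def test_double_application_raises(self, yeast_net):
        ext = nw.add_3hp_pathway(yeast_net)
        with pytest.raises(nw.NetworkError, match="already present"):
            nw.add_3hp_pathway(ext)

    def test_missing_precursor_raises(self):
        net = nw.load_network(LINEAR_TOY)
        with pytest.raises(nw.NetworkError, match="precursor"):
            nw.add_3hp_pathway(net)


class TestValidate:
    def test_bundled_model_passes_clean(self, yeast_net):
        report = nw.validate(yeast_net)
        assert report.ok and not report.findings

    def test_orphan_balanced_metabolite_is_named(self):
        text = LINEAR_TOY + "ORPHAN  orphan  cytosol  2  yes\n"
        # append within metabolite section instead
        lines = text.splitlines()
        idx = lines.index("# REACTIONS")
        lines.insert(idx, "ORPHAN  orphan  cytosol  2  yes")
        net = nw.load_network("\n".join(lines[:-1]))
        report = nw.validate(net)
        assert not report.ok
        assert any(f.subject == "ORPHAN" for f in report.findings)

    def test_mutated_atom_map_is_detected_with_reaction_id(self, yeast_net):
        net = yeast_net.copy()
        rxn = net.reaction("GND")
        v = rxn.atom_maps[0]
        # reroute two carbons onto the same label: invalid atom map
        broken = nw.AtomMapVariant(
            v.weight, v.substrates, v.substrate_labels, v.products,
            tuple(tuple("a" if lab == "b" else lab for lab in labels)
                  for labels in v.product_labels),
        )
        rxn.atom_maps = [broken]
        report = nw.validate(net)
        assert not report.ok
        assert any(f.subject == "GND" for f in report.findings)


class TestSerialization:
    def test_round_trip_preserves_matrix_and_atom_maps(self, yeast_net):
        text = nw.serialize_network(yeast_net)
        net2 = nw.load_network(text)
        assert np.allclose(net2.stoichiometric_matrix(), yeast_net.stoichiometric_matrix())
        for r1, r2 in zip(yeast_net.reactions, net2.reactions):
            assert [v.as_tuples() for v in r1.atom_maps] == [
                v.as_tuples() for v in r2.atom_maps
            ]

    def test_serialization_is_bit_stable(self, yeast_net):
        text = nw.serialize_network(yeast_net)
        assert nw.serialize_network(nw.load_network(text)) == text
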
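"""Mass engine: compositions, parsing, exact masses, m/z arithmetic."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rnacad.rna_chem import (
    Composition,
    CompositionError,
    ModifiedRNASequence,
    SequenceParseError,
    default_registry,
    monoisotopic_mass,
    mz,
    neutral_mass_from_mz,
    parse_sequence,
    read_sequences,
    residue_mass_delta,
)


class TestComposition:
    def test_formula_round_trip(self):
        comp = Composition.from_formula("C10H13N5O4")
        assert comp == {"C": 10, "H": 13, "N": 5, "O": 4}
        assert Composition.from_formula(comp.formula()) == comp

    def test_arithmetic(self):
        water = Composition.from_formula("H2O")
        assert water + water == Composition.from_formula("H4O2")
        assert 3 * water == Composition.from_formula("H6O3")
        assert (water + water) - water == water

    def test_subtraction_underflow_raises(self):
        with pytest.raises(CompositionError):
            Composition.from_formula("H2O") - Composition.from_formula("H2O2")

    def test_negative_count_rejected(self):
        with pytest.raises(CompositionError):
            Composition({"C": -1})

    def test_hashable_and_contains(self):
        a = Composition.from_formula("C5H5N5")
        b = Composition.from_formula("C10H13N5O4")
        assert hash(a) == hash(Composition(dict(a)))
        assert b.contains(a)
        assert not a.contains(b)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["C", "H", "N", "O", "P"]),
                st.integers(min_value=0, max_value=50),
            ),
            min_size=1,
            max_size=5,
        ).map(lambda items: Composition(dict(items)) if any(c for _, c in items) else Composition({"H": 1})),
        st.lists(
            st.tuples(
                st.sampled_from(["C", "H", "N", "O", "P"]),
                st.integers(min_value=0, max_value=50),
            ),
            min_size=1,
            max_size=5,
        ).map(lambda items: Composition(dict(items)) if any(c for _, c in items) else Composition({"H": 1})),
    )
    @settings(max_examples=50, deadline=None)
    def test_addition_commutes_and_mass_is_additive(self, a, b):
        assert a + b == b + a
        assert (a + b).monoisotopic_mass == pytest.approx(
            a.monoisotopic_mass + b.monoisotopic_mass, abs=1e-9
        )


class TestParsing:
    def test_whitespace_grouped_sequence(self):
        seq = parse_sequence("GAAGG GAAAC CUUCG")
        assert len(seq) == 15
        assert seq.residues[0] == "G"
        assert seq.residues[14] == "G"

    def test_bracketed_modification(self):
        seq = parse_sequence("GAAGGGA[c3A]ACCUUCG")
        assert len(seq) == 15
        assert seq.residues[7] == "c3A"

    def test_comma_alias_for_dideaza(self):
        assert parse_sequence("[c1,3A]").residues == ("c13A",)

    def test_unknown_code_reports_position(self):
        with pytest.raises(SequenceParseError, match="'X' at position 3"):
            parse_sequence("GAXGG")

    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceParseError):
            parse_sequence("   ")

    def test_unterminated_bracket(self):
        with pytest.raises(SequenceParseError, match="unterminated"):
            parse_sequence("GA[c3A")

    def test_sequence_file(self, tmp_path):
        path = tmp_path / "seqs.txt"
        path.write_text("# comment\nRNA1\tGAAGG GAAAC CUUCG\nGAAGGGCAACCUUCG\n")
        seqs = read_sequences(path)
        assert set(seqs) == {"RNA1", "seq2"}
        assert len(seqs["RNA1"]) == 15


class TestMasses:
    def test_unmodified_15mer_mass(self, rna1):
        assert rna1.monoisotopic_mass() == pytest.approx(4835.718, abs=1e-3)

    def test_c7_variant_mass(self):
        seq = parse_sequence("GAAGGGCAACCUUCG")
        assert seq.monoisotopic_mass() == pytest.approx(4811.707, abs=1e-3)

    def test_single_adenosine(self):
        seq = parse_sequence("A")
        assert seq.monoisotopic_mass() == pytest.approx(267.0968, abs=1e-4)

    def test_phosphate_terminus_adds_hpo3(self, rna1):
        phosphorylated = ModifiedRNASequence(rna1.residues, five_prime="phosphate")
        assert phosphorylated.monoisotopic_mass() - rna1.monoisotopic_mass() == (
            pytest.approx(79.96633, abs=1e-4)
        )

    def test_pyteomics_cross_check(self, rna1):
        """Independent mass oracle: pyteomics on the Hill formula string."""
        pyteomics_mass = pytest.importorskip("pyteomics.mass")
        for obj in (
            default_registry()["A"].nucleoside,
            default_registry()["G"].base,
            rna1.composition(),
        ):
            assert obj.monoisotopic_mass == pytest.approx(
                pyteomics_mass.calculate_mass(formula=obj.formula()), abs=1e-4
            )

    @pytest.mark.parametrize("position", [2, 3, 7, 8, 9])  # the adenosines
    def test_deaza_swap_additivity(self, position):
        """Swapping A for c3A anywhere shifts the mass by one N-to-CH unit."""
        base = parse_sequence("GAAGGGAAACCUUCG")
        codes = list(base.residues)
        codes[position - 1] = "c3A"
        swapped = ModifiedRNASequence(tuple(codes))
        delta = base.monoisotopic_mass() - swapped.monoisotopic_mass()
        assert delta == pytest.approx(0.995249, abs=1e-6)


class TestResidueDeltas:
    def test_deaza_delta(self):
        assert residue_mass_delta("A", "c3A") == pytest.approx(0.995249, abs=1e-6)

    def test_deoxy_delta_is_one_oxygen(self):
        assert residue_mass_delta("A", "dA") == pytest.approx(15.9949, abs=1e-4)

    def test_identity(self):
        assert residue_mass_delta("A", "A") == 0.0

    def test_unknown_code(self):
        with pytest.raises(KeyError):
            residue_mass_delta("A", "Z")


class TestMz:
    def test_quadruply_protonated_15mer(self):
        assert mz(4835.718, 4) == pytest.approx(1209.937, abs=1e-3)

    def test_water(self):
        assert mz(18.010565, 1) == pytest.approx(19.018, abs=1e-3)

    @given(
        st.floats(min_value=100.0, max_value=10000.0),
        st.integers(min_value=1, max_value=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, mass, n):
        assert neutral_mass_from_mz(mz(mass, n), n) == pytest.approx(mass, rel=1e-12)

    def test_invalid_charge(self):
        with pytest.raises(ValueError):
            mz(100.0, 0)


class TestRegistry:
    def test_duplicate_code_rejected(self):
        registry = default_registry()
        with pytest.raises(ValueError, match="already registered"):
            registry.register("A", "C10H13N5O4", "C5H5N5")

    def test_config_extension(self):
        registry = default_registry()
        registry.update_from_config(
            {
                "residues": [
                    {
                        "code": "m6A",
                        "nucleoside": "C11H15N5O4",
                        "base": "C6H7N5",
                        "basic_n3": True,
                    }
                ]
            }
        )
        seq = parse_sequence("G[m6A]C", registry=registry)
        assert seq.residues[1] == "m6A"
        assert monoisotopic_mass(seq) > 0

    def test_base_must_be_subcomposition(self):
        registry = default_registry()
        with pytest.raises(CompositionError):
            registry.register("bad", "C5H5N5", "C10H13N5O4")
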
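"""Unit tests for the scalar descriptor layer and the sklearn transformer."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from damkit import (
    HARTREE_TO_EV,
    OrbitalPair,
    ReactivityDescriptors,
    SpeciesEnergies,
    descriptor_pipeline,
    electroaccepting_power,
    electrodonating_power,
    electron_affinity,
    gap,
    ionization_potential,
    rank_by,
)
from damkit.dam import DEFAULT_REFERENCES


class TestEnergyDifferences:
    def test_identity_cases_give_zero(self):
        e = SpeciesEnergies("x", -10.0, -10.0, -10.0)
        assert ionization_potential(e) == 0.0
        assert electron_affinity(e) == 0.0

    def test_hartree_inputs_convert_with_codata_factor(self):
        e = SpeciesEnergies("x", -1000.000000, -999.714100, -1000.0, unit="hartree")
        assert ionization_potential(e) == pytest.approx(0.285900 * HARTREE_TO_EV, abs=1e-9)
        assert ionization_potential(e) == pytest.approx(7.7797, abs=5e-4)

    def test_negative_affinity_when_anion_above_neutral(self):
        # unbound extra electron: A < 0, the sign convention of the sulfone parent
        e = SpeciesEnergies("x", 0.0, 5.0, 1.10)
        assert electron_affinity(e) == pytest.approx(-1.10)

    def test_unit_token_validated(self):
        with pytest.raises(ValueError, match="kcal"):
            SpeciesEnergies("x", 0.0, 1.0, -1.0, unit="kcal")

    def test_non_finite_energy_rejected_naming_compound(self):
        with pytest.raises(ValueError, match="badcmp"):
            SpeciesEnergies("badcmp", float("nan"), 1.0, -1.0)


class TestGap:
    def test_degenerate_orbitals_give_zero_gap(self):
        assert gap(OrbitalPair("x", -5.0, -5.0)) == 0.0

    @pytest.mark.parametrize(
        "homo,lumo,expected",
        [(-7.25, -0.30, 6.95), (-7.66, -1.57, 6.09)],
    )
    def test_panel_values(self, homo, lumo, expected):
        assert gap(OrbitalPair("x", homo, lumo)) == pytest.approx(expected, abs=1e-12)

    def test_inverted_ordering_warns_but_computes(self):
        with pytest.warns(UserWarning, match="unphysical"):
            pair = OrbitalPair("x", -1.0, -2.0)
        assert gap(pair) == pytest.approx(-1.0)


class TestOmegaPowers:
    def test_analytic_values(self):
        assert electrodonating_power(1.0, 0.0) == pytest.approx(9.0 / 16.0, abs=1e-15)
        assert electroaccepting_power(1.0, 0.0) == pytest.approx(1.0 / 16.0, abs=1e-15)

    @pytest.mark.parametrize(
        "i_pot,e_aff,wm,wp",
        [
            (7.78, -1.10, 3.48, 0.14),   # sulfone parent
            (21.26, 1.84, 13.86, 2.31),  # fluorine anchor
            (8.63, 1.65, 6.79, 1.65),    # nitro derivative
            (7.63, -1.64, 3.04, 0.05),   # BHT standard
        ],
    )
    def test_panel_values(self, i_pot, e_aff, wm, wp):
        assert electrodonating_power(i_pot, e_aff) == pytest.approx(wm, abs=0.01)
        assert electroaccepting_power(i_pot, e_aff) == pytest.approx(wp, abs=0.01)

    def test_degenerate_denominator_rejected_naming_compound(self):
        with pytest.raises(ValueError, match="cmp7"):
            electrodonating_power(1.0, 1.0, "cmp7")
        with pytest.raises(ValueError, match="cmp7"):
            electroaccepting_power(0.0, 1.0, "cmp7")


class TestReactivityDescriptorsTransformer:
    def test_direct_input(self):
        X = pd.DataFrame({"compound_id": ["DDS"], "i_pot": [7.78], "e_aff": [-1.10]})
        out = ReactivityDescriptors(input_kind="direct").fit_transform(X)
        assert out.loc[0, "omega_minus"] == pytest.approx(3.48, abs=0.01)
        assert out.loc[0, "omega_plus"] == pytest.approx(0.14, abs=0.01)

    def test_auto_detects_energies_and_converts_units(self):
        X = pd.DataFrame(
            {
                "compound_id": ["a"],
                "e_neutral": [-1000.0],
                "e_cation": [-999.7],
                "e_anion": [-1000.05],
                "unit": ["hartree"],
            }
        )
        out = ReactivityDescriptors().fit_transform(X)
        assert out.loc[0, "i_pot"] == pytest.approx(0.3 * HARTREE_TO_EV)
        assert out.loc[0, "e_aff"] == pytest.approx(0.05 * HARTREE_TO_EV)

    def test_auto_detects_orbitals(self):
        X = pd.DataFrame({"compound_id": ["a"], "e_homo": [-7.0], "e_lumo": [-1.0]})
        out = ReactivityDescriptors().fit_transform(X)
        assert list(out.columns) == ["compound_id", "gap"]
        assert out.loc[0, "gap"] == pytest.approx(6.0)

    def test_duplicate_ids_rejected(self):
        X = pd.DataFrame({"compound_id": ["a", "a"], "i_pot": [8, 8], "e_aff": [1, 1.2]})
        with pytest.raises(ValueError, match="duplicate"):
            ReactivityDescriptors(input_kind="direct").fit(X)

    def test_strict_false_yields_nan_for_inverted_ia(self):
        X = pd.DataFrame({"compound_id": ["a", "b"], "i_pot": [8.0, 1.0], "e_aff": [1.0, 2.0]})
        out = ReactivityDescriptors(input_kind="direct", strict=False).fit_transform(X)
        assert np.isfinite(out.loc[0, "omega_minus"])
        assert np.isnan(out.loc[1, "omega_minus"])
        with pytest.raises(ValueError, match="'b'"):
            ReactivityDescriptors(input_kind="direct").fit_transform(X)

    def test_sklearn_clone_compatible(self):
        est = ReactivityDescriptors(input_kind="direct", strict=False)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()


class TestDescriptorPipeline:
    def test_empty_inputs_give_empty_output(self):
        assert descriptor_pipeline() == []

    def test_energy_only_and_orbital_only_compounds(self):
        records = descriptor_pipeline(
            energies=[SpeciesEnergies("e1", 0.0, 8.0, -1.0)],
            orbitals=[OrbitalPair("o1", -7.0, -1.0)],
        )
        by_id = {r.compound_id: r for r in records}
        assert by_id["e1"].descriptors.omega_minus is not None
        assert by_id["e1"].descriptors.gap is None
        assert by_id["o1"].descriptors.gap == pytest.approx(6.0)
        assert by_id["o1"].descriptors.omega_minus is None

    def test_compound_in_both_inputs_gets_everything(self):
        records = descriptor_pipeline(
            energies=[SpeciesEnergies("c", 0.0, 8.0, -1.0)],
            orbitals=[OrbitalPair("c", -7.0, -1.0)],
            ref=DEFAULT_REFERENCES,
        )
        (rec,) = records
        assert rec.descriptors.gap == pytest.approx(6.0)
        assert rec.descriptors.i_pot == pytest.approx(8.0)
        assert rec.dam is not None

    def test_duplicate_between_energies_and_direct_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            descriptor_pipeline(
                energies=[SpeciesEnergies("c", 0.0, 8.0, -1.0)],
                direct=[("c", 8.0, 1.0)],
            )

    def test_hartree_and_ev_paths_agree(self):
        ev = SpeciesEnergies("c", -100.0, -92.0, -101.0, unit="eV")
        ha = SpeciesEnergies(
            "c",
            -100.0 / HARTREE_TO_EV,
            -92.0 / HARTREE_TO_EV,
            -101.0 / HARTREE_TO_EV,
            unit="hartree",
        )
        r_ev = descriptor_pipeline(energies=[ev], ref=DEFAULT_REFERENCES)[0]
        r_ha = descriptor_pipeline(energies=[ha], ref=DEFAULT_REFERENCES)[0]
        for attr in ("i_pot", "e_aff", "omega_minus", "omega_plus"):
            assert getattr(r_ha.descriptors, attr) == pytest.approx(
                getattr(r_ev.descriptors, attr), abs=1e-9
            )


class TestRankBy:
    def test_single_record(self):
        records = descriptor_pipeline(direct=[("only", 8.0, 1.0)])
        assert rank_by(records, "omega_minus") == ["only"]

    def test_direction_and_tie_break(self):
        records = descriptor_pipeline(direct=[("b", 8.0, 1.0), ("a", 8.0, 1.0), ("c", 9.0, 1.0)])
        assert rank_by(records, "i_pot") == ["a", "b", "c"]  # tie a/b -> lexicographic
        assert rank_by(records, "i_pot", direction="descending") == ["c", "b", "a"]

    def test_missing_key_rejected(self):
        records = descriptor_pipeline(direct=[("a", 8.0, 1.0)])
        with pytest.raises(ValueError, match="ra"):
            rank_by(records, "ra")  # no DAM point without a reference
        with pytest.raises(ValueError, match="gap"):
            rank_by(records, "gap")

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown ranking key"):
            rank_by([], "chirality")
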
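"""Reference SRM methods: fixture fidelity, annotation, validation, CSV I/O."""

import dataclasses

import pytest

from oxidha.srm import (
    SRMMethod,
    SRMTransition,
    annotate_method,
    method_frame,
    read_transitions,
    reference_method,
    reference_performance,
    validate_method,
    write_transitions,
)


class TestReferenceFixtures:
    def test_transition_counts(self, hdohe_method, hpdohe_method):
        # 12 analytes x (quantitative + qualitative) + 2 internal standards
        assert len(hdohe_method.transitions) == 26
        assert len(hpdohe_method.transitions) == 26
        assert len(hdohe_method.analytes) == 12

    def test_classes_never_mix(self, hdohe_method, hpdohe_method):
        assert all("HDoHE" in a for a in hdohe_method.analytes)
        assert all("HpDoHE" in a for a in hpdohe_method.analytes)

    def test_printed_rows_hdohe(self, hdohe_method):
        t = hdohe_method.transition("17-HDoHE", "quantitative")
        assert (t.precursor_mz, t.product_mz) == (343.10, 201.10)
        assert (t.cone_voltage, t.collision_energy) == (27, 14)
        assert t.expected_rt == 6.46
        assert t.peak_group == 14
        q = hdohe_method.transition("5-HDoHE", "qualitative")
        assert (q.precursor_mz, q.product_mz) == (343.20, 93.10)

    def test_printed_rows_hpdohe(self, hpdohe_method):
        t = hpdohe_method.transition("17-HpDoHE", "quantitative")
        assert (t.precursor_mz, t.product_mz) == (341.30, 111.20)
        assert (t.cone_voltage, t.collision_energy) == (30, 12)
        assert t.expected_rt == 7.03
        # the one analyte whose two transitions differ in product and voltages
        q8 = hpdohe_method.transition("8-HpDoHE", "quantitative")
        u8 = hpdohe_method.transition("8-HpDoHE", "qualitative")
        assert (q8.precursor_mz, q8.product_mz) == (359.30, 108.30)
        assert (u8.precursor_mz, u8.product_mz) == (341.30, 113.10)
        assert (u8.cone_voltage, u8.collision_energy) == (31, 9)

    def test_internal_standard_transitions(self, hdohe_method, hpdohe_method):
        for method in (hdohe_method, hpdohe_method):
            is_pairs = {
                (t.precursor_mz, t.product_mz)
                for t in method.transitions
                if t.role == "internal_standard"
            }
            assert is_pairs == {(327.20, 116.10), (327.20, 184.20)}
        assert hdohe_method.dwell_time_ms == 9.0

    def test_roles_complete(self, hdohe_method, hpdohe_method):
        for method in (hdohe_method, hpdohe_method):
            for analyte in method.analytes:
                roles = {t.role for t in method.transitions_for(analyte)}
                assert roles == {"quantitative", "qualitative"}

    def test_performance_tables(self):
        hd = reference_performance("HDoHE").set_index("analyte_id")
        assert hd.loc["7-HDoHE", "lod_pg"] == 0.46
        assert hd.loc["20-HDoHE", "r_squared"] == 0.998
        hp = reference_performance("HpDoHE").set_index("analyte_id")
        assert hp.loc["10-HpDoHE", "lod_pg"] == 671.0
        assert hp.loc["20-HpDoHE", "calibrated_range"] == "0.25-10"

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            reference_method("HETE")


class TestAnnotation:
    def test_every_analyte_transition_annotated(self, hdohe_method):
        annotated = annotate_method(hdohe_method)
        for t in annotated.transitions:
            assert t.annotation is not None
            if t.role == "internal_standard":
                assert t.annotation == "internal standard, not enumerated"

    def test_20_hdohe_quantitative_assignment(self, hdohe_method):
        annotated = annotate_method(hdohe_method)
        assert (
            annotated.transition("20-HDoHE", "quantitative").annotation
            == "[αcc+H-CO2]-"
        )

    def test_dehydrated_precursor_rows_resolve(self, hpdohe_method):
        """Rows selecting the in-source dehydrated ion (nominal 341) are
        annotated against the [M-H-H2O]- fragment set."""
        annotated = annotate_method(hpdohe_method)
        t = annotated.transition("16-HpDoHE", "quantitative")
        assert t.precursor_mz == 341.20
        assert t.annotation == "[αcc+H]-"


class TestValidation:
    def test_reference_methods_have_no_hard_conflicts(
        self, hdohe_method, hpdohe_method
    ):
        for method in (hdohe_method, hpdohe_method):
            assert not [d for d in validate_method(method) if d[0] == "error"]

    def test_coelution_notes(self, hpdohe_method):
        notes = [m for s, m in validate_method(hpdohe_method) if s == "note"]
        assert any("10-HpDoHE" in n and "11-HpDoHE" in n for n in notes)
        assert any("7-HpDoHE" in n and "8-HpDoHE" in n for n in notes)

    def test_missing_qualitative_flagged(self, hdohe_method):
        pruned = dataclasses.replace(
            hdohe_method,
            transitions=tuple(
                t
                for t in hdohe_method.transitions
                if not (t.analyte_id == "17-HDoHE" and t.role == "qualitative")
            ),
        )
        diags = validate_method(pruned)
        assert ("error", "analyte 17-HDoHE lacks qualitative transition") in diags

    def test_duplicate_transition_flagged(self, hdohe_method):
        dup = hdohe_method.transitions[0]
        method = dataclasses.replace(
            hdohe_method, transitions=hdohe_method.transitions + (dup,)
        )
        assert any(
            s == "error" and "duplicate" in m for s, m in validate_method(method)
        )

    def test_shared_transition_at_same_rt_is_hard_conflict(self):
        t1 = SRMTransition("A-HDoHE", 343.1, 201.1, "quantitative", 30, 14, 6.46)
        t2 = SRMTransition("B-HDoHE", 343.1, 201.1, "quantitative", 30, 14, 6.47)
        method = SRMMethod("clash", "HDoHE", (t1, t2))
        assert any(
            s == "error" and "co-elute on the same transition" in m
            for s, m in validate_method(method)
        )


class TestCsvRoundTrip:
    def test_write_read_identity(self, tmp_path, hpdohe_method):
        path = tmp_path / "method.csv"
        write_transitions(hpdohe_method, path)
        back = read_transitions(path)
        assert back.analyte_class == "HpDoHE"
        assert [t.key for t in back.transitions] == [
            t.key for t in hpdohe_method.transitions
        ]
        for a, b in zip(back.transitions, hpdohe_method.transitions):
            assert a == b

    def test_duplicate_row_rejected_with_row_number(self, tmp_path, hdohe_method):
        path = tmp_path / "method.csv"
        df = method_frame(hdohe_method)
        df.loc[len(df)] = df.iloc[0]
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 28"):
            read_transitions(path)

    def test_hand_added_analyte_accepted_when_both_roles_present(
        self, tmp_path, hdohe_method
    ):
        path = tmp_path / "method.csv"
        df = method_frame(hdohe_method)
        for role, prod in (("quantitative", "199.10"), ("qualitative", "243.10")):
            df.loc[len(df)] = [
                "21-HDoHE", "HDoHE", "343.10", prod, role, 30, 14, "9.10", 22,
            ]
        df.to_csv(path, index=False)
        method = read_transitions(path)
        assert "21-HDoHE" in method.analytes
        assert not [d for d in validate_method(method) if d[0] == "error"]

    def test_malformed_mz_rejected(self, tmp_path, hdohe_method):
        path = tmp_path / "method.csv"
        df = method_frame(hdohe_method)
        df.loc[0, "precursor_mz"] = "abc"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 2"):
            read_transitions(path)

    def test_unknown_role_rejected(self, tmp_path, hdohe_method):
        path = tmp_path / "method.csv"
        df = method_frame(hdohe_method)
        df.loc[0, "role"] = "confirm"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="unknown role"):
            read_transitions(path)
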
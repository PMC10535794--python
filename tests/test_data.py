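"""Domain types, CSV round-trip, validation, guidelines and summaries."""

import numpy as np
import pandas as pd
import pytest

from troutrisk.data import (
    Matrix,
    builtin_guidelines,
    guidelines_frame,
    lookup_guideline,
    read_concentrations,
    summarize,
    validate_concentrations,
    write_concentrations,
)
from troutrisk.errors import ConfigurationError, EmptyGroupError, ValidationError


def _frame(rows):
    return pd.DataFrame(
        rows, columns=["sector", "matrix", "element", "replicate_id", "concentration"]
    )


class TestValidation:
    def test_single_valid_row_identity(self):
        out = validate_concentrations(_frame([("lower", "muscle", "Pb", 1, 0.24)]))
        assert len(out) == 1
        assert out.loc[0, "concentration"] == 0.24
        assert out.loc[0, "replicate_id"] == 1

    @pytest.mark.parametrize(
        "row, fragment",
        [
            (("lower", "muscle", "Pb", 1, -0.1), "negative concentration"),
            (("lowest", "muscle", "Pb", 1, 0.2), "unknown sector"),
            (("lower", "plasma", "Pb", 1, 0.2), "unknown matrix"),
            (("lower", "muscle", "Hg", 1, 0.2), "unknown element"),
            (("lower", "muscle", "Pb", 0, 0.2), "replicate_id"),
            (("lower", "muscle", "Pb", 1.5, 0.2), "replicate_id"),
            (("lower", "muscle", "Pb", 1, np.nan), "non-finite"),
        ],
    )
    def test_invalid_rows_rejected_naming_row(self, row, fragment):
        with pytest.raises(ValidationError, match="row 0") as err:
            validate_concentrations(_frame([row]))
        assert fragment in str(err.value)

    def test_duplicate_key_rejected(self):
        rows = [("lower", "muscle", "Pb", 1, 0.2), ("lower", "muscle", "Pb", 1, 0.3)]
        with pytest.raises(ValidationError, match="duplicate"):
            validate_concentrations(_frame(rows))

    def test_missing_column_rejected(self):
        with pytest.raises(ValidationError, match="concentration"):
            validate_concentrations(
                pd.DataFrame({"sector": ["lower"], "matrix": ["muscle"],
                              "element": ["Pb"], "replicate_id": [1]})
            )

    def test_full_design_row_count(self, survey_dataset):
        # 3 sectors x 3 matrices x 4 elements x 12 replicates
        assert len(survey_dataset) == 432


class TestCsvRoundTrip:
    def test_write_read_bit_exact(self, tmp_path, survey_dataset):
        path = tmp_path / "conc.csv"
        write_concentrations(survey_dataset, path)
        back = read_concentrations(path)
        pd.testing.assert_frame_equal(back, survey_dataset)

    def test_schema_column_mapping(self, tmp_path):
        path = tmp_path / "renamed.csv"
        pd.DataFrame(
            {"sector": ["lower"], "matrix": ["muscle"], "element": ["Pb"],
             "replicate_id": [1], "value_mgkg": [0.24]}
        ).to_csv(path, index=False)
        out = read_concentrations(path, schema={"concentration": "value_mgkg"})
        assert out.loc[0, "concentration"] == 0.24

    def test_missing_file(self, tmp_path):
        with pytest.raises(ValidationError, match="not found"):
            read_concentrations(tmp_path / "nope.csv")


class TestGuidelines:
    def test_registry_has_twelve_unique_limits(self):
        limits = builtin_guidelines()
        assert len(limits) == 12
        keys = {(g.matrix, g.element, g.source) for g in limits}
        assert len(keys) == 12
        assert all(g.value > 0 for g in limits)

    @pytest.mark.parametrize(
        "matrix, element, value, source",
        [
            (Matrix.MUSCLE, "Pb", 0.3, "FAO/WHO"),
            (Matrix.MUSCLE, "As", 2.0, "FSANZ"),
            (Matrix.MUSCLE, "Cu", 30.0, "FAO/WHO"),
            (Matrix.MUSCLE, "Zn", 30.0, "FAO/WHO"),
            (Matrix.WATER, "As", 0.01, "USEPA"),
            (Matrix.WATER, "Cu", 1.3, "USEPA"),
            (Matrix.WATER, "Pb", 0.015, "USEPA"),
            (Matrix.WATER, "Zn", 5.0, "USEPA"),
            (Matrix.SEDIMENT, "As", 5.9, "CEQG-ISQG"),
            (Matrix.SEDIMENT, "Cu", 35.7, "CEQG-ISQG"),
            (Matrix.SEDIMENT, "Pb", 35.0, "CEQG-ISQG"),
            (Matrix.SEDIMENT, "Zn", 123.0, "CEQG-ISQG"),
        ],
    )
    def test_registered_maximum_limits(self, matrix, element, value, source):
        g = lookup_guideline(matrix, element)
        assert g.value == value
        assert g.source == source

    def test_unknown_limit_raises(self):
        with pytest.raises(ConfigurationError):
            lookup_guideline(Matrix.WATER, "Hg")

    def test_register_element_requires_valid_toxicity(self):
        from troutrisk.data import ELEMENTS, register_element

        with pytest.raises(ConfigurationError):
            register_element("Cd", rfd=-1.0)
        with pytest.raises(ConfigurationError):
            register_element("Pb", rfd=0.0035)  # already registered
        try:
            info = register_element("Cd", rfd=1e-3, arm=0.5)
            assert not info.carcinogen
            out = validate_concentrations(_frame([("lower", "muscle", "Cd", 1, 0.1)]))
            assert len(out) == 1
        finally:
            ELEMENTS.pop("Cd", None)

    def test_units_follow_matrix(self):
        frame = guidelines_frame()
        assert set(frame.loc[frame.matrix == "water", "units"]) == {"mg/L"}
        assert set(frame.loc[frame.matrix == "muscle", "units"]) == {"mg/kg w/w"}


class TestSummarize:
    def test_even_n_median_is_midpoint(self):
        frame = _frame([("lower", "muscle", "Pb", i + 1, v) for i, v in enumerate([1, 2, 3, 4])])
        out = summarize(frame)
        assert out.loc[0, "median"] == 2.5
        assert out.loc[0, "mean"] == 2.5
        assert out.loc[0, "n"] == 4

    def test_odd_n_median_is_central_value(self):
        frame = _frame(
            [("lower", "muscle", "Pb", i + 1, v) for i, v in enumerate([0.2, 0.24, 0.28])]
        )
        assert summarize(frame).loc[0, "median"] == 0.24

    def test_median_invariant_under_permutation(self, survey_dataset):
        shuffled = survey_dataset.sample(frac=1, random_state=3).reset_index(drop=True)
        a = summarize(survey_dataset).sort_values(["sector", "matrix", "element"])
        b = summarize(shuffled).sort_values(["sector", "matrix", "element"])
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_replicate_count_conserved(self, survey_dataset):
        assert (summarize(survey_dataset)["n"] == 12).all()

    def test_empty_dataset_raises(self):
        with pytest.raises(EmptyGroupError):
            summarize(_frame([]))
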
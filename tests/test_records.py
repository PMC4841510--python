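"""Twin-cohort record validation, CSV round-trips and cohort pooling."""

from collections import Counter

import pytest

from twinpaf import (
    TwinCohortRecord,
    ValidationError,
    bundled_table2,
    combine_records,
    estimate,
    read_twin_table,
    write_twin_table,
)
from twinpaf.errors import TableFormatError


def _record(**overrides):
    base = dict(
        disease_name="Example disease",
        category="other",
        country="Nowhere",
        sex_subset="both",
        n_pairs_total=100,
        n_concordant=5,
        n_discordant=20,
    )
    base.update(overrides)
    return TwinCohortRecord(**base)


class TestValidation:
    @pytest.mark.parametrize(
        "overrides",
        [
            {"n_pairs_total": 0},
            {"n_concordant": -1},
            {"n_concordant": 6, "n_discordant": 95},  # N_C + N_D > N_T
            {"category": "metabolic"},
            {"sex_subset": "unknown"},
            {"n_pairs_total": 10, "n_concordant": 6, "n_discordant": 5},
        ],
    )
    def test_invariant_violations_rejected(self, overrides):
        with pytest.raises(ValidationError):
            _record(**overrides)

    def test_bundled_disease_must_keep_its_category(self):
        with pytest.raises(ValidationError, match="categorised"):
            _record(disease_name="Asthma", category="other")

    def test_affected_individual_count(self):
        assert _record().n_affected_individuals == 2 * 5 + 20


class TestTableIO:
    def test_round_trip_identity(self, tmp_path, table2_records):
        path = tmp_path / "table.csv"
        write_twin_table(table2_records, path)
        assert read_twin_table(path) == table2_records

    def test_single_row_file(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text(
            "disease_name,category,country,sex_subset,"
            "n_pairs_total,n_concordant,n_discordant\n"
            'Bladder cancer,cancer,"Sweden, Denmark, Finland",both,15668,5,189\n',
            encoding="utf-8",
        )
        (record,) = read_twin_table(path)
        assert record.n_pairs_total == 15668
        assert record.n_concordant == 5
        assert record.n_discordant == 189

    def test_thousands_separators_rejected(self, tmp_path):
        path = tmp_path / "sep.csv"
        path.write_text(
            "disease_name,category,country,sex_subset,"
            "n_pairs_total,n_concordant,n_discordant\n"
            'Bladder cancer,cancer,Sweden,both,"15,668",5,189\n',
            encoding="utf-8",
        )
        with pytest.raises(ValidationError, match="thousands"):
            read_twin_table(path)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "missing.csv"
        path.write_text(
            "disease_name,category,country,sex_subset,n_pairs_total,n_concordant\n"
            "X,other,Y,both,10,1\n",
            encoding="utf-8",
        )
        with pytest.raises(TableFormatError, match="n_discordant"):
            read_twin_table(path)

    def test_invariant_violation_names_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "disease_name,category,country,sex_subset,"
            "n_pairs_total,n_concordant,n_discordant\n"
            "X,other,Y,both,10,6,5\n",
            encoding="utf-8",
        )
        with pytest.raises(ValidationError, match="row 1"):
            read_twin_table(path)

    def test_empty_table_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "disease_name,category,country,sex_subset,"
            "n_pairs_total,n_concordant,n_discordant\n",
            encoding="utf-8",
        )
        with pytest.raises(ValidationError, match="empty"):
            read_twin_table(path)


class TestBundledTable:
    def test_has_28_rows_with_expected_category_sizes(self, table2_records):
        assert len(table2_records) == 28
        counts = Counter(r.category for r in table2_records)
        assert counts == {
            "cancer": 9,
            "cardiovascular": 2,
            "neurological": 4,
            "lung": 2,
            "obesity-associated": 2,
            "autoimmune": 3,
            "genitourinary": 3,
            "other": 3,
        }

    @pytest.mark.parametrize(
        "name, counts, category",
        [
            ("Asthma", (5084, 257, 447), "lung"),
            ("Type 1 diabetes", (4307, 3, 20), "autoimmune"),
            ("Migraine", (9077, 382, 1377), "neurological"),
            ("Stroke-related death", (3852, 35, 316), "cardiovascular"),
        ],
    )
    def test_spot_counts(self, table2_records, name, counts, category):
        record = next(r for r in table2_records if r.disease_name == name)
        assert (record.n_pairs_total, record.n_concordant, record.n_discordant) == counts
        assert record.category == category

    def test_pooled_cancer_cohort_sizes_are_shared(self, table2_records):
        """The six sex-combined cancer rows all come from the same pooled
        Nordic registry of 15,668 MZ pairs; the three sex-specific cancer
        rows report that registry's female (8,437) or male (7,231) halves."""
        sizes = [
            r.n_pairs_total
            for r in table2_records
            if r.category == "cancer" and r.sex_subset == "both"
        ]
        assert sizes == [15668] * 6
        sex_specific = sorted(
            r.n_pairs_total
            for r in table2_records
            if r.category == "cancer" and r.sex_subset != "both"
        )
        assert sex_specific == [7231, 8437, 8437]

    def test_fixture_is_freshly_loaded_each_call(self):
        assert bundled_table2() == bundled_table2()
        assert bundled_table2() is not bundled_table2()


class TestCombineRecords:
    def test_single_record_is_identity(self):
        record = _record()
        assert combine_records([record]) == record

    def test_counts_sum_and_sexes_pool_to_both(self):
        female = _record(sex_subset="female", n_pairs_total=1000, n_concordant=3, n_discordant=10)
        male = _record(sex_subset="male", n_pairs_total=1200, n_concordant=2, n_discordant=8)
        pooled = combine_records([female, male])
        assert (pooled.n_pairs_total, pooled.n_concordant, pooled.n_discordant) == (2200, 5, 18)
        assert pooled.sex_subset == "both"

    def test_order_independent(self):
        female = _record(sex_subset="female", n_pairs_total=1000, n_concordant=3, n_discordant=10)
        male = _record(sex_subset="male", n_pairs_total=1200, n_concordant=2, n_discordant=8)
        assert combine_records([female, male]) == combine_records([male, female])

    def test_combine_then_estimate_equals_estimate_of_sums(self):
        female = _record(sex_subset="female", n_pairs_total=1000, n_concordant=3, n_discordant=10)
        male = _record(sex_subset="male", n_pairs_total=1200, n_concordant=2, n_discordant=8)
        via_combine = estimate(combine_records([female, male]))
        direct = estimate(_record(n_pairs_total=2200, n_concordant=5, n_discordant=18))
        assert via_combine.paf_pct == direct.paf_pct
        assert via_combine.relative_risk == direct.relative_risk

    def test_conflicting_names_rejected(self):
        with pytest.raises(ValidationError, match="conflicting"):
            combine_records([_record(), _record(disease_name="Other disease")])

    def test_duplicate_sex_subset_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            combine_records([_record(sex_subset="female"), _record(sex_subset="female")])

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            combine_records([])
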
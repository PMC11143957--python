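"""Family-table IO and preprocessing operations."""

import io

import numpy as np
import pandas as pd
import pytest

import pgstransmit as pt

HEADER = ("family_id,zygosity,pgs_mother,pgs_father,pgs_twin1,pgs_twin2,"
          "pheno_twin1,pheno_twin2")


def _read(text, **kw):
    return pt.read_family_table(io.StringIO(text), **kw)


class TestReadFamilyTable:
    def test_missing_cell_parsed_as_missing(self):
        data = _read(HEADER + "\nF1,MZ,0.1,,0.3,0.3,1.2,0.9\n")
        rec = data.records[0]
        assert rec.pgs_father is None
        assert rec.pgs_mother == pytest.approx(0.1)
        assert rec.zygosity == "MZ"

    def test_empty_file_gives_empty_collection(self):
        data = _read("")
        assert len(data) == 0

    def test_na_sentinel_equivalent_to_empty_string(self):
        a = _read(HEADER + "\nF1,MZ,0.1,NA,0.3,0.3,1.2,0.9\n",
                  na_values=("", "NA"))
        b = _read(HEADER + "\nF1,MZ,0.1,,0.3,0.3,1.2,0.9\n")
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_unknown_zygosity_names_row(self):
        with pytest.raises(ValueError, match="zygosity.*row 1"):
            _read(HEADER + "\nF1,MZ,0,0,0,0,0,0\nF2,QQ,0,0,0,0,0,0\n")

    def test_duplicate_family_id_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            _read(HEADER + "\nF1,MZ,0,0,0,0,0,0\nF1,DZ,0,0,0,0,0,0\n")

    def test_column_map_renames_to_canonical(self):
        text = ("fid,zyg,m,f,t1,t2,p1,p2\nF1,DZ,0.1,0.2,0.3,0.4,0.5,0.6\n")
        schema = dict(zip(pt.data.CANONICAL_COLUMNS,
                          ("fid", "zyg", "m", "f", "t1", "t2", "p1", "p2")))
        data = _read(text, schema=schema)
        assert data.records[0].pgs_twin2 == pytest.approx(0.4)

    def test_all_missing_record_flagged_unusable(self):
        data = _read(HEADER + "\nF1,MZ,,,,,,\n")
        assert not data.records[0].usable


class TestPropagateMzGenotypes:
    def _data(self, rows):
        return _read(HEADER + "\n" + "\n".join(rows) + "\n")

    def test_copies_to_missing_mz_cotwin(self):
        out = pt.propagate_mz_genotypes(self._data(["F1,MZ,,,0.42,,,"]))
        assert out.records[0].pgs_twin2 == pytest.approx(0.42)
        out = pt.propagate_mz_genotypes(self._data(["F1,MZ,,,,0.42,,"]))
        assert out.records[0].pgs_twin1 == pytest.approx(0.42)

    def test_dz_families_untouched(self):
        out = pt.propagate_mz_genotypes(self._data(["F1,DZ,,,0.42,,,"]))
        assert out.records[0].pgs_twin2 is None

    def test_both_missing_stay_missing(self):
        out = pt.propagate_mz_genotypes(self._data(["F1,MZ,,,,,1.0,"]))
        assert out.records[0].pgs_twin1 is None
        assert out.records[0].pgs_twin2 is None

    def test_idempotent(self):
        data = self._data(["F1,MZ,0.1,,0.42,,,", "F2,DZ,,,0.3,0.1,0.5,"])
        once = pt.propagate_mz_genotypes(data)
        twice = pt.propagate_mz_genotypes(once)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_unequal_observed_mz_values_left_as_is(self, caplog):
        with caplog.at_level("WARNING"):
            out = pt.propagate_mz_genotypes(self._data(["F1,MZ,,,0.4,0.6,,"]))
        assert out.records[0].pgs_twin1 == pytest.approx(0.4)
        assert out.records[0].pgs_twin2 == pytest.approx(0.6)
        assert any("unequal" in r.message for r in caplog.records)


class TestScoreSymptoms:
    def test_all_zero_and_all_two(self):
        assert pt.score_symptoms(np.zeros((4, 5))) == 0.0
        assert pt.score_symptoms(np.full((4, 5), 2.0)) == 2.0

    def test_period_score_is_mean_of_occasion_means(self):
        # occasion means 1.0 and 0.4 -> 0.7
        ratings = np.array([[1, 1, 1, 1, 1], [0, 0, 1, 1, 0]], dtype=float)
        assert pt.score_symptoms(ratings) == pytest.approx(0.7)

    def test_missing_occasion_skipped_and_item_order_irrelevant(self):
        ratings = np.array([[2, 0, np.nan], [np.nan] * 3], dtype=float)
        assert pt.score_symptoms(ratings) == pytest.approx(1.0)
        rng = np.random.default_rng(0)
        r = rng.integers(0, 3, size=(4, 5)).astype(float)
        base = pt.score_symptoms(r)
        assert pt.score_symptoms(r[::-1]) == pytest.approx(base)
        assert pt.score_symptoms(r[:, ::-1]) == pytest.approx(base)

    def test_no_rated_items_gives_missing_not_zero(self):
        assert np.isnan(pt.score_symptoms(np.full((3, 5), np.nan)))

    def test_out_of_scale_rating_rejected(self):
        with pytest.raises(ValueError, match="0, 1, 2"):
            pt.score_symptoms(np.array([[3.0]]))


class TestTransformAdjust:
    def test_constant_scores_give_zero_residuals(self):
        out = pt.transform_adjust([1.0, 1.0, 1.0, 1.0], ["M", "F", "M", "F"])
        assert np.abs(out).max() < 1e-12

    def test_sex_saturated_design_gives_zero_residuals(self):
        out = pt.transform_adjust([1.0, 1.0, 0.25, 0.25], ["M", "M", "F", "F"])
        assert np.abs(out).max() < 1e-12

    def test_single_sex_intercept_only(self):
        out = pt.transform_adjust([1.0, 0.0, 0.25], ["M", "M", "M"])
        assert out == pytest.approx([0.5, -0.5, 0.0], abs=1e-12)

    def test_negative_score_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            pt.transform_adjust([-0.1, 1.0], ["M", "F"])

    def test_residuals_uncorrelated_with_sex(self):
        rng = np.random.default_rng(5)
        scores = rng.uniform(0, 2, 200)
        sex = rng.integers(0, 2, 200)
        out = pt.transform_adjust(scores, sex)
        assert abs(np.corrcoef(out, sex)[0, 1]) < 1e-10

    def test_missing_scores_stay_missing(self):
        out = pt.transform_adjust([1.0, np.nan, 0.25], ["M", "F", "F"])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2]]).all()


class TestResidualizePgs:
    def test_constant_covariates_give_standardized_input(self):
        pgs = np.array([1.0, 2.0, 3.0, 4.0])
        out = pt.residualize_pgs(pgs, np.zeros((4, 3)))
        expect = (pgs - pgs.mean()) / pgs.std()
        assert out == pytest.approx(expect)

    def test_perfect_linear_dependence_raises_on_standardization(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(ValueError, match="zero variance"):
            pt.residualize_pgs(2.0 * x + 1.0, x[:, None])

    def test_hand_ols_example(self):
        out = pt.residualize_pgs(np.array([1.0, 2.0, 3.0]),
                                 np.array([[1.0], [0.0], [0.0]]),
                                 standardize=False)
        assert out == pytest.approx([0.0, -0.5, 0.5], abs=1e-12)

    def test_residuals_uncorrelated_with_every_covariate(self):
        rng = np.random.default_rng(9)
        cov = rng.normal(size=(300, 10))
        pgs = cov @ rng.normal(size=10) * 0.2 + rng.normal(size=300)
        out = pt.residualize_pgs(pgs, cov)
        for j in range(10):
            assert abs(np.corrcoef(out, cov[:, j])[0, 1]) < 1e-10
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std() == pytest.approx(1.0)

    def test_missing_covariates_blank_that_person(self):
        cov = np.array([[1.0], [np.nan], [0.5], [0.2]])
        out = pt.residualize_pgs(np.array([1.0, 2.0, 3.0, 4.0]), cov)
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_collinear_covariates_named(self):
        cov = pd.DataFrame({"pc1": [1.0, 2, 3, 4], "pc2": [2.0, 4, 6, 8],
                            "pc3": [0.3, -1, 2, 0.5]})
        with pytest.raises(ValueError, match="pc2"):
            pt.residualize_pgs(np.array([1.0, 0, 2, 1]), cov)


class TestPreprocessPersonTable:
    def _person_frame(self):
        rows = []
        rng = np.random.default_rng(2)
        for fid, zyg in (("F1", "MZ"), ("F2", "DZ")):
            for role in ("mother", "father", "twin1", "twin2"):
                # MZ co-twin genotype left ungenotyped; propagation fills it
                pgs = np.nan if (zyg == "MZ" and role == "twin2") \
                    else float(rng.normal())
                row = {"family_id": fid, "role": role, "zygosity": zyg,
                       "sex": "F" if role in ("mother", "twin1") else "M",
                       "pgs": pgs,
                       "pc1": float(rng.normal())}
                for o in (1, 2):
                    for i in (1, 2, 3):
                        row[f"occ{o}_item{i}"] = (
                            int(rng.integers(0, 3)) if role.startswith("twin")
                            else np.nan)
                rows.append(row)
        return pd.DataFrame(rows)

    def test_full_chain_produces_canonical_family_rows(self):
        persons = self._person_frame()
        items = {"occ1": ["occ1_item1", "occ1_item2", "occ1_item3"],
                 "occ2": ["occ2_item1", "occ2_item2", "occ2_item3"]}
        data = pt.data.preprocess_person_table(
            persons, covariate_cols=["pc1"], occasion_items=items)
        assert len(data) == 2
        rec = data.records[0]
        assert rec.zygosity == "MZ"
        # MZ propagation keeps both twin PGS present and equal
        assert rec.pgs_twin1 == rec.pgs_twin2
        vals, _ = data.arrays()
        pgs = vals[:, :4]
        # pooled re-standardization over the 7 genotyped persons (the
        # propagated MZ co-twin cell is a duplicate, not a new person)
        genotyped = np.delete(pgs.ravel(), 3)     # drop F1 twin2 slot
        assert np.nanmean(genotyped) == pytest.approx(0.0, abs=1e-10)
        assert np.nanstd(genotyped) == pytest.approx(1.0, abs=1e-10)

    def test_missing_member_leaves_missing_cells(self):
        persons = self._person_frame()
        persons = persons[~((persons.family_id == "F2")
                            & (persons.role == "father"))]
        items = {"occ1": ["occ1_item1", "occ1_item2", "occ1_item3"]}
        data = pt.data.preprocess_person_table(persons, occasion_items=items)
        assert data.records[1].pgs_father is None

    def test_unknown_role_rejected(self):
        persons = self._person_frame()
        persons.loc[0, "role"] = "uncle"
        with pytest.raises(ValueError, match="uncle"):
            pt.data.preprocess_person_table(persons, score_col="pgs")
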
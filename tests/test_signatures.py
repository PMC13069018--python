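"""Gene sets, metagene scoring, quantile dichotomization and the
CDKPredX classifier rule."""

import numpy as np
import pandas as pd
import pytest

from cdkpredx import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    apply_to_external_cohort,
    classify_cdkpredx,
    dichotomize,
    metagene_score,
    read_gmt,
    write_gmt,
)
from cdkpredx.signatures import MissingGenesError

from conftest import independent_score_matrix


def _expr(values, genes, samples=None):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestGmt:
    def test_parse_basic_line(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("SET1\tdesc\tG1\tG2\n")
        coll = read_gmt(p)
        assert coll["SET1"].genes == ("G1", "G2")
        assert coll["SET1"].description == "desc"

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("A\td\tG1\nA\td\tG2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(p)

    def test_malformed_line_rejected(self, tmp_path):
        p = tmp_path / "x.gmt"
        p.write_text("ONLYNAME\tdesc\n")
        with pytest.raises(ValueError, match="malformed"):
            read_gmt(p)

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection()
        coll.add(GeneSet("A", ("G1", "G2"), "first"))
        coll.add(GeneSet("B", ("G9",), "second"))
        write_gmt(coll, tmp_path / "rt.gmt")
        back = read_gmt(tmp_path / "rt.gmt")
        assert {gs.name: gs.genes for gs in back} == {gs.name: gs.genes for gs in coll}

    def test_empty_and_duplicate_gene_sets_invalid(self):
        with pytest.raises(ValueError):
            GeneSet("E", ())
        with pytest.raises(ValueError):
            GeneSet("D", ("G1", "G1"))


class TestMetageneScore:
    def test_constant_matrix(self):
        expr = _expr(np.full((4, 3), 2.5), ["a", "b", "c", "d"])
        score = metagene_score(expr, GeneSet("S", ("a", "c")))
        assert np.allclose(score.values, 2.5)

    def test_mean_of_two_genes(self):
        expr = _expr([[2.0], [4.0]], ["a", "b"])
        assert metagene_score(expr, GeneSet("S", ("a", "b"))).iloc[0] == 3.0

    def test_missing_genes_error_names_absentees(self):
        genes_present = [f"p{i}" for i in range(40)]
        genes_missing = [f"m{i}" for i in range(47)]
        expr = _expr(np.zeros((40, 2)), genes_present)
        gs = GeneSet("BIG", tuple(genes_present + genes_missing))
        with pytest.raises(MissingGenesError) as exc:
            metagene_score(expr, gs, min_fraction_present=0.5)
        assert exc.value.missing == genes_missing

    def test_score_bounded_by_member_genes(self, rng):
        values = rng.normal(size=(10, 5))
        genes = [f"g{i}" for i in range(10)]
        expr = _expr(values, genes)
        score = metagene_score(expr, GeneSet("S", tuple(genes[:6])))
        lo = values[:6].min(axis=0)
        hi = values[:6].max(axis=0)
        assert ((score.values >= lo) & (score.values <= hi)).all()


class TestDichotomize:
    def test_median_split_of_1_to_8(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
        calls, thr = dichotomize(scores, "median")
        assert thr == 4.5
        assert (calls == "high").sum() == 4

    def test_lower_quartile_split_of_1_to_8(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=list("abcdefgh"))
        calls, thr = dichotomize(scores, "lower_quartile")
        assert thr == 2.75
        assert (calls == "high").sum() == 6

    def test_all_equal_degenerates_to_all_high_with_warning(self):
        scores = pd.Series([3.0, 3.0, 3.0])
        with pytest.warns(UserWarning, match="identical"):
            calls, _ = dichotomize(scores, "median")
        assert (calls == "high").all()

    def test_tie_at_threshold_is_high(self):
        scores = pd.Series([1.0, 2.0, 2.0, 3.0])
        calls, thr = dichotomize(scores, "median")
        assert thr == 2.0
        assert (calls == "high").sum() == 3


class TestClassifier:
    def _modules(self):
        coll = GeneSetCollection()
        for name, g in (("Pr", "PRG"), ("Er", "ERG"), ("Im", "IMG")):
            coll.add(GeneSet(name, (g,)))
        return coll

    def _matrix(self):
        # 8 samples with controlled scores: thresholds are Pr Q1,
        # Er median, Im median of each row
        values = pd.DataFrame(
            {
                f"s{i}": v
                for i, v in enumerate(
                    np.array(
                        [
                            [9, 9, 9, 9, 9, 9, 1, 1],   # PRG: s6,s7 below Q1
                            [9, 9, 9, 9, 1, 1, 9, 9],   # ERG
                            [1, 1, 9, 9, 1, 1, 9, 9],   # IMG
                        ],
                        dtype=float,
                    ).T
                )
            },
            index=["PRG", "ERG", "IMG"],
        )
        return ExpressionMatrix(values)

    def test_rule_positive_and_negative_calls(self):
        res = classify_cdkpredx(self._matrix(), self._modules())
        t = res.table
        # s0, s1: high Pr, high Er, low Im -> positive
        assert t.loc["s0", "label"] == "positive"
        assert t.loc["s1", "label"] == "positive"
        # s2: Im high -> negative despite high Pr/Er
        assert t.loc["s2", "label"] == "negative"
        # s4: Er low -> negative; s6: Pr low -> negative
        assert t.loc["s4", "label"] == "negative"
        assert t.loc["s6", "label"] == "negative"

    def test_partition_every_sample_labeled_once(self):
        res = classify_cdkpredx(self._matrix(), self._modules())
        assert set(res.table["label"]) <= {"positive", "negative"}
        assert res.table["label"].notna().all()
        assert len(res.table) == 8

    def test_prevalence_under_independent_modules(self):
        expr = independent_score_matrix(2000, seed=42)
        res = classify_cdkpredx(expr, self._modules())
        # P(high Pr) * P(high Er) * P(low Im) = 0.75 * 0.5 * 0.5
        assert abs(res.positive_fraction - 0.1875) < 0.03

    def test_monotonicity_raising_im_flips_positive(self):
        expr = self._matrix()
        res = classify_cdkpredx(expr, self._modules())
        assert res.table.loc["s0", "label"] == "positive"
        bumped = expr.values.copy()
        bumped.loc["IMG", "s0"] = res.thresholds["im_median"] + 10.0
        res2 = classify_cdkpredx(ExpressionMatrix(bumped), self._modules())
        assert res2.table.loc["s0", "label"] == "negative"

    def test_label_invariance_under_increasing_transform(self):
        expr = independent_score_matrix(200, seed=9)
        res1 = classify_cdkpredx(expr, self._modules())
        transformed = ExpressionMatrix(3.0 * expr.values + 11.0)
        res2 = classify_cdkpredx(transformed, self._modules())
        assert (res1.labels == res2.labels).all()

    def test_missing_module_set_errors(self):
        coll = GeneSetCollection()
        coll.add(GeneSet("Pr", ("PRG",)))
        with pytest.raises(KeyError, match="Er"):
            classify_cdkpredx(self._matrix(), coll)


class TestExternalCohort:
    def _setup(self):
        coll = GeneSetCollection()
        for name, g in (("Pr", "PRG"), ("Er", "ERG"), ("Im", "IMG")):
            coll.add(GeneSet(name, (g,)))
        return independent_score_matrix(150, seed=3), coll

    def test_self_application_matches_derivation(self):
        expr, coll = self._setup()
        a = classify_cdkpredx(expr, coll)
        b = apply_to_external_cohort(expr, coll, "external")
        assert (a.labels == b.labels).all()
        assert b.cohort == "external"

    def test_global_shift_invariant_in_quantile_mode(self):
        expr, coll = self._setup()
        a = classify_cdkpredx(expr, coll)
        shifted = ExpressionMatrix(expr.values + 3.0)
        b = apply_to_external_cohort(shifted, coll, "shifted")
        assert (a.labels == b.labels).all()

    def test_global_shift_changes_labels_in_absolute_mode(self):
        expr, coll = self._setup()
        a = classify_cdkpredx(expr, coll)
        shifted = ExpressionMatrix(expr.values + 3.0)
        b = apply_to_external_cohort(
            shifted, coll, "shifted", mode="absolute", reference_thresholds=a.thresholds
        )
        # every score clears the old Pr/Er thresholds and the Im cut,
        # so the label pattern cannot be identical
        assert not (a.labels == b.labels).all()
        assert (b.table["pr_call"] == "high").all()

    def test_absolute_mode_requires_thresholds(self):
        expr, coll = self._setup()
        with pytest.raises(ValueError, match="reference_thresholds"):
            apply_to_external_cohort(expr, coll, "x", mode="absolute")
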
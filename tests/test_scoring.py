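"""Scoring engine: allele matching, dosage rules, both paths, export."""

import numpy as np
import pytest

from prskit import (
    SKIP,
    ContractViolation,
    EmptyTableError,
    GenotypeCall,
    MissingPolicy,
    RoleKind,
    ScoreVariant,
    VariantKey,
    WeightTable,
    effect_dosage,
    export_results,
    filter_weights_by_annotation,
    match_effect_allele,
    matrix_from_calls,
    read_results,
    score_dense,
    score_sparse,
    sparsify,
)
from conftest import make_random_matrix

KEY = VariantKey("chr1", 100, "A", ("G",))


class TestMatchEffectAllele:
    @pytest.mark.parametrize(
        "effect,other,kind,index",
        [
            ("G", "A", RoleKind.ALT_EFFECT, 1),
            ("A", "G", RoleKind.REF_EFFECT, 0),
            ("T", None, RoleKind.UNMATCHED, None),
            ("G", None, RoleKind.ALT_EFFECT, 1),
            # other allele inconsistent with the site -> degrade to UNMATCHED
            ("G", "T", RoleKind.UNMATCHED, None),
        ],
    )
    def test_biallelic_matching(self, effect, other, kind, index):
        role = match_effect_allele(KEY, effect, other)
        assert role.kind is kind
        if index is not None:
            assert role.allele_index == index

    def test_multiallelic_matches_correct_alt_index(self):
        key = VariantKey("chr1", 100, "A", ("C", "T"))
        assert match_effect_allele(key, "T", "A").allele_index == 2
        assert match_effect_allele(key, "C", "A").allele_index == 1


class TestEffectDosage:
    @pytest.mark.parametrize(
        "call,role_allele,expected",
        [
            (GenotypeCall(0, 1), 1, 1),
            (GenotypeCall(1, 1), 1, 2),
            (GenotypeCall(0, 0), 1, 0),
            (GenotypeCall(0, 0), 0, 2),
            (GenotypeCall(0, 1), 0, 1),
        ],
    )
    def test_counting(self, call, role_allele, expected):
        role = match_effect_allele(KEY, "A" if role_allele == 0 else "G")
        assert effect_dosage(call, role) == expected

    def test_missing_call_skip_under_exclude(self):
        role = match_effect_allele(KEY, "G")
        assert effect_dosage(GenotypeCall(-1, -1), role, MissingPolicy.EXCLUDE) is SKIP

    def test_missing_call_hom_ref_fill(self):
        # the sparse-path assumption: a no-call is two reference alleles
        ref_role = match_effect_allele(KEY, "A")
        alt_role = match_effect_allele(KEY, "G")
        assert effect_dosage(GenotypeCall(-1, -1), ref_role, MissingPolicy.HOM_REF) == 2
        assert effect_dosage(GenotypeCall(-1, -1), alt_role, MissingPolicy.HOM_REF) == 0

    def test_unmatched_role_is_contract_violation(self):
        role = match_effect_allele(KEY, "T")
        with pytest.raises(ContractViolation):
            effect_dosage(GenotypeCall(0, 1), role)


def wt_of(*rows):
    return WeightTable(
        "S", "GRCh38",
        [ScoreVariant("S", c, p, e, o, w) for c, p, e, o, w in rows],
    )


class TestScoreDense:
    def test_two_variant_arithmetic(self):
        m = matrix_from_calls(
            ["s"],
            [
                (VariantKey("chr1", 100, "A", ("G",)), [GenotypeCall(0, 1)]),
                (VariantKey("chr1", 200, "C", ("T",)), [GenotypeCall(1, 1)]),
            ],
        )
        wt = wt_of(("chr1", 100, "G", "A", 0.5), ("chr1", 200, "T", "C", -0.2))
        run = score_dense(m, wt)
        assert run[0].prs_sum == pytest.approx(1 * 0.5 + 2 * -0.2)
        assert run[0].n_variants_found == 2
        assert run[0].n_variants_in_score == 2

    def test_absent_variant_contributes_nothing(self):
        m = matrix_from_calls(
            ["s"], [(VariantKey("chr1", 100, "A", ("G",)), [GenotypeCall(0, 1)])]
        )
        wt = wt_of(("chr1", 100, "G", "A", 0.5), ("chr9", 999, "T", "C", 4.0))
        run = score_dense(m, wt)
        assert run[0].prs_sum == pytest.approx(0.5)
        assert run[0].n_variants_found == 1
        assert run.n_absent == 1

    def test_unmatched_variant_skipped_and_tallied(self):
        m = matrix_from_calls(
            ["s"], [(VariantKey("chr1", 100, "A", ("G",)), [GenotypeCall(0, 1)])]
        )
        wt = wt_of(("chr1", 100, "T", None, 4.0), ("chr1", 100, "G", "A", 0.5))
        run = score_dense(m, wt)
        assert run.n_unmatched == 1
        assert run[0].prs_sum == pytest.approx(0.5)

    def test_empty_weight_table_is_error(self, toy_matrix):
        with pytest.raises((EmptyTableError, Exception)):
            score_dense(toy_matrix, WeightTable("S", "GRCh38", []))

    def test_matches_nested_loop_recomputation(self, rng):
        """Vectorised dense scorer vs an independent pure-Python oracle."""
        m = make_random_matrix(rng, 100, 500, missing_rate=0.1, n_alts_max=2)
        rows = []
        for i, key in enumerate(m.variants):
            if i % 7 == 0:  # some REF-effect rows
                rows.append((key.chrom, key.pos, key.ref, key.alts[0],
                             float(rng.normal())))
            else:
                alt = key.alts[int(rng.integers(len(key.alts)))]
                rows.append((key.chrom, key.pos, alt, key.ref, float(rng.normal())))
        wt = wt_of(*rows)
        for policy in (MissingPolicy.EXCLUDE, MissingPolicy.HOM_REF):
            run = score_dense(m, wt, policy=policy)
            for si in range(m.n_samples):
                total = 0.0
                found = 0
                for sv in wt.variants:
                    vi = m.locus_index[(sv.chrom, sv.pos)]
                    role = match_effect_allele(
                        m.variants[vi], sv.effect_allele, sv.other_allele
                    )
                    if role.kind is RoleKind.UNMATCHED:
                        continue
                    d = effect_dosage(m.call(vi, si), role, policy)
                    if d is SKIP:
                        continue
                    found += 1
                    total += d * sv.weight
                assert run[si].prs_sum == pytest.approx(total, abs=1e-12)
                assert run[si].n_variants_found == found

    def test_monotonicity_adding_positive_variant(self, toy_matrix):
        wt1 = wt_of(("chr1", 100, "G", "A", 0.5))
        wt2 = wt_of(("chr1", 100, "G", "A", 0.5), ("chr2", 500, "T", None, 0.3))
        r1 = score_dense(toy_matrix, wt1)
        r2 = score_dense(toy_matrix, wt2)
        for a, b in zip(r1, r2):
            assert b.prs_sum >= a.prs_sum


class TestScoreSparse:
    def test_equals_dense_path_without_missing(self, clean_cohort):
        dense, wt = clean_cohort.dense, clean_cohort.weights
        vds = sparsify(dense)
        for policy in (MissingPolicy.EXCLUDE, MissingPolicy.HOM_REF):
            rd = score_dense(dense, wt, policy=policy)
            rs = score_sparse(vds, wt, policy=policy)
            assert np.array_equal(rd.prs, rs.prs)  # bitwise identical
            assert [r.n_variants_found for r in rd] == [
                r.n_variants_found for r in rs
            ]

    def test_qc_failed_weight_excluded_before_scoring(self, small_cohort):
        vds = sparsify(small_cohort.dense)
        run = score_sparse(vds, small_cohort.weights, ann=small_cohort.annotation)
        n_failed = int(small_cohort.qc_failed.sum())
        assert run.n_removed_by_qc == n_failed
        assert run.n_variants_in_score == len(small_cohort.weights) - n_failed
        assert run[0].n_variants_in_score == run.n_variants_in_score

    def test_blocks_covering_all_loci_force_homref_sum(self):
        keys = [
            VariantKey("chr1", 100, "A", ("G",)),
            VariantKey("chr1", 200, "C", ("T",)),
        ]
        m = matrix_from_calls(
            ["s"], [(k, [GenotypeCall(0, 0)]) for k in keys]
        )
        vds = sparsify(m)
        wt = wt_of(("chr1", 100, "A", "G", 0.7), ("chr1", 200, "T", "C", 0.4))
        # ann supplies REF/ALT orientation since no entries are stored
        from prskit import AnnotationTable

        ann = AnnotationTable(
            {
                ("chr1", 100, "A", "G"): {"passed_qc": True, "allele_freq": 0.2},
                ("chr1", 200, "C", "T"): {"passed_qc": True, "allele_freq": 0.2},
            }
        )
        run = score_sparse(vds, wt, ann=ann)
        # REF-effect variant contributes 2*w, ALT-effect contributes 0
        assert run[0].prs_sum == pytest.approx(2 * 0.7)
        assert run[0].n_variants_found == 2

    def test_policy_discrepancy_equals_enumeration(self, small_cohort):
        """sparse(HOM_REF) - dense(EXCLUDE) is exactly the hom-ref dosage
        sum over each sample's missing weight-variants."""
        dense, ann = small_cohort.dense, small_cohort.annotation
        wt = filter_weights_by_annotation(small_cohort.weights, ann)
        vds = sparsify(dense)
        rd = score_dense(dense, wt, policy=MissingPolicy.EXCLUDE)
        rs = score_sparse(vds, small_cohort.weights, ann=ann,
                          policy=MissingPolicy.HOM_REF)
        diff = rs.prs - rd.prs
        expected = np.zeros(dense.n_samples)
        for sv in wt.variants:
            vi = dense.locus_index[(sv.chrom, sv.pos)]
            role = match_effect_allele(
                dense.variants[vi], sv.effect_allele, sv.other_allele
            )
            hr = 2 if role.allele_index == 0 else 0
            missing = dense.alleles[vi, :, 0] < 0
            expected += missing * hr * sv.weight
        assert np.abs(expected).max() > 0  # the check is not vacuous
        np.testing.assert_allclose(diff, expected, atol=1e-9)

    def test_homref_policy_found_count_constant_across_samples(self, small_cohort):
        vds = sparsify(small_cohort.dense)
        run = score_sparse(vds, small_cohort.weights, policy=MissingPolicy.HOM_REF)
        counts = {r.n_variants_found for r in run}
        assert len(counts) == 1


class TestContributionsAndExport:
    def test_contributions_sum_to_prs(self, small_cohort):
        run = score_dense(
            small_cohort.dense, small_cohort.weights, collect_contributions=True
        )
        for r in run:
            total = sum(p for _, _, _, p in r.contributions)
            assert abs(total - r.prs_sum) <= 1e-12 * max(1.0, abs(r.prs_sum))

    def test_export_and_read_back_full_precision(self, tmp_path, small_cohort):
        run = score_dense(small_cohort.dense, small_cohort.weights)
        p = str(tmp_path / "res.tsv")
        export_results(run, p)
        back = read_results(p)
        assert [r.sample_id for r in back] == run.sample_ids
        assert [r.prs_sum for r in back] == [r.prs_sum for r in run]

    def test_export_row_counts(self, tmp_path):
        from prskit import ScoreResult

        results = [
            ScoreResult(f"s{i}", 0.1 * i, 2, 3) for i in range(3)
        ]
        p = tmp_path / "r.tsv"
        export_results(results, str(p))
        lines = p.read_text().splitlines()
        assert len(lines) == 4  # header + 3 rows

    def test_contribution_file_rows_sum_to_prs(self, tmp_path, toy_matrix):
        wt = wt_of(("chr1", 100, "G", "A", 0.5), ("chr2", 500, "T", "G", 0.25))
        run = score_dense(toy_matrix, wt, collect_contributions=True)
        p = tmp_path / "r.tsv"
        export_results(run, str(p), include_contributions=True)
        import pandas as pd

        contrib = pd.read_csv(str(p) + ".contributions.tsv", sep="\t")
        sums = contrib.groupby("sample_id")["product"].sum()
        for r in run:
            if r.n_variants_found:
                assert sums[r.sample_id] == pytest.approx(r.prs_sum, abs=1e-12)

    def test_empty_results_gives_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        export_results([], str(p))
        assert p.read_text().splitlines() == [
            "sample_id\tprs_sum\tn_variants_found\tn_variants_in_score"
        ]
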
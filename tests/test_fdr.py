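"""Permutation null construction and the FDR ratio estimator."""

import numpy as np
import pandas as pd
import pytest

from mmsurv import FdrThresholds, build_null, estimate_fdr, permute_clinical, screen_mms
from mmsurv.screening import MMSAssociation

from conftest import cohort_inputs


class TestPermuteClinical:
    def test_row_multiset_conserved(self, null_cohort):
        clin = null_cohort.clinical
        perm = permute_clinical(clin, np.random.default_rng(0))
        cols = ["os_months", "os_event", "age"]
        before = clin.rows[cols].sort_values(cols).reset_index(drop=True)
        after = perm.rows[cols].sort_values(cols).reset_index(drop=True)
        pd.testing.assert_frame_equal(before, after)
        assert list(perm.rows["sample_id"]) == list(clin.rows["sample_id"])

    def test_whole_rows_travel_together(self, null_cohort):
        clin = null_cohort.clinical
        perm = permute_clinical(clin, np.random.default_rng(1))
        originals = set(map(tuple, clin.rows[["os_months", "age"]].to_numpy()))
        for row in perm.rows[["os_months", "age"]].to_numpy():
            assert tuple(row) in originals

    def test_seed_determinism(self, null_cohort):
        a = permute_clinical(null_cohort.clinical, 99)
        b = permute_clinical(null_cohort.clinical, 99)
        pd.testing.assert_frame_equal(a.rows, b.rows)

    def test_two_samples_two_arrangements(self):
        from mmsurv.io_formats import ClinicalTable

        clin = ClinicalTable(
            pd.DataFrame(
                {"sample_id": ["A", "B"], "os_months": [1.0, 2.0], "os_event": [True, False], "age": [50.0, 60.0]}
            )
        )
        seen = set()
        for seed in range(20):
            perm = permute_clinical(clin, seed)
            seen.add(tuple(perm.rows["os_months"]))
        assert seen == {(1.0, 2.0), (2.0, 1.0)}


class TestBuildNull:
    def test_seed_reproducibility_bitwise(self, null_cohort):
        matrix, clinical, tp53 = cohort_inputs(null_cohort)
        a = build_null(matrix, clinical, tp53, n_permutations=3, seed=11)
        b = build_null(matrix, clinical, tp53, n_permutations=3, seed=11)
        np.testing.assert_array_equal(a.p_rank, b.p_rank)
        np.testing.assert_array_equal(a.beta, b.beta)

    def test_zero_permutations_empty_then_estimator_errors(self, null_cohort):
        matrix, clinical, tp53 = cohort_inputs(null_cohort)
        null = build_null(matrix, clinical, tp53, n_permutations=0, seed=0)
        assert null.p_rank.size == 0
        obs = [MMSAssociation(term_id="GO:0000001")]
        with pytest.raises(ValueError):
            estimate_fdr(obs, null)

    def test_null_p_values_roughly_uniform(self, null_cohort):
        """On a no-effect cohort the null log-rank p-values should look
        uniform: the QQ slope against uniform quantiles is near 1."""
        matrix, clinical, tp53 = cohort_inputs(null_cohort)
        null = build_null(matrix, clinical, tp53, n_permutations=10, seed=2)
        p = np.sort(null.p_rank.ravel())
        q = (np.arange(p.size) + 0.5) / p.size
        slope = np.polyfit(q, p, 1)[0]
        assert 0.8 < slope < 1.2

    def test_long_format_persistence_round_trip(self, null_cohort, tmp_path):
        matrix, clinical, tp53 = cohort_inputs(null_cohort)
        null = build_null(matrix, clinical, tp53, n_permutations=2, seed=3)
        path = tmp_path / "null.tsv"
        null.to_tsv(path)
        df = pd.read_csv(path, sep="\t")
        assert len(df) == 2 * len(matrix.term_ids)
        first = df.iloc[0]
        assert first["p_rank"] == pytest.approx(null.p_rank[0, 0])


def make_null(p_rank, p_cox, cp, beta):
    from mmsurv.fdr import NullDistribution

    arr = lambda v: np.asarray(v, dtype=float)
    pr = arr(p_rank)
    return NullDistribution(
        p_rank=pr,
        p_cox=arr(p_cox),
        cp=arr(cp),
        beta=arr(beta),
        degenerate=np.zeros(pr.shape, dtype=bool),
        term_ids=[f"GO:{j:07d}" for j in range(pr.shape[1])],
        n_permutations=pr.shape[0],
        seed=0,
    )


class TestEstimateFdr:
    def hit(self, term="GO:0000001"):
        return MMSAssociation(term_id=term, beta=-1.0, p_cox=0.001, p_rank=0.001, cp=0.001)

    def miss(self, term="GO:0000002"):
        return MMSAssociation(term_id=term, beta=-1.0, p_cox=0.5, p_rank=0.5, cp=0.5)

    def test_equal_fractions_give_one(self):
        null = make_null([[0.001, 0.5]], [[0.001, 0.5]], [[0.001, 0.5]], [[-1.0, -1.0]])
        est = estimate_fdr([self.hit(), self.miss()], null)
        assert est.fdr == pytest.approx(1.0)

    def test_clean_null_gives_zero(self):
        null = make_null([[0.5, 0.6]], [[0.5, 0.6]], [[0.5, 0.6]], [[-1.0, 1.0]])
        est = estimate_fdr([self.hit(), self.miss()], null)
        assert est.fdr == 0.0

    def test_zero_denominator_undefined(self):
        null = make_null([[0.001]], [[0.001]], [[0.001]], [[-1.0]])
        est = estimate_fdr([self.miss()], null)
        assert not est.defined and np.isnan(est.fdr)

    def test_sign_condition_separates_directions(self):
        null = make_null([[0.001, 0.001]], [[0.001, 0.001]], [[0.001, 0.001]], [[-1.0, 1.0]])
        neg = estimate_fdr([self.hit()], null, sign="negative_beta")
        pos_obs = MMSAssociation(term_id="GO:0000003", beta=1.0, p_cox=0.001, p_rank=0.001, cp=0.001)
        pos = estimate_fdr([pos_obs], null, sign="positive_beta")
        assert neg.null_fraction == pytest.approx(0.5)
        assert pos.null_fraction == pytest.approx(0.5)

    def test_invariant_to_permutation_and_term_order(self):
        rng = np.random.default_rng(7)
        shape = (6, 5)
        pr, pc, b = rng.random(shape), rng.random(shape), rng.normal(size=shape)
        cp = np.sqrt(pr * pc)
        obs = [self.hit(), self.miss()]
        base = estimate_fdr(obs, make_null(pr, pc, cp, b))
        sh = rng.permutation(shape[0])
        to = rng.permutation(shape[1])
        shuffled = estimate_fdr(obs, make_null(pr[sh][:, to], pc[sh][:, to], cp[sh][:, to], b[sh][:, to]))
        assert base.fdr == pytest.approx(shuffled.fdr)

    def test_fdr_clamped_to_unit_interval(self):
        null = make_null([[0.001, 0.001]], [[0.001, 0.001]], [[0.001, 0.001]], [[-1.0, -1.0]])
        est = estimate_fdr([self.hit(), self.miss()], null)
        assert est.fdr == 1.0  # raw ratio 1.0/0.5 = 2, clamped
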
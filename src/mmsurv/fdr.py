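"""Sign-aware permutation estimate of the false discovery rate.

The null model is built by randomly re-assigning whole clinical
records (survival time, event flag, age) to samples while leaving the
mutation profiles — and hence every burden signature — untouched, then
re-running the full screen on each shuffled dataset.  The FDR of a
selection rule is the fraction of null (permutation) results passing
the rule, divided by the fraction of observed results passing it,
restricted to one coefficient sign: protective discoveries (beta < 0)
are compared against protective-looking null results, which matters
because the null distribution of the coefficients is itself
asymmetric.  TP53 status derives from the mutation profile and by
default stays with the sample rather than travelling with the
permuted clinical record; a flag allows the alternative reading.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mmsurv.io_formats import ClinicalTable
from mmsurv.mms import MMSMatrix
from mmsurv.screening import MMSAssociation, _screen_arrays

__all__ = [
    "FdrThresholds",
    "NullDistribution",
    "FdrEstimate",
    "permute_clinical",
    "build_null",
    "estimate_fdr",
]


@dataclass(frozen=True)
class FdrThresholds:
    """Joint p-value thresholds defining a 'discovery'."""

    t_rank: float = 0.05
    t_cox: float = 0.05
    t_cp: float = 0.025

    def __post_init__(self):
        for v in (self.t_rank, self.t_cox, self.t_cp):
            if not 0 < v < 1:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class NullDistribution:
    """Per-permutation, per-term screening statistics under the null.

    Arrays have shape (n_permutations, n_terms); ``degenerate`` marks
    entries whose burden column was constant in that permutation (the
    matrix is fixed, so in practice whole columns).
    """

    p_rank: np.ndarray
    p_cox: np.ndarray
    cp: np.ndarray
    beta: np.ndarray
    degenerate: np.ndarray
    term_ids: list[str]
    n_permutations: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (permutation, term, statistics) for persistence."""
        n_perm, n_terms = self.p_rank.shape
        return pd.DataFrame(
            {
                "permutation": np.repeat(np.arange(n_perm), n_terms),
                "term_id": self.term_ids * n_perm,
                "p_rank": self.p_rank.ravel(),
                "p_cox": self.p_cox.ravel(),
                "cp": self.cp.ravel(),
                "beta": self.beta.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class FdrEstimate:
    """A permutation FDR estimate with its two ingredient fractions."""

    fdr: float
    null_fraction: float
    observed_fraction: float
    defined: bool


def permute_clinical(clinical: ClinicalTable, rng) -> ClinicalTable:
    """Randomly re-assign whole clinical rows to the sample ids.

    Time, event flags and age stay together as one record, so the
    multiset of clinical rows is exactly conserved; only their pairing
    with the (fixed) mutation profiles changes.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    rows = clinical.rows
    perm = rng.permutation(len(rows))
    shuffled = rows.drop(columns=["sample_id"]).iloc[perm].reset_index(drop=True)
    shuffled.insert(0, "sample_id", rows["sample_id"].to_numpy())
    return ClinicalTable(shuffled, n_skipped=0)


def build_null(
    mms: MMSMatrix,
    clinical: ClinicalTable,
    tp53,
    n_permutations: int = 500,
    seed: int = 0,
    endpoint: str = "OS",
    rho: float = 0.0,
    permute_tp53: bool = False,
) -> NullDistribution:
    """Screen ``n_permutations`` clinically shuffled datasets.

    With ``permute_tp53`` the TP53 indicator travels with the clinical
    record instead of staying with the sample's mutation profile.
    """
    rng = np.random.default_rng(seed)
    clin = clinical.subset(mms.sample_ids)
    time, event, keep = clin.endpoint(endpoint)
    age = clin.rows["age"].to_numpy(float)[keep]
    tp53 = np.asarray(tp53)[keep]
    burden = mms.values[keep]
    n = time.size
    n_terms = len(mms.term_ids)

    shape = (n_permutations, n_terms)
    out = {k: np.ones(shape) for k in ("p_rank", "p_cox", "cp")}
    beta = np.zeros(shape)
    degen = np.zeros(shape, dtype=bool)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        t_perm = tp53[perm] if permute_tp53 else tp53
        pr, pc, cp, bt, dg = _screen_arrays(time[perm], event[perm], age[perm], t_perm, burden, rho=rho)
        out["p_rank"][b] = pr
        out["p_cox"][b] = pc
        out["cp"][b] = cp
        beta[b] = bt
        degen[b] = dg
    return NullDistribution(
        p_rank=out["p_rank"],
        p_cox=out["p_cox"],
        cp=out["cp"],
        beta=beta,
        degenerate=degen,
        term_ids=list(mms.term_ids),
        n_permutations=n_permutations,
        seed=seed,
    )


def _discovery_mask(p_rank, p_cox, cp, beta, thresholds: FdrThresholds, sign: str):
    if sign == "negative_beta":
        sign_ok = beta < 0
    elif sign == "positive_beta":
        sign_ok = beta > 0
    else:
        raise ValueError("sign must be 'negative_beta' or 'positive_beta'")
    return (
        (p_rank < thresholds.t_rank)
        & (p_cox < thresholds.t_cox)
        & (cp < thresholds.t_cp)
        & sign_ok
    )


def estimate_fdr(
    observed: list[MMSAssociation],
    null: NullDistribution,
    thresholds: FdrThresholds = FdrThresholds(),
    sign: str = "negative_beta",
) -> FdrEstimate:
    """Ratio of null to observed discovery fractions, one sign at a time.

    The numerator is the fraction of all null (permutation, term)
    results jointly below the three thresholds with the required
    coefficient sign; the denominator is the same fraction over the
    observed associations.  The ratio is clamped to [0, 1]; a zero
    denominator yields an undefined estimate (``defined=False``,
    ``fdr=nan``).
    """
    if null.n_permutations == 0 or null.p_rank.size == 0:
        raise ValueError("null distribution is empty")
    if not observed:
        raise ValueError("no observed associations given")

    valid = ~null.degenerate
    null_hits = _discovery_mask(null.p_rank, null.p_cox, null.cp, null.beta, thresholds, sign)
    null_fraction = float(null_hits[valid].sum() / valid.sum()) if valid.sum() else 0.0

    usable = [a for a in observed if not a.degenerate]
    if not usable:
        raise ValueError("all observed associations are degenerate")
    obs = np.array(
        [[a.p_rank, a.p_cox, a.cp, a.beta] for a in usable], dtype=float
    )
    obs_hits = _discovery_mask(obs[:, 0], obs[:, 1], obs[:, 2], obs[:, 3], thresholds, sign)
    observed_fraction = float(obs_hits.mean())

    if observed_fraction == 0.0:
        return FdrEstimate(float("nan"), null_fraction, observed_fraction, defined=False)
    fdr = min(max(null_fraction / observed_fraction, 0.0), 1.0)
    return FdrEstimate(fdr, null_fraction, observed_fraction, defined=True)
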
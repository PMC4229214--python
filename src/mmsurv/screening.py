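"""Screen every macro mutation signature against a survival endpoint.

Each signature is tested twice, the two tests covering each other's
blind spots: a k-group log-rank test on the burden factorized into the
groups 0 / 1 / 2 (no linearity assumption, but no age adjustment), and
a Cox proportional-hazards model with the burden as a single numeric
covariate alongside age at diagnosis and TP53 mutation status (age
adjusted, but linear in the burden).  Candidates are ranked by the
composite p-value, the geometric mean of the two test p-values, and
selected by the joint rule p_rank < 0.05, p_cox < 0.05, CP < 0.025,
with a relaxed log-rank-only rule (p_rank < 0.01) admitting further
hazard-increasing signatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from mmsurv.io_formats import ClinicalTable
from mmsurv.mms import MMSMatrix
from mmsurv.survival_stats import SurvivalData, coxph_on, logrank_on

__all__ = [
    "MMSAssociation",
    "SelectionRule",
    "PredictorSet",
    "SplitHalfResult",
    "composite_p",
    "screen_mms",
    "select_predictors",
    "split_half_consistency",
]


@dataclass
class MMSAssociation:
    """Screening result for one signature.

    ``beta`` is the Cox log hazard ratio per burden unit (negative =
    protective), ``cp`` the composite p-value, ``n1``/``n2`` the
    member-gene and mutated-member-gene counts, and ``degenerate``
    marks signatures whose burden column was constant (their p-values
    are reported as 1 and they never enter selection).
    """

    term_id: str
    term_name: str = ""
    beta: float = 0.0
    p_cox: float = 1.0
    p_rank: float = 1.0
    cp: float = 1.0
    n1: int = 0
    n2: int = 0
    degenerate: bool = False

    @property
    def direction(self) -> str:
        return "negative" if self.beta < 0 else "positive"


@dataclass(frozen=True)
class SelectionRule:
    """Thresholds of the two-stage predictor selection."""

    strict_p: float = 0.05
    strict_cp: float = 0.025
    relaxed_negative_p_rank: float = 0.01

    def __post_init__(self):
        for v in (self.strict_p, self.strict_cp, self.relaxed_negative_p_rank):
            if not 0 < v < 1:
                raise ValueError("selection thresholds must lie in (0, 1)")


@dataclass
class PredictorSet:
    """Selected signatures, partitioned by effect direction.

    ``positive`` lists protective signatures (beta < 0, longer
    survival with higher burden), ``negative`` hazard-increasing ones;
    both are ordered by composite p-value ascending.
    """

    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)

    def __post_init__(self):
        if set(self.positive) & set(self.negative):
            raise ValueError("a term cannot be both a positive and a negative predictor")


def composite_p(p_rank: float, p_cox: float) -> float:
    """Geometric mean of the log-rank and Cox p-values.

    Lies between the two inputs, so a signature must do reasonably
    well on both tests to rank highly.
    """
    for p in (p_rank, p_cox):
        if not 0 <= p <= 1:
            raise ValueError(f"p-value {p!r} outside [0, 1]")
    return math.sqrt(p_rank * p_cox)


def _screen_arrays(time, event, age, tp53, burden_matrix, rho: float = 0.0):
    """Fast path: screen every burden column, returning plain arrays.

    Returns (p_rank, p_cox, cp, beta, degenerate) each of length
    n_terms.  Shared by the observed screen and the permutation null.
    """
    sd = SurvivalData(time, event)
    n_terms = burden_matrix.shape[1]
    p_rank = np.ones(n_terms)
    p_cox = np.ones(n_terms)
    beta = np.zeros(n_terms)
    degen = np.zeros(n_terms, dtype=bool)
    base = np.column_stack([np.zeros_like(age, dtype=float), age, tp53])
    for j in range(n_terms):
        col = burden_matrix[:, j]
        if np.ptp(col) == 0:
            degen[j] = True
            continue
        p_rank[j] = logrank_on(sd, col, rho=rho).p_value
        base[:, 0] = col
        fit = coxph_on(sd, base)
        beta[j] = fit.beta[0]
        p_cox[j] = fit.p_values[0]
    cp = np.sqrt(p_rank * p_cox)
    return p_rank, p_cox, cp, beta, degen


def screen_mms(
    mms: MMSMatrix,
    clinical: ClinicalTable,
    tp53,
    endpoint: str = "OS",
    rho: float = 0.0,
) -> list[MMSAssociation]:
    """Run both survival tests on every signature.

    ``clinical`` is aligned to the matrix sample order by sample id;
    for the PFS endpoint, samples with a missing endpoint are dropped
    from both tests.  Constant burden columns are flagged degenerate.
    """
    clin = clinical.subset(mms.sample_ids)
    time, event, keep = clin.endpoint(endpoint)
    age = clin.rows["age"].to_numpy(float)[keep]
    tp53 = np.asarray(tp53)[keep]
    burden = mms.values[keep]

    p_rank, p_cox, cp, beta, degen = _screen_arrays(time, event, age, tp53, burden, rho=rho)
    out = []
    for j, term in enumerate(mms.term_ids):
        out.append(
            MMSAssociation(
                term_id=term,
                term_name=mms.term_names.get(term, ""),
                beta=float(beta[j]),
                p_cox=float(p_cox[j]),
                p_rank=float(p_rank[j]),
                cp=float(cp[j]),
                n1=int(mms.n1[j]) if mms.n1 is not None else 0,
                n2=int(mms.n2[j]) if mms.n2 is not None else 0,
                degenerate=bool(degen[j]),
            )
        )
    return out


def select_predictors(
    associations: list[MMSAssociation], rule: SelectionRule = SelectionRule()
) -> PredictorSet:
    """Apply the strict joint rule, then the relaxed negative rule.

    Strict: p_rank and p_cox below ``strict_p`` and CP below
    ``strict_cp``; the survivors split into protective (beta < 0) and
    hazard-increasing (beta >= 0) predictors.  Relaxed: remaining
    hazard-increasing signatures with p_rank below
    ``relaxed_negative_p_rank`` join the negative list.  Both lists
    are ordered by CP ascending with term id breaking ties.
    """
    key = lambda a: (a.cp, a.term_id)
    usable = [a for a in associations if not a.degenerate]
    strict = [
        a
        for a in usable
        if a.p_rank < rule.strict_p and a.p_cox < rule.strict_p and a.cp < rule.strict_cp
    ]
    positive = sorted((a for a in strict if a.beta < 0), key=key)
    negative = sorted((a for a in strict if a.beta >= 0), key=key)
    chosen = {a.term_id for a in strict}
    relaxed = sorted(
        (
            a
            for a in usable
            if a.term_id not in chosen
            and a.beta > 0
            and a.p_rank < rule.relaxed_negative_p_rank
        ),
        key=key,
    )
    return PredictorSet(
        positive=[a.term_id for a in positive],
        negative=[a.term_id for a in negative + relaxed],
    )


@dataclass
class SplitHalfResult:
    """Per-term Cox coefficients re-estimated on two random halves."""

    term_ids: list[str]
    beta_a: np.ndarray
    beta_b: np.ndarray

    @property
    def sign_agreement(self) -> float:
        return float(np.mean(np.sign(self.beta_a) == np.sign(self.beta_b)))


def split_half_consistency(
    mms: MMSMatrix,
    clinical: ClinicalTable,
    tp53,
    predictor_terms: list[str],
    seed: int,
    endpoint: str = "OS",
    rho: float = 0.0,
) -> SplitHalfResult:
    """Re-estimate predictor effects on a random equal-size split.

    The cohort is partitioned into two halves (sizes differing by at
    most one for odd n) and the screen re-run on each half restricted
    to ``predictor_terms``; agreeing coefficient signs indicate a
    robust effect direction.
    """
    n = len(mms.sample_ids)
    if n < 4:
        raise ValueError("need at least 4 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    halves = perm[: n // 2], perm[n // 2 :]
    cols = [mms.term_ids.index(t) for t in predictor_terms]
    tp53 = np.asarray(tp53)

    betas = []
    for half in halves:
        sub = MMSMatrix(
            values=mms.values[np.sort(half)][:, cols],
            sample_ids=[mms.sample_ids[i] for i in np.sort(half)],
            term_ids=list(predictor_terms),
            cap=mms.cap,
            term_names=mms.term_names,
        )
        assoc = screen_mms(sub, clinical, tp53[np.sort(half)], endpoint=endpoint, rho=rho)
        betas.append(np.array([a.beta for a in assoc]))
    return SplitHalfResult(term_ids=list(predictor_terms), beta_a=betas[0], beta_b=betas[1])
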
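"""Bayes/hypergeometric model of nodal staging accuracy.

If a patient truly harbors ``p`` positive nodes among a nodal population
of ``M`` and pathology examines ``n`` of them without replacement, the
observed positive count ``k`` is hypergeometric.  Combining that sampling
model with a prior over ``p`` (estimated from thoroughly examined
patients) gives, via Bayes' theorem, the probability that a patient
declared node-negative actually harbors occult positive nodes — as a
function of how many nodes were examined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NodePrior",
    "detection_pmf",
    "estimate_prior",
    "occult_probability",
    "occult_table",
]


@dataclass
class NodePrior:
    """Probability mass over the true number of positive nodes per patient."""

    support: np.ndarray
    mass: np.ndarray
    source: str = "custom"

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=int)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.support.shape != self.mass.shape or self.support.ndim != 1:
            raise ValueError("support and mass must be 1-D arrays of equal length")
        if (self.mass < 0).any():
            raise ValueError("prior masses must be non-negative")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError(f"prior masses must sum to 1 (got {self.mass.sum():.12f})")
        if (self.support < 0).any() or len(np.unique(self.support)) != len(self.support):
            raise ValueError("support must be distinct non-negative integers")

    @classmethod
    def from_dict(cls, masses: dict[int, float], source: str = "custom") -> "NodePrior":
        support = np.array(sorted(masses), dtype=int)
        return cls(support, np.array([masses[p] for p in support]), source)

    @property
    def p_max(self) -> int:
        return int(self.support.max())


def detection_pmf(p_true: int, m_total: int, n_examined: int) -> np.ndarray:
    """Pr(k observed positives | p_true positives among m_total, n examined).

    Sampling is without replacement, so the result is the hypergeometric
    pmf evaluated on k = 0 ... min(p_true, n_examined); it sums to 1 within
    1e-12 (scipy computes it via log-gamma, avoiding factorial overflow).
    """
    if not 0 <= p_true <= m_total:
        raise ValueError(f"p_true must lie in [0, m_total={m_total}], got {p_true}")
    if not 1 <= n_examined <= m_total:
        raise ValueError(
            f"n_examined must lie in [1, m_total={m_total}], got {n_examined}")
    k = np.arange(0, min(p_true, n_examined) + 1)
    pmf = stats.hypergeom.pmf(k, m_total, p_true, n_examined)
    total = pmf.sum()
    if abs(total - 1.0) > 1e-12:
        pmf = pmf / total
    return pmf


def estimate_prior(cohort: pd.DataFrame, min_eln: int | None = None,
                   min_patients: int = 50) -> NodePrior:
    """Empirical prior over true positive-node counts.

    Patients with ``eln_count >= min_eln`` (default: the cohort's 90th
    percentile of ELN count) are treated as near-completely sampled, so
    their observed positive counts estimate the latent distribution.
    """
    if min_eln is None:
        min_eln = int(np.percentile(cohort["eln_count"], 90))
    qualifying = cohort.loc[cohort["eln_count"] >= min_eln, "positive_count"]
    if len(qualifying) < min_patients:
        raise ValueError(
            f"only {len(qualifying)} patients have eln_count >= {min_eln}; "
            f"at least {min_patients} are required to estimate the prior")
    counts = qualifying.value_counts().sort_index()
    support = counts.index.to_numpy(dtype=int)
    mass = counts.to_numpy(dtype=float)
    return NodePrior(support, mass / mass.sum(), source="empirical")


def occult_probability(prior: NodePrior, m_total: int, n_examined: int,
                       k_observed: int = 0) -> float:
    """Posterior probability of occult disease: Pr(p > k | k seen in n).

    Bayes over the prior with hypergeometric likelihoods:
    ``sum_{p>k} prior(p) L(k|p) / sum_p prior(p) L(k|p)``.
    """
    if not 0 <= k_observed <= n_examined:
        raise ValueError(f"need 0 <= k_observed <= n_examined, got k={k_observed}, n={n_examined}")
    if not 1 <= n_examined <= m_total:
        raise ValueError(f"n_examined must lie in [1, m_total={m_total}], got {n_examined}")
    if prior.p_max > m_total:
        raise ValueError(f"prior support exceeds m_total={m_total}")
    like = stats.hypergeom.pmf(k_observed, m_total, prior.support, n_examined)
    weighted = prior.mass * like
    denom = weighted.sum()
    if denom <= 0:
        raise ValueError(
            f"observation (k={k_observed}, n={n_examined}) has zero probability "
            "under the prior; posterior is undefined")
    return float(weighted[prior.support > k_observed].sum() / denom)


def occult_table(prior: NodePrior, m_total: int,
                 n_range: range | None = None,
                 k_values: tuple[int, ...] = (0,)) -> pd.DataFrame:
    """Tabulate occult-disease probability across examined-node counts.

    Rows are indexed by ``n``; the ``k = 0`` column — probability of >= 1
    undetected positive node in declared node-negative disease — is the
    primary output and is non-increasing in ``n``, reaching exactly 0 at
    ``n = m_total`` (full sampling leaves nothing undetected).
    """
    if n_range is None:
        n_range = range(1, m_total + 1)
    rows = {}
    for k in k_values:
        col = []
        for n in n_range:
            if k > n:
                col.append(np.nan)
                continue
            try:
                col.append(occult_probability(prior, m_total, n, k))
            except ValueError:
                col.append(np.nan)  # observation impossible under the prior
        rows[f"p_occult_given_k{k}"] = col
    table = pd.DataFrame(rows, index=pd.Index(list(n_range), name="n_examined"))
    return table
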
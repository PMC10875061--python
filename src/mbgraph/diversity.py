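"""Alpha and beta diversity metrics used as node attributes.

Conventions (documented deliberately, since names alone are ambiguous):

* Shannon entropy and Jensen-Shannon divergence use the natural logarithm,
  so both are reported in nats. Shannon's maximum is ``ln(S_obs)``;
  JSD's maximum (disjoint supports) is ``ln 2``.
* Chao1 is the classic estimator ``S_obs + F1^2 / (2 F2)`` with the
  bias-corrected fallback ``S_obs + F1 (F1 - 1) / 2`` when no doubletons
  exist (F1 = number of singletons, F2 = number of doubletons).
* Jaccard is computed on presence/absence, not abundance-weighted.
* Jensen-Shannon is reported as a divergence, not its square root.
"""
from __future__ import annotations

import numpy as np

from .errors import DegenerateInputError, ValidationError
from .types import AbundanceTable, DistanceMatrix

__all__ = [
    "chao1",
    "shannon",
    "inverse_simpson",
    "bray_curtis",
    "jaccard",
    "jensen_shannon",
    "beta_matrix",
    "BETA_METRICS",
]


def _counts(x, name="counts") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D vector")
    if (x < 0).any():
        raise ValidationError(f"{name} must be non-negative")
    return x


def chao1(counts) -> float:
    """Chao1 richness estimate from a vector of integer counts.

    Always at least the observed richness; equals it when no singletons
    are present.
    """
    x = _counts(counts)
    if x.sum() == 0:
        raise DegenerateInputError("all-zero count vector")
    s_obs = int((x > 0).sum())
    f1 = int((x == 1).sum())
    f2 = int((x == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts) -> float:
    """Shannon entropy H = -sum p ln p, in nats."""
    x = _counts(counts)
    total = x.sum()
    if total == 0:
        raise DegenerateInputError("all-zero count vector")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def inverse_simpson(counts) -> float:
    """Inverse Simpson index 1 / sum p^2; ranges from 1 to S_obs."""
    x = _counts(counts)
    total = x.sum()
    if total == 0:
        raise DegenerateInputError("all-zero count vector")
    p = x / total
    return float(1.0 / (p * p).sum())


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = _counts(x, "x")
    y = _counts(y, "y")
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    return x, y


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x, y = _pair(x, y)
    denom = (x + y).sum()
    if denom == 0:
        raise DegenerateInputError("both vectors are all-zero")
    return float(np.abs(x - y).sum() / denom)


def jaccard(x, y) -> float:
    """Binary Jaccard dissimilarity 1 - |A∩B| / |A∪B| over supports."""
    x, y = _pair(x, y)
    a = x > 0
    b = y > 0
    union = (a | b).sum()
    if union == 0:
        raise DegenerateInputError("both vectors have empty support")
    return float(1.0 - (a & b).sum() / union)


def jensen_shannon(x, y) -> float:
    """Jensen-Shannon divergence (nats) between row-normalised proportions.

    JSD(p, q) = 0.5 KL(p||m) + 0.5 KL(q||m) with m = (p + q)/2. Symmetric,
    bounded by ln 2, and zero iff the proportion vectors coincide.
    """
    x, y = _pair(x, y)
    if x.sum() == 0 or y.sum() == 0:
        raise DegenerateInputError("a vector sums to zero")
    p = x / x.sum()
    q = y / y.sum()
    m = 0.5 * (p + q)
    # 0 * log(0/m) := 0; m > 0 wherever p > 0 or q > 0
    def kl(a, b):
        mask = a > 0
        return float((a[mask] * np.log(a[mask] / b[mask])).sum())

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)


BETA_METRICS = {
    "bray_curtis": bray_curtis,
    "jaccard": jaccard,
    "jensen_shannon": jensen_shannon,
}


def beta_matrix(table: AbundanceTable, metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise beta-diversity matrix over the samples of a table."""
    if metric not in BETA_METRICS:
        raise ValidationError(
            f"unknown metric {metric!r}; choose from {sorted(BETA_METRICS)}"
        )
    counts = table.counts
    keep = counts.sum(axis=1) > 0
    labels = [s for s, k in zip(table.sample_ids, keep) if k]
    counts = counts[keep]
    n = len(labels)
    if n < 2:
        raise DegenerateInputError(
            f"need at least 2 non-empty samples, have {n}"
        )
    fn = BETA_METRICS[metric]
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(counts[i], counts[j])
    return DistanceMatrix(labels=labels, values=values)
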
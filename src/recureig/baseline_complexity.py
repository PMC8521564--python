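"""Sample entropy baseline and gait signal preprocessing.

Sample entropy (SampEn) is the negative log conditional probability that
two subsequences matching for m points (within a Chebyshev tolerance
delta) still match at m+1 points. Regular signals score near 0; when no
(m+1)-template pair matches, the conditional probability is 0 and SampEn
is infinite, reported here as an explicit sentinel rather than silently
averaged away.

Gait swing-interval records are smoothed with a third-order 1-D median
filter that treats the signal as zero beyond the endpoints, then truncated
to their first 120 samples so all subjects share a common length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.spatial.distance import pdist

__all__ = [
    "SampEnConfig",
    "SampEnResult",
    "sample_entropy",
    "median_filter3",
    "preprocess_gait",
    "GAIT_LENGTH",
]

GAIT_LENGTH = 120


@dataclass(frozen=True)
class SampEnConfig:
    """SampEn parameters.

    delta_factor is the multiplier k in delta = k * sigma, where sigma is
    the sample standard deviation (n-1 denominator) of the series itself.
    Set ``normalize=True`` to z-score the series first (delta is then
    relative to unit variance; the value of SampEn is unchanged because
    Chebyshev distances and sigma rescale together).
    """

    m: int = 2
    tau: int = 1
    delta_factor: float = 0.3
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be >= 1")
        if self.delta_factor <= 0:
            raise ValueError("delta_factor must be > 0")


@dataclass(frozen=True)
class SampEnResult:
    """SampEn value plus the (A, B) template-match counts behind it."""

    value: float
    match_counts: tuple

    @property
    def is_infinite(self) -> bool:
        return np.isinf(self.value)


def _delayed_templates(t: np.ndarray, m: int, tau: int, count: int) -> np.ndarray:
    """First ``count`` delayed m-templates (t_j, t_{j+tau}, ..., t_{j+(m-1)tau})."""
    return np.column_stack([t[j * tau : j * tau + count] for j in range(m)])


def sample_entropy(series, cfg: SampEnConfig = SampEnConfig()) -> SampEnResult:
    """SampEn = -ln(A/B) with Chebyshev matching and self-matches excluded.

    Both the m- and (m+1)-template counts run over the same index range
    (templates that admit an (m+1)-point extension), so A <= B always and
    the value is nonnegative; A = 0 yields the infinity sentinel.
    """
    t = np.asarray(series, dtype=float)
    if t.ndim != 1:
        raise ValueError("series must be 1-D")
    n_templates = t.size - cfg.m * cfg.tau
    if n_templates < 2:
        raise ValueError(
            f"series of length {t.size} too short for SampEn with "
            f"m={cfg.m}, tau={cfg.tau}; need at least {cfg.m * cfg.tau + 2} samples"
        )
    if cfg.normalize:
        sd = t.std(ddof=1)
        if sd > 0:
            t = (t - t.mean()) / sd
    sigma = t.std(ddof=1)
    delta = cfg.delta_factor * sigma
    if delta <= 0:
        # constant series: every template matches at every length
        pairs = n_templates * (n_templates - 1) // 2
        return SampEnResult(0.0, (pairs, pairs))

    Xm = _delayed_templates(t, cfg.m, cfg.tau, n_templates)
    Xm1 = _delayed_templates(t, cfg.m + 1, cfg.tau, n_templates)
    B = int(np.count_nonzero(pdist(Xm, metric="chebyshev") <= delta))
    A = int(np.count_nonzero(pdist(Xm1, metric="chebyshev") <= delta))
    if A == 0:
        return SampEnResult(np.inf, (A, B))
    return SampEnResult(float(-np.log(A / B)), (A, B))


def median_filter3(series) -> np.ndarray:
    """Third-order (width-3) 1-D median filter, zero beyond the endpoints."""
    t = np.asarray(series, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("series must be a non-empty 1-D sequence")
    return median_filter(t, size=3, mode="constant", cval=0.0)


def preprocess_gait(raw, length: int = GAIT_LENGTH) -> np.ndarray:
    """Median-filter the full record, then keep the first ``length`` samples."""
    t = np.asarray(raw, dtype=float)
    if t.size < length:
        raise ValueError(
            f"gait record has {t.size} samples; need at least {length}"
        )
    return median_filter3(t)[:length]
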
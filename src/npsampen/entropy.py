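"""Sample entropy (SampEn) and nonparametric sample entropy (NPSampEn).

Both estimators quantify the regularity of a short time series by asking how
often template vectors of length ``m`` that are close (Chebyshev distance)
remain close when extended to length ``m + 1``.  Classical SampEn compares
every template distance against a single tolerance ``r`` (a multiple of the
segment standard deviation) and returns ``ln(phi_m / phi_m1)``.  NPSampEn
removes the tolerance parameter entirely: the sorted vector of *all unique*
template distances (the "scope") is used as a data-derived tolerance grid,
the two cumulative match-probability profiles are evaluated on that grid,
and the log-ratio is averaged over the grid.  This makes the estimator
defined for any series and insensitive to the choice of ``r`` that plagues
SampEn on 1-minute heart-rate segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistancePair",
    "ScopeVector",
    "CumulativeProfiles",
    "EntropyResult",
    "template_distances",
    "build_scope",
    "cumulative_profiles",
    "sampen",
    "npsampen",
]


class SeriesTooShortError(ValueError):
    """Raised when a series cannot support the requested embedding."""


def _as_series(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return x


@dataclass(frozen=True)
class DistancePair:
    """Aligned Chebyshev distance matrices at dimensions m and m+1.

    Both matrices are square of side ``N - m`` (template index i = 1..N-m at
    both dimensions); the diagonal (self-matches) is excluded from every
    downstream computation.  ``dm1 >= dm`` entrywise because the (m+1)-point
    distance adds one more coordinate under a max.
    """

    dm: np.ndarray
    dm1: np.ndarray
    m: int

    @property
    def n_templates(self) -> int:
        return self.dm.shape[0]

    def offdiag(self, which: str) -> np.ndarray:
        """Flattened off-diagonal entries of one matrix."""
        mat = self.dm if which == "m" else self.dm1
        mask = ~np.eye(mat.shape[0], dtype=bool)
        return mat[mask]


@dataclass(frozen=True)
class ScopeVector:
    """Sorted unique pooled template distances — the data-derived tolerances."""

    scope: np.ndarray

    @property
    def nbin(self) -> int:
        return self.scope.size


@dataclass(frozen=True)
class CumulativeProfiles:
    """Cumulative match-probability profiles Phi^m(q), Phi^{m+1}(q) on the scope grid."""

    phi_m: np.ndarray
    phi_m1: np.ndarray


@dataclass(frozen=True)
class EntropyResult:
    """An entropy value plus diagnostics.

    ``value`` is NaN when the estimator is undefined (SampEn with zero match
    counts); ``defined`` distinguishes that from a true zero.  ``diagnostics``
    carries method-specific counters: for NPSampEn the scope length ``nbin``
    and the number of scope bins skipped because ``Phi^{m+1}(q) = 0``; for
    SampEn the two mean match probabilities.
    """

    value: float
    method: str
    defined: bool = True
    reason: str | None = None
    diagnostics: dict = field(default_factory=dict)


def template_distances(x, m: int) -> DistancePair:
    """Chebyshev distance matrices between all template pairs at m and m+1.

    ``dm[i, j] = max_{0<=k<m} |x(i+k) - x(j+k)|`` for i, j in 1..N-m; the
    (m+1)-dimensional matrix shares the same index range and satisfies
    ``dm1[i, j] = max(dm[i, j], |x(i+m) - x(j+m)|)``.
    """
    x = _as_series(x)
    if m < 1:
        raise ValueError(f"embedding dimension must be >= 1, got {m}")
    n = x.size
    if n < m + 2:
        raise SeriesTooShortError(
            f"series of length {n} too short for m={m}; need N >= {m + 2}"
        )
    n_t = n - m
    base = np.abs(x[:, None] - x[None, :])
    dm = base[:n_t, :n_t].copy()
    for k in range(1, m):
        np.maximum(dm, base[k : k + n_t, k : k + n_t], out=dm)
    dm1 = np.maximum(dm, base[m : m + n_t, m : m + n_t])
    return DistancePair(dm=dm, dm1=dm1, m=m)


def build_scope(d: DistancePair) -> ScopeVector:
    """Sorted unique pooled off-diagonal distances from both matrices.

    Uniqueness is exact floating-point equality.
    """
    pooled = np.concatenate([d.offdiag("m"), d.offdiag("m1")])
    return ScopeVector(scope=np.unique(pooled))


def cumulative_profiles(d: DistancePair, scope: ScopeVector) -> CumulativeProfiles:
    """Phi profiles: mean over templates of the row-wise empirical CDF at scope(q).

    Every row contributes the same number of off-diagonal entries (N-m-1), so
    the mean of row CDFs equals the pooled ECDF of all off-diagonal entries;
    that pooled form is computed here.
    """
    def pooled_ecdf(flat: np.ndarray) -> np.ndarray:
        s = np.sort(flat)
        return np.searchsorted(s, scope.scope, side="right") / s.size

    return CumulativeProfiles(
        phi_m=pooled_ecdf(d.offdiag("m")),
        phi_m1=pooled_ecdf(d.offdiag("m1")),
    )


def sampen(x, m: int = 2, r: float = 0.2) -> EntropyResult:
    """Classical sample entropy with tolerance ``r`` times the segment SD.

    Self-matches are excluded; the SD is the population SD (divisor N).
    Returns an undefined marker (NaN value, ``defined=False``) when either
    match probability is zero instead of raising, so batch sweeps can record
    NaN for undefined points.
    """
    x = _as_series(x)
    if r <= 0:
        raise ValueError(f"tolerance r must be > 0, got {r}")
    d = template_distances(x, m)
    r_abs = r * x.std()
    mask = ~np.eye(d.n_templates, dtype=bool)
    denom = mask.sum()
    phi_m = np.count_nonzero(d.dm[mask] <= r_abs) / denom
    phi_m1 = np.count_nonzero(d.dm1[mask] <= r_abs) / denom
    diag = {"phi_m": phi_m, "phi_m1": phi_m1, "r_abs": float(r_abs)}
    if phi_m1 == 0.0 or phi_m == 0.0:
        return EntropyResult(
            value=float("nan"),
            method="sampen",
            defined=False,
            reason="zero match count at m+1" if phi_m1 == 0 else "zero match count at m",
            diagnostics=diag,
        )
    return EntropyResult(value=float(np.log(phi_m / phi_m1)), method="sampen", diagnostics=diag)


def npsampen(x, m: int = 2) -> EntropyResult:
    """Nonparametric sample entropy: tolerance-free regularity estimate.

    The scope grid is the sorted unique pooled distance set; the value is the
    mean over scope bins of ``ln(Phi^m(q) / Phi^{m+1}(q))``.  Bins where
    ``Phi^{m+1}(q) = 0`` (always possible at the smallest distances, which
    live in the m-matrix) are excluded from both the sum and the divisor and
    counted in ``diagnostics['skipped_bins']``.
    """
    x = _as_series(x)
    d = template_distances(x, m)
    scope = build_scope(d)
    prof = cumulative_profiles(d, scope)
    ok = prof.phi_m1 > 0.0
    n_used = int(np.count_nonzero(ok))
    skipped = scope.nbin - n_used
    value = float(np.mean(np.log(prof.phi_m[ok] / prof.phi_m1[ok])))
    # clip the tiny negative zero that floating-point log of ratio 1 can give
    if value < 0 and value > -1e-15:
        value = 0.0
    return EntropyResult(
        value=value,
        method="npsampen",
        diagnostics={"nbin": scope.nbin, "skipped_bins": skipped},
    )
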
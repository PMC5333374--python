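"""Validation statistics for electrode localization.

Implements the quantities used to validate semi-automatic localization
against expert raters: the per-contact gold standard (mean of manual
localizations), Euclidean localization errors, Krippendorff's alpha for
interval data as the chance-corrected inter-rater reliability, and a
paired permutation t-test whose null distribution is built from random
sign flips of the paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RaterLocalizations", "gold_standard", "localization_errors",
           "summarize_errors", "krippendorff_alpha_interval",
           "paired_permutation_test"]


@dataclass
class RaterLocalizations:
    """K x R x 3 coordinates: K contacts localized by R raters."""

    coords: np.ndarray
    method_tag: str = "manual"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (K, R, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("missing or non-finite entries are not supported")

    @property
    def K(self) -> int:
        return self.coords.shape[0]

    @property
    def R(self) -> int:
        return self.coords.shape[1]


def gold_standard(rl: RaterLocalizations) -> np.ndarray:
    """Per-contact mean coordinate across raters, G_k = (1/R) sum_r L_kr."""
    if rl.R < 2:
        raise ValueError("gold standard requires at least 2 raters")
    return rl.coords.mean(axis=1)


def localization_errors(est: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-contact Euclidean distances e_k = ||est_k - ref_k|| in mm."""
    est = np.asarray(est, dtype=float).reshape(-1, 3)
    ref = np.asarray(ref, dtype=float).reshape(-1, 3)
    if est.shape != ref.shape:
        raise ValueError(f"shape mismatch: {est.shape} vs {ref.shape}")
    return np.linalg.norm(est - ref, axis=1)


def summarize_errors(errors: np.ndarray) -> dict:
    errors = np.asarray(errors, dtype=float)
    return {"mean": float(errors.mean()), "sd": float(errors.std(ddof=1)) if len(errors) > 1 else 0.0,
            "median": float(np.median(errors)), "max": float(errors.max())}


def krippendorff_alpha_interval(ratings: np.ndarray) -> float:
    """Krippendorff's alpha for interval data, alpha = 1 - D_o/D_e.

    ``ratings`` is a units x raters matrix with no missing entries;
    disagreement is squared difference.  Observed disagreement averages
    over rater pairs within units; expected disagreement over all pairs
    of pooled values.  3D coordinates enter by treating each contact's
    x, y and z component as a separate unit.  If every value is
    identical, expected disagreement is zero and alpha is defined as 1.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2:
        raise ValueError("ratings must be a units x raters matrix")
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 units and 2 raters")
    if not np.isfinite(X).all():
        raise ValueError("missing entries are not supported")
    N = n * m
    # within-unit squared differences over ordered rater pairs
    row_ss = (X ** 2).sum(axis=1)
    row_sum = X.sum(axis=1)
    within = (2 * m * row_ss - 2 * row_sum ** 2)
    D_o = within.sum() / (N * (m - 1))
    # pooled squared differences over ordered value pairs
    total_ss = float((X ** 2).sum())
    total = float(X.sum())
    D_e = (2 * N * total_ss - 2 * total ** 2) / (N * (N - 1))
    if D_e <= 0:
        return 1.0
    return float(1.0 - D_o / D_e)


def paired_permutation_test(a: np.ndarray, b: np.ndarray,
                            n_perm: int = 100_000, seed: int = 0):
    """Paired t-test with a sign-flip permutation null distribution.

    The paired differences d = a - b yield the observed t statistic;
    the null distribution is built from ``n_perm`` random sign flips of
    d.  The two-sided p-value is the proportion of permuted |t| at or
    above the observed |t|, counting the observed permutation itself, so
    p >= 1/(n_perm + 1).
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("a and b must have equal length >= 2")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    d = a - b
    if np.allclose(d, 0.0):
        return 0.0, 1.0   # all permutations tie with the observed statistic
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise ValueError("zero-variance differences: t statistic undefined")
    n = len(d)
    t_obs = d.mean() / (sd / np.sqrt(n))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    D = signs * d
    means = D.mean(axis=1)
    sds = D.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(sds > 0, means / (sds / np.sqrt(n)),
                          np.sign(means) * np.inf)
    n_ge = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    p = (1 + n_ge) / (n_perm + 1)
    return float(t_obs), float(p)
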
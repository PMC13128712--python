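"""Ω SSCP cohort summaries and closed-form Bures–Wasserstein geometry.

A cohort's digit profiles are summarised by the average non-scaled,
non-centred sums-of-squares-and-cross-products matrix

    Ω = (1/n) Y Yᵀ

where column j of the p x n matrix Y holds specimen j's profile heights at
stations k_range (the tip station is omitted since it is zero height by
definition; k = 2..18 gives the 17 x 17 form, k = 2..11 the mastication-
surface-only form).  No mean correction or variance scaling is applied, so
Ω retains mean profile size and lets larger variance weigh more in
comparisons.  Ω is positive semi-definite by construction and is compared
with the Bures–Wasserstein metric

    δ(A, B) = [tr A + tr B - 2 tr((A^{1/2} B A^{1/2})^{1/2})]^{1/2}

(the 2-Wasserstein distance between centred Gaussians with these
covariance-like matrices), together with its geodesic
γ(t) = (1-t)²A + t²B + t(1-t)[(AB)^{1/2} + (BA)^{1/2}], whose midpoint is
the Wasserstein mean (1/4)[A + B + (AB)^{1/2} + (BA)^{1/2}] and which is
bounded above (in the Loewner order) by the linear interpolation
(1-t)A + tB.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigh

from .profile_model import Cohort, Digit, NumericalError, ValidationError, _as_digit

__all__ = [
    "OmegaMatrix",
    "assemble_profile_matrix",
    "omega",
    "psd_sqrt",
    "bures_wasserstein",
    "bw_geodesic",
    "geodesic_bound_check",
]

#: eigenvalues above -CLAMP_TOL * trace are clamped to zero in psd routines
CLAMP_TOL = 1e-9


@dataclass(frozen=True)
class OmegaMatrix:
    """p x p average non-centred SSCP summary of a cohort's profile heights (μm²)."""

    values: np.ndarray
    k_range: tuple[int, int]
    n: int
    label: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("omega matrix must be square")
        scale = max(np.abs(v).max(), 1.0)
        if np.abs(v - v.T).max() > 1e-12 * scale:
            raise ValidationError("omega matrix must be symmetric to 1e-12 relative")
        tr = float(np.trace(v))
        if eigh(v, eigvals_only=True, subset_by_index=[0, 0])[0] < -CLAMP_TOL * max(tr, 1e-300):
            raise ValidationError("omega matrix must be psd within the clamping tolerance")

    @property
    def p(self) -> int:
        return int(self.values.shape[0])

    @property
    def trace(self) -> float:
        return float(np.trace(self.values))


def assemble_profile_matrix(
    cohort: Cohort, digit_kind: Digit | str, k_range: tuple[int, int] = (2, 18)
) -> np.ndarray:
    """Stack per-specimen heights at stations k_range into a p x n matrix.

    Column j holds specimen j's heights (μm) at the 1-based station indices
    k_range[0]..k_range[1] inclusive, specimen order preserved.
    """
    digit = _as_digit(digit_kind)
    k0, k1 = k_range
    if not (1 <= k0 <= k1):
        raise ValidationError(f"invalid k_range {k_range}")
    cols = []
    for s in cohort.specimens:
        prof = s.profile(digit)
        if k1 > prof.n_stations:
            raise ValidationError(
                f"specimen {s.specimen_id}: profile has {prof.n_stations} stations, "
                f"missing station k={k1}"
            )
        cols.append(prof.y[k0 - 1 : k1])
    return np.column_stack(cols)


def omega(
    Y: np.ndarray,
    k_range: tuple[int, int] = (2, 18),
    label: tuple[str, str] | None = None,
) -> OmegaMatrix:
    """Average non-centred SSCP (1/n) Y Yᵀ — no centering, no scaling."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.size == 0:
        raise ValidationError("Y must be a non-empty p x n matrix")
    n = Y.shape[1]
    values = (Y @ Y.T) / n
    values = 0.5 * (values + values.T)
    return OmegaMatrix(values=values, k_range=tuple(k_range), n=n, label=label)


def _as_matrix(M) -> np.ndarray:
    if isinstance(M, OmegaMatrix):
        return M.values
    return np.asarray(M, dtype=float)


def psd_sqrt(M) -> np.ndarray:
    """Symmetric psd square root via spectral decomposition.

    Eigenvalues in the band [-CLAMP_TOL * tr, 0) are clamped to zero;
    anything below the band raises a not-psd error.
    """
    A = _as_matrix(M)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("matrix must be square")
    A = 0.5 * (A + A.T)
    vals, vecs = eigh(A)
    tr = max(float(np.trace(A)), 0.0)
    floor = -CLAMP_TOL * max(tr, 1e-300)
    if vals.min() < floor:
        raise NumericalError(
            f"matrix is not psd: min eigenvalue {vals.min():.3e} below tolerance {floor:.3e}"
        )
    vals = np.clip(vals, 0.0, None)
    root = (vecs * np.sqrt(vals)) @ vecs.T
    return 0.5 * (root + root.T)


def _psd_pinv_sqrt_pair(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(A^{1/2}, pseudo-inverse of A^{1/2}) on the clamped spectrum."""
    A = 0.5 * (A + A.T)
    vals, vecs = eigh(A)
    tr = max(float(np.trace(A)), 0.0)
    floor = -CLAMP_TOL * max(tr, 1e-300)
    if vals.min() < floor:
        raise NumericalError("matrix is not psd within the clamping tolerance")
    vals = np.clip(vals, 0.0, None)
    sq = np.sqrt(vals)
    cutoff = CLAMP_TOL * max(sq.max(), 1e-300)
    inv = np.where(sq > cutoff, 1.0 / np.where(sq > 0, sq, 1.0), 0.0)
    return (vecs * sq) @ vecs.T, (vecs * inv) @ vecs.T


def bures_wasserstein(A, B) -> float:
    """Closed-form Bures–Wasserstein distance between psd matrices.

    δ(A,B) = sqrt(tr A + tr B - 2 tr((A^{1/2} B A^{1/2})^{1/2})); symmetric,
    zero at A = B, a Riemannian metric on the psd cone.
    """
    a, b = _as_matrix(A), _as_matrix(B)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    ra = psd_sqrt(a)
    inner = ra @ b @ ra
    try:
        cross = psd_sqrt(inner)
    except NumericalError as exc:
        raise NumericalError(
            f"inner matrix A^(1/2) B A^(1/2) failed psd tolerance: {exc}"
        ) from exc
    d2 = float(np.trace(a) + np.trace(b) - 2.0 * np.trace(cross))
    scale = max(float(np.trace(a) + np.trace(b)), 1e-300)
    if d2 < -1e-8 * scale:
        raise NumericalError(f"negative squared distance {d2:.3e} beyond tolerance")
    return float(np.sqrt(max(d2, 0.0)))


def _cross_sqrt(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(AB)^{1/2} via the similarity A^{1/2}(A^{1/2} B A^{1/2})^{1/2} A^{-1/2}.

    The pseudo-inverse on the clamped spectrum gives the continuous
    extension when A is singular.
    """
    ra, ra_pinv = _psd_pinv_sqrt_pair(a)
    inner = psd_sqrt(ra @ b @ ra)
    return ra @ inner @ ra_pinv


def bw_geodesic(A, B, t: float) -> np.ndarray:
    """Point γ(t) on the Bures–Wasserstein geodesic from A (t=0) to B (t=1).

    γ(t) = (1-t)²A + t²B + t(1-t)[(AB)^{1/2} + (BA)^{1/2}]; the midpoint is
    the Wasserstein mean of A and B.
    """
    if not (0.0 <= t <= 1.0):
        raise ValidationError(f"geodesic parameter t must lie in [0, 1], got {t}")
    a, b = _as_matrix(A), _as_matrix(B)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    if t == 0.0:
        return a.copy()
    if t == 1.0:
        return b.copy()
    X = _cross_sqrt(a, b)
    g = (1 - t) ** 2 * a + t ** 2 * b + t * (1 - t) * (X + X.T)
    return 0.5 * (g + g.T)


def geodesic_bound_check(A, B, t: float) -> tuple[bool, float]:
    """Check the linear-interpolation bound γ(t) <= (1-t)A + tB spectrally.

    Returns (pass, worst eigenvalue of (1-t)A + tB - γ(t)); the bound holds
    when the worst eigenvalue is >= -1e-8 of the interpolant's trace.
    """
    a, b = _as_matrix(A), _as_matrix(B)
    gap = (1 - t) * a + t * b - bw_geodesic(a, b, t)
    worst = float(eigh(0.5 * (gap + gap.T), eigvals_only=True, subset_by_index=[0, 0])[0])
    scale = max(float(np.trace((1 - t) * a + t * b)), 1e-300)
    return worst >= -1e-8 * scale, worst
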
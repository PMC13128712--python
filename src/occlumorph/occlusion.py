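"""Weighted 1-D 2-Wasserstein occlusion distances between digit asperity sets.

The analytical occlusive method encodes each digit's pooled peak and gullet
asperities as a weighted point distribution on the tip→condyle reference
axis and measures the minimal quadratic transport ("earth-mover") work to
carry one digit's distribution onto the other's.  Low distance means a good
reciprocal fit of asperities (peaks meeting opposing gullets); high distance
means the two digits are functionally differentiated.

Encoding ("peak run"): asperity heights act as weights within each
individual — the moveable digit uses y directly, the fixed digit (stored
post-flip in the occlusal frame) uses -y adjusted by subtracting its
minimum, i.e. max(y) - y, the only reading that guarantees non-negative
weights.  A second "gullet run" first reflects the heights vertically
(y -> max(y) - y) and repeats the digit-specific weighting, emphasising
gullet structure instead of peaks.  The two runs are averaged into one
summary distance per individual.

The distance itself is the exact closed form for distributions on a line:

    W2(a, b) = ( integral_0^1 |F_a^{-1}(q) - F_b^{-1}(q)|^2 dq )^{1/2}

computed by merging the two cumulative-weight breakpoint sequences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .ordination import DistanceMatrix
from .profile_model import (
    Asperity,
    AsperityKind,
    ChelaSpecimen,
    Cohort,
    DegenerateMassError,
    Digit,
    ValidationError,
    _as_digit,
)

__all__ = [
    "WeightedPointSet",
    "OcclusiveDistance",
    "build_weighted_pointset",
    "wasserstein1d_p2",
    "occlusive_distance",
    "cross_digit_distance_matrix",
]


@dataclass(frozen=True)
class WeightedPointSet:
    """Sorted support locations with non-negative weights summing to one."""

    locations: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        loc = np.asarray(self.locations, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "locations", loc)
        object.__setattr__(self, "weights", w)
        if loc.ndim != 1 or loc.shape != w.shape or loc.size < 1:
            raise ValidationError("point set needs matching 1-D locations and weights, length >= 1")
        if not (np.isfinite(loc).all() and np.isfinite(w).all()):
            raise ValidationError("point set entries must be finite")
        if np.any(np.diff(loc) < 0):
            raise ValidationError("locations must be non-decreasing")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        total = w.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1 after normalization, got {total}")

    @classmethod
    def from_raw(cls, locations, weights) -> "WeightedPointSet":
        """Sort by location and normalize raw non-negative weights to unit mass."""
        loc = np.asarray(locations, dtype=float)
        w = np.asarray(weights, dtype=float)
        order = np.argsort(loc, kind="stable")
        loc, w = loc[order], w[order]
        total = w.sum()
        if total <= 0:
            raise DegenerateMassError("all weights are zero; no mass to transport")
        return cls(locations=loc, weights=w / total)


@dataclass(frozen=True)
class OcclusiveDistance:
    """Peak-run and gullet-run transport distances with their mean."""

    d_peak: float
    d_gullet: float

    @property
    def d_mean(self) -> float:
        return 0.5 * (self.d_peak + self.d_gullet)


def build_weighted_pointset(
    asperities: Sequence[Asperity],
    digit_kind: Digit | str,
    run: str = "peak",
    *,
    uniform_fallback: bool = False,
    x_scale: float | None = None,
    subset: str = "all",
) -> WeightedPointSet:
    """Encode a digit's asperities as the transport operand.

    ``run`` is ``"peak"`` or ``"gullet_reflected"``; the gullet run reflects
    the heights (y -> max(y) - y) before the digit-specific weighting
    (moveable: w = y; fixed: w = max(y) - y).  ``x_scale`` divides locations
    (pass x_ie to normalize to [0, 1]).  ``subset`` restricts the pooled
    asperity list to peaks or gullets for sensitivity analysis.

    If every weight vanishes after the adjustment (constant heights on a
    fixed digit, say), a :class:`DegenerateMassError` is raised unless
    ``uniform_fallback`` explicitly requests equal weights.
    """
    digit = _as_digit(digit_kind)
    if run not in ("peak", "gullet_reflected"):
        raise ValidationError(f"unknown run {run!r}")
    if subset not in ("all", "peaks", "gullets"):
        raise ValidationError(f"unknown subset {subset!r}")
    pool = list(asperities)
    if subset == "peaks":
        pool = [a for a in pool if a.kind is AsperityKind.PEAK]
    elif subset == "gullets":
        pool = [a for a in pool if a.kind is AsperityKind.GULLET]
    if not pool:
        raise ValidationError("need at least one asperity to build a point set")
    x = np.array([a.x for a in pool], dtype=float)
    y = np.array([a.y for a in pool], dtype=float)
    if run == "gullet_reflected":
        y = y.max() - y
    if digit is Digit.MOVEABLE:
        w = y.copy()
    else:
        w = y.max() - y
    if w.sum() <= 0:
        if not uniform_fallback:
            raise DegenerateMassError(
                "all weights zero after digit-specific adjustment "
                "(enable uniform_fallback to use equal weights)"
            )
        w = np.ones_like(w)
    if x_scale is not None:
        if x_scale <= 0:
            raise ValidationError("x_scale must be positive")
        x = x / x_scale
    return WeightedPointSet.from_raw(x, w)


def wasserstein1d_p2(a: WeightedPointSet, b: WeightedPointSet) -> float:
    """Exact 2-Wasserstein distance between two weighted distributions on a line.

    Merges the cumulative-weight breakpoints of both quantile functions and
    integrates the squared quantile difference piecewise; symmetric and zero
    iff the distributions coincide.
    """
    qa = np.cumsum(a.weights)
    qb = np.cumsum(b.weights)
    # interior breakpoints of both quantile functions, as interval edges in [0, 1]
    edges = np.concatenate(([0.0], np.union1d(qa[:-1], qb[:-1]), [1.0]))
    edges = edges[(edges >= 0.0) & (edges <= 1.0)]
    lo = edges[:-1]
    dq = np.diff(edges)
    ia = np.minimum(np.searchsorted(qa, lo, side="right"), qa.size - 1)
    ib = np.minimum(np.searchsorted(qb, lo, side="right"), qb.size - 1)
    diff = a.locations[ia] - b.locations[ib]
    return float(np.sqrt(np.sum(dq * diff * diff)))


def occlusive_distance(
    specimen: ChelaSpecimen,
    *,
    uniform_fallback: bool = False,
    normalize_locations: bool = False,
    subset: str = "all",
) -> OcclusiveDistance:
    """Within-individual transport distance between the two digits' asperities.

    ``d_peak`` compares the peak-run encodings of the moveable and fixed
    digit, ``d_gullet`` the reflected (gullet) run, ``d_mean`` their
    unweighted average.  Locations stay in raw μm by default because the two
    digits of one animal share a physical scale; ``normalize_locations``
    divides each digit's x by its own x_ie.
    """
    dists = {}
    for run in ("peak", "gullet_reflected"):
        sets = {}
        for digit in (Digit.MOVEABLE, Digit.FIXED):
            try:
                sets[digit] = build_weighted_pointset(
                    specimen.asperities(digit),
                    digit,
                    run,
                    uniform_fallback=uniform_fallback,
                    x_scale=specimen.x_ie(digit) if normalize_locations else None,
                    subset=subset,
                )
            except (DegenerateMassError, ValidationError) as exc:
                raise type(exc)(f"specimen {specimen.specimen_id} ({digit.value}): {exc}") from exc
        dists[run] = wasserstein1d_p2(sets[Digit.MOVEABLE], sets[Digit.FIXED])
    return OcclusiveDistance(d_peak=dists["peak"], d_gullet=dists["gullet_reflected"])


def cross_digit_distance_matrix(
    cohorts: Sequence[Cohort],
    digit_selector: str = "both",
    run: str = "peak",
    *,
    normalize_locations: bool = True,
    uniform_fallback: bool = False,
    subset: str = "all",
) -> tuple[DistanceMatrix, list[dict]]:
    """Pairwise transport distances between every selected digit of every specimen.

    Labels are ``"<specimen_id>:<digit>"``.  ``run`` may be ``"peak"``,
    ``"gullet_reflected"`` or ``"mean"`` (average of both runs per pair).
    Location normalization by x_ie defaults ON here because digits of
    unequal axis length are compared across species.  Degenerate digits are
    excluded and itemized in the returned skip report, never silently.
    """
    if digit_selector not in ("fixed", "moveable", "both"):
        raise ValidationError(f"unknown digit_selector {digit_selector!r}")
    if run not in ("peak", "gullet_reflected", "mean"):
        raise ValidationError(f"unknown run {run!r}")
    digits = {
        "fixed": (Digit.FIXED,),
        "moveable": (Digit.MOVEABLE,),
        "both": (Digit.MOVEABLE, Digit.FIXED),
    }[digit_selector]
    runs = ("peak", "gullet_reflected") if run == "mean" else (run,)

    labels: list[str] = []
    species: list[str] = []
    encoded: list[dict] = []
    skip_report: list[dict] = []
    for cohort in cohorts:
        for s in cohort.specimens:
            for digit in digits:
                try:
                    sets = {
                        r: build_weighted_pointset(
                            s.asperities(digit), digit, r,
                            uniform_fallback=uniform_fallback,
                            x_scale=s.x_ie(digit) if normalize_locations else None,
                            subset=subset,
                        )
                        for r in runs
                    }
                except (DegenerateMassError, ValidationError) as exc:
                    skip_report.append({
                        "specimen_id": s.specimen_id,
                        "species_code": s.species_code,
                        "digit": digit.value,
                        "reason": str(exc),
                    })
                    continue
                labels.append(f"{s.specimen_id}:{digit.value}")
                species.append(s.species_code)
                encoded.append(sets)
    n = len(labels)
    if n == 0:
        raise ValidationError("no valid digits to compare (see skip report)")
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.mean([
                wasserstein1d_p2(encoded[i][r], encoded[j][r]) for r in runs
            ]))
            values[i, j] = values[j, i] = d
    dm = DistanceMatrix(labels=labels, values=values, groups=species)
    return dm, skip_report
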
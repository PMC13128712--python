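"""Per-digit and per-cohort biomechanical and surface statistics.

Tribological summaries of a digit's mastication surface (the tooth-bearing
span x <= x_ie, indexed i = 1..i_e):

* ``Rq``     root-mean-square height, sqrt((1/i_e) * sum y_i^2)
* ``avg_y``  mean height
* ``sigma2`` height variance, the algebraic identity Rq^2 - avg_y^2
* ``tel``    stretch of the profile point process, sum |y_i|
* ``xRp``    location of the tallest peak asperity; ``xRv`` of the deepest
  gullet (occlusal frame: the gullet asperity of maximum relief)
* ``W``      digit depth at the posterior end of the tooth row (station
  nearest x_ie)

Lever mechanics: velocity ratio VR = L1U/L2M (mechanical advantage),
occluding crunch force F2AV = VR * F1AV, mastication-surface length
L2M - L1U, and the corrected maximum effective gape angle
delta = arccos((L2M - x_ie)/L2M).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .profile_model import (
    Asperity,
    AsperityKind,
    ChelaSpecimen,
    Cohort,
    Digit,
    GridProfile,
    LeverGeometry,
    ToothClass,
    ValidationError,
)

__all__ = [
    "SurfaceStats",
    "OverbiteSummary",
    "ToothSummary",
    "surface_stats",
    "velocity_ratio",
    "crunch_force",
    "mastication_length",
    "gape_angle",
    "overbite_summary",
    "tooth_summary",
    "cohort_surface_stats",
]


@dataclass(frozen=True)
class SurfaceStats:
    """Tribological statistics of one digit's mastication surface (μm)."""

    Rq: float
    avg_y: float
    sigma2: float
    tel: float
    xRp: Optional[float]
    xRv: Optional[float]
    W: float
    n_peaks: int
    n_gullets: int


@dataclass(frozen=True)
class OverbiteSummary:
    """Cohort tip-offset summary.

    ``p_overbite`` near 0.5 indicates random chance over measurement error;
    ``overbite_pct_of_xie`` expresses the mean overbite relative to the
    cohort's mean moveable-digit mastication surface length.
    """

    p_overbite: float
    p_underbite: float
    p_tie: float
    n_ties: int
    mean_overbite_um: Optional[float]
    overbite_pct_of_xie: Optional[float]


@dataclass(frozen=True)
class ToothSummary:
    """Mean tooth-type counts and first-order tooth-type transitions.

    ``transition[digit]`` is a 2x2 row-stochastic matrix over (ATB, FT) in
    the distal→proximal reading direction; ``row_support[digit]`` flags rows
    with at least one observed transition (unsupported rows are all zero,
    never fabricated).
    """

    mean_count: dict
    transition: dict
    row_support: dict


# ---------------------------------------------------------------------------
# Surface statistics
# ---------------------------------------------------------------------------

def surface_stats(profile, asperities: Sequence[Asperity] = (), x_ie: float | None = None) -> SurfaceStats:
    """Compute tribological statistics over the mastication surface.

    ``profile`` may be a :class:`GridProfile` or a plain ``(x, y)`` pair of
    sequences.  Stations with x <= x_ie define the surface; ``x_ie`` defaults
    to the last station.  ``W`` is read at the station nearest x_ie
    (nearest-station convention, no interpolation).
    """
    if isinstance(profile, GridProfile):
        x, y = profile.x, profile.y
    else:
        x = np.asarray(profile[0], dtype=float)
        y = np.asarray(profile[1], dtype=float)
    if x_ie is None:
        x_ie = float(x[-1])
    mask = x <= x_ie * (1 + 1e-12)
    if not mask.any():
        raise ValidationError(f"no profile stations within x_ie = {x_ie}")
    ys = y[mask]
    i_e = ys.size
    rq = float(np.sqrt(np.sum(ys ** 2) / i_e))
    avg = float(np.mean(ys))
    sigma2 = rq ** 2 - avg ** 2
    tel = float(np.sum(np.abs(ys)))
    w = float(y[np.argmin(np.abs(x - x_ie))])

    peaks = [a for a in asperities if a.kind is AsperityKind.PEAK and a.x <= x_ie * (1 + 1e-12)]
    gullets = [a for a in asperities if a.kind is AsperityKind.GULLET and a.x <= x_ie * (1 + 1e-12)]
    # tie-break for equal maxima: the most distal (smallest x) asperity wins
    xrp = min((a for a in peaks if a.y == max(p.y for p in peaks)), key=lambda a: a.x).x if peaks else None
    xrv = min((a for a in gullets if a.y == max(g.y for g in gullets)), key=lambda a: a.x).x if gullets else None
    return SurfaceStats(
        Rq=rq, avg_y=avg, sigma2=sigma2, tel=tel,
        xRp=xrp, xRv=xrv, W=w, n_peaks=len(peaks), n_gullets=len(gullets),
    )


def velocity_ratio(g: LeverGeometry) -> float:
    """Chelal mechanical advantage VR = L1U / L2M, in (0, 1)."""
    if g.L1U >= g.L2M:
        raise ValidationError("velocity ratio requires L1U < L2M")
    return g.L1U / g.L2M


def crunch_force(F1AV: float, VR: float) -> float:
    """Occluding chelal crunch force F2AV = VR * F1AV."""
    if F1AV < 0 or VR < 0:
        raise ValidationError("crunch force inputs must be non-negative")
    return VR * F1AV


def mastication_length(g: LeverGeometry) -> float:
    """Mastication-surface estimate: output arm minus input arm, L2M - L1U."""
    if g.L1U >= g.L2M:
        raise ValidationError("mastication length requires L1U < L2M")
    return g.L2M - g.L1U


def gape_angle(L2M: float, x_ie: float) -> float:
    """Maximum effective gape angle, degrees: arccos((L2M - x_ie)/L2M).

    Monotone increasing in x_ie, 0° at x_ie = 0 and 90° at x_ie = L2M.
    """
    if L2M <= 0:
        raise ValidationError("L2M must be positive")
    if not (0.0 <= x_ie <= L2M):
        raise ValidationError(f"require 0 <= x_ie <= L2M, got x_ie={x_ie}, L2M={L2M}")
    return math.degrees(math.acos((L2M - x_ie) / L2M))


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def overbite_summary(cohort: Cohort) -> OverbiteSummary:
    """Overbite/underbite proportions and mean overbite scale for a cohort.

    Exact tip matches (tip_offset == 0) are counted as neither over- nor
    underbite and reported separately, so p_overbite + p_underbite + p_tie
    sums to 1 exactly.
    """
    offsets = np.array([s.tip_offset_um for s in cohort.specimens], dtype=float)
    n = offsets.size
    over = offsets > 0
    under = offsets < 0
    ties = offsets == 0
    p_over = float(over.sum()) / n
    p_under = float(under.sum()) / n
    p_tie = float(ties.sum()) / n
    if over.any():
        mean_over = float(offsets[over].mean())
        mean_xie = float(np.mean([s.geometry.x_ie_md for s in cohort.specimens]))
        pct = 100.0 * mean_over / mean_xie
    else:
        mean_over = None
        pct = None
    return OverbiteSummary(
        p_overbite=p_over, p_underbite=p_under, p_tie=p_tie,
        n_ties=int(ties.sum()), mean_overbite_um=mean_over, overbite_pct_of_xie=pct,
    )


_CLASSES = (ToothClass.ATB, ToothClass.FT)


def tooth_summary(cohort: Cohort) -> ToothSummary:
    """Mean tooth-type counts and distal→proximal transition probabilities.

    Counts cover classified peak asperities (ATB vs FT) per digit.  First-
    order transitions are pooled over specimens from consecutive classified
    teeth read anterior-distal → posterior-proximal; rows are normalized
    over observed transitions only, and digits contributing fewer than two
    classified teeth add no transitions.
    """
    mean_count: dict = {}
    transition: dict = {}
    row_support: dict = {}
    n = len(cohort.specimens)
    for digit in (Digit.MOVEABLE, Digit.FIXED):
        counts = {c: 0 for c in _CLASSES}
        trans = np.zeros((2, 2), dtype=float)
        for s in cohort.specimens:
            seq = [
                a.tooth_class
                for a in sorted(s.asperities(digit), key=lambda a: a.x)
                if a.tooth_class is not None
            ]
            for c in seq:
                counts[c] += 1
            for first, second in zip(seq, seq[1:]):
                trans[_CLASSES.index(first), _CLASSES.index(second)] += 1
        for c in _CLASSES:
            mean_count[(digit.value, c.value)] = counts[c] / n
        sums = trans.sum(axis=1)
        support = sums > 0
        probs = np.zeros_like(trans)
        for r in range(2):
            if support[r]:
                probs[r] = trans[r] / sums[r]
        transition[digit.value] = probs
        row_support[digit.value] = tuple(bool(b) for b in support)
    return ToothSummary(mean_count=mean_count, transition=transition, row_support=row_support)


def cohort_surface_stats(cohorts: Sequence[Cohort]):
    """One SurfaceStats row per specimen x digit, as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for cohort in cohorts:
        for s in cohort.specimens:
            for digit in (Digit.MOVEABLE, Digit.FIXED):
                st = surface_stats(s.profile(digit), s.asperities(digit), s.x_ie(digit))
                rows.append({
                    "specimen_id": s.specimen_id,
                    "species_code": s.species_code,
                    "digit": digit.value,
                    "Rq_um": st.Rq, "avg_y_um": st.avg_y, "sigma2_um2": st.sigma2,
                    "tel_um": st.tel, "xRp_um": st.xRp, "xRv_um": st.xRv,
                    "W_um": st.W, "n_peaks": st.n_peaks, "n_gullets": st.n_gullets,
                })
    return pd.DataFrame(rows)
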
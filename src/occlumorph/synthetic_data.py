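"""Seeded generator of synthetic digit-pair cohorts.

Raw per-specimen measurements for the four cadaver-inhabiting astigmatan
species are deposited externally, so every pipeline stage is exercised on
synthetic cohorts generated here.  The generator's contract is the set of
published cohort-level summary targets, not any particular microscopic
mechanism: per-digit tooth-type means, overbite probabilities and scales,
exact-tie rate, surface-roughness levels and their between-species
ordering, fixed-digit "toothiness", and the blade/pocket structure of the
lardoglyphid.

Generative model per specimen:

1. Lever geometry drawn around species means (mastication surface
   x_ie_md = L2M - L1U by construction).
2. The moveable digit gets k peak asperities (k from a zero-truncated
   Poisson whose mean equals the preset target exactly), interleaved with
   k + 1 gullets; the tip-adjacent gullet sits at height 0 (gullet floor on
   the reference axis).  Peak locations concentrate around a species mass
   centroid along the normalized axis — the dial that makes the transport
   ordination track the roughness cline.
3. The fixed digit is the occlusal complement of the moveable digit
   (fd peaks at md gullet locations, heights flipped as max(y) - y), then
   perturbed by (1 - complementarity)-scaled location and height noise.
   A k-peak moveable digit thus yields a (k+1)-peak fixed digit: fixed
   digits are toothier structurally.  At complementarity = 1 the exact
   complement is emitted and the within-individual occlusion distance is
   identically zero.  Lardoglyphid-style fixed digits additionally carry
   two zero-height "pockets" at fixed relative positions.
4. Grid profiles (18 equispaced stations over the full reference axis) are
   monotone-spline interpolants through the asperity points, and all
   heights are rescaled so the mastication-surface Rq hits the species
   roughness target up to lognormal specimen noise.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .profile_model import (
    Asperity,
    AsperityKind,
    ChelaSpecimen,
    Cohort,
    Digit,
    GridProfile,
    LeverGeometry,
    N_STATIONS,
    ToothClass,
    ValidationError,
    write_specimens,
)

__all__ = [
    "ArchetypeSpec",
    "archetype_presets",
    "generate_specimen",
    "generate_cohorts",
    "perfect_complement_pair",
]


@dataclass(frozen=True)
class ArchetypeSpec:
    """Generative parameters for one synthetic species cohort.

    Count, probability and roughness targets are cohort means the generator
    is calibrated to reproduce; ``tooth_mean_md``/``tooth_mean_fd`` carry
    the per-digit classified tooth-type count targets.
    """

    species_code: str
    n_peaks_md: float
    n_peaks_fd: float
    height_scale_um: float
    roughness_target_um: float
    complementarity: float
    overbite_prob: float
    overbite_scale_um: float
    tie_prob: float
    tooth_mean_md: dict
    tooth_mean_fd: dict
    pockets_fd: int
    mass_centroid: float
    L1U_mean_um: float
    L2M_mean_um: float
    L2F_mean_um: float
    geometry_cv: float
    socket_prob: Optional[float] = None
    snub_prob: float = 0.4
    MvG_mean_um3: Optional[float] = None
    TMvG_mean_um3: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_peaks_md < 0 or self.n_peaks_fd < self.n_peaks_md:
            raise ValidationError("require 0 <= n_peaks_md <= n_peaks_fd")
        for p in (self.complementarity, self.overbite_prob, self.tie_prob):
            if not (0.0 <= p <= 1.0):
                raise ValidationError("probabilities must lie in [0, 1]")
        if self.pockets_fd not in (0, 2):
            raise ValidationError("pockets_fd must be 0 or 2")

    @property
    def x_ie_md_mean_um(self) -> float:
        """Implied mastication-surface mean, L2M - L1U."""
        return self.L2M_mean_um - self.L1U_mean_um

    @property
    def blade_fraction_md(self) -> float:
        """Probability a classified moveable-digit tooth is flat-top (FT)."""
        s = self.tooth_mean_md["ATB"] + self.tooth_mean_md["FT"]
        return self.tooth_mean_md["FT"] / s if s > 0 else 0.0

    @property
    def blade_fraction_fd(self) -> float:
        s = self.tooth_mean_fd["ATB"] + self.tooth_mean_fd["FT"]
        return self.tooth_mean_fd["FT"] / s if s > 0 else 0.0


def archetype_presets() -> dict[str, ArchetypeSpec]:
    """Four species presets matching the published cohort summaries.

    A10B (*Acarus siro*): rough ATB-rich crusher with clear overbite
    (p = 0.75, mean scale 0.49 μm).  C3 (*Sancassania berlesei*):
    intermediate, high-variance occlusion, overbite p = 0.8, scale 0.44 μm.
    L3 (*Lardoglyphus zacheri*): blade-like FT-dominant moveable digit,
    two fixed-digit pockets, no clear overbite (p = 0.5), x_ie ≈ 13.5 μm.
    T13 (*Tyrophagus putrescentiae*): smooth generalist with an unusually
    toothy moveable digit, overbite p = 0.5.  Tooth-type count targets are
    the per-digit ATB/FT cohort means; the exact-tip-match rate 2/80 is
    shared across presets.
    """
    tie = 2.0 / 80.0
    common = dict(tie_prob=tie, geometry_cv=0.06)
    return {
        "A10B": ArchetypeSpec(
            species_code="A10B", n_peaks_md=3.5, n_peaks_fd=4.5,
            height_scale_um=2.6, roughness_target_um=2.3,
            complementarity=0.90, overbite_prob=0.75, overbite_scale_um=0.49,
            tooth_mean_md={"ATB": 1.45, "FT": 1.45},
            tooth_mean_fd={"ATB": 3.70, "FT": 0.65},
            pockets_fd=0, mass_centroid=0.20,
            L1U_mean_um=22.0, L2M_mean_um=40.0, L2F_mean_um=38.8,
            socket_prob=18 / 20, snub_prob=0.55,
            MvG_mean_um3=7180.0, TMvG_mean_um3=6349.0,
            **common,
        ),
        "C3": ArchetypeSpec(
            species_code="C3", n_peaks_md=3.0, n_peaks_fd=4.0,
            height_scale_um=2.0, roughness_target_um=1.7,
            complementarity=0.60, overbite_prob=0.80, overbite_scale_um=0.44,
            tooth_mean_md={"ATB": 1.40, "FT": 1.15},
            tooth_mean_fd={"ATB": 2.55, "FT": 0.90},
            pockets_fd=0, mass_centroid=0.44,
            L1U_mean_um=22.8, L2M_mean_um=38.0, L2F_mean_um=36.9,
            socket_prob=12 / 20, snub_prob=0.40,
            MvG_mean_um3=3022.0, TMvG_mean_um3=2670.0,
            **common,
        ),
        "L3": ArchetypeSpec(
            species_code="L3", n_peaks_md=2.0, n_peaks_fd=3.0,
            height_scale_um=1.5, roughness_target_um=1.2,
            complementarity=0.80, overbite_prob=0.50, overbite_scale_um=0.30,
            tooth_mean_md={"ATB": 0.05, "FT": 1.35},
            tooth_mean_fd={"ATB": 0.06, "FT": 1.05},
            pockets_fd=2, mass_centroid=0.60,
            L1U_mean_um=20.5, L2M_mean_um=34.0, L2F_mean_um=33.0,
            socket_prob=None, snub_prob=0.40,
            MvG_mean_um3=3646.0, TMvG_mean_um3=3211.0,
            **common,
        ),
        "T13": ArchetypeSpec(
            species_code="T13", n_peaks_md=3.5, n_peaks_fd=4.5,
            height_scale_um=1.3, roughness_target_um=1.1,
            complementarity=0.65, overbite_prob=0.50, overbite_scale_um=0.30,
            tooth_mean_md={"ATB": 1.35, "FT": 1.65},
            tooth_mean_fd={"ATB": 2.15, "FT": 2.05},
            pockets_fd=0, mass_centroid=0.63,
            L1U_mean_um=16.0, L2M_mean_um=30.0, L2F_mean_um=29.1,
            socket_prob=16 / 20, snub_prob=0.25,
            MvG_mean_um3=4773.0, TMvG_mean_um3=4435.0,
            **common,
        ),
    }


# ---------------------------------------------------------------------------
# Sampling helpers
# ---------------------------------------------------------------------------

def _ztp_lambda(mean: float) -> float:
    """Rate lambda such that the zero-truncated Poisson mean equals ``mean``."""
    if mean <= 1.0:
        raise ValidationError("zero-truncated Poisson mean must exceed 1")
    lam = mean
    for _ in range(60):
        e = np.exp(-lam)
        f = lam / (1.0 - e) - mean
        fprime = (1.0 - e - lam * e) / (1.0 - e) ** 2
        lam -= f / fprime
        lam = max(lam, 1e-9)
    return lam


def _draw_ztp(rng: np.random.Generator, mean: float) -> int:
    lam = _ztp_lambda(mean)
    for _ in range(1000):
        k = int(rng.poisson(lam))
        if k > 0:
            return k
    return 1


_BETA_CONCENTRATION = 70.0  # within-species spread of the asperity mass centroid


def _peak_locations(rng: np.random.Generator, k: int, centroid: float, span: float) -> np.ndarray:
    a = centroid * _BETA_CONCENTRATION
    b = (1.0 - centroid) * _BETA_CONCENTRATION
    lo, hi = 0.18 * span, 0.95 * span
    x = np.sort(lo + (hi - lo) * rng.beta(a, b, size=k))
    gap = 0.04 * span
    for i in range(1, k):  # keep asperities resolvable
        if x[i] - x[i - 1] < gap:
            x[i] = x[i - 1] + gap
    if x[-1] > hi:
        x = lo + (x - x[0]) * (hi - lo) / max(x[-1] - x[0], gap)
    return x


def _grid_profile(
    digit: Digit, axis_len: float, asperities: Sequence[Asperity], tail_height: float
) -> GridProfile:
    """Monotone spline through the asperity points, sampled at 18 stations."""
    xs = [0.0] + [a.x for a in asperities] + [axis_len]
    ys = [0.0] + [a.y for a in asperities] + [tail_height]
    xs = np.asarray(xs)
    ys = np.asarray(ys)
    keep = np.concatenate(([True], np.diff(xs) > 1e-9))
    interp = PchipInterpolator(xs[keep], ys[keep])
    gx = np.linspace(0.0, axis_len, N_STATIONS)
    gy = interp(gx)
    gy[0] = 0.0
    gy = np.clip(gy, 0.0, None)
    return GridProfile(digit_kind=digit, x=gx, y=gy)


def _assign_classes(
    rng: np.random.Generator, asperities: list[Asperity], spec: ArchetypeSpec, digit: Digit
) -> list[Asperity]:
    """Give peak asperities ATB/FT classes at the preset's target rates."""
    means = spec.tooth_mean_md if digit is Digit.MOVEABLE else spec.tooth_mean_fd
    n_target = spec.n_peaks_md if digit is Digit.MOVEABLE else spec.n_peaks_fd
    classified_mean = means["ATB"] + means["FT"]
    p_class = min(1.0, classified_mean / n_target) if n_target > 0 else 0.0
    bf = spec.blade_fraction_md if digit is Digit.MOVEABLE else spec.blade_fraction_fd
    out = []
    for a in asperities:
        tc = None
        if a.kind is AsperityKind.PEAK and rng.uniform() < p_class:
            tc = ToothClass.FT if rng.uniform() < bf else ToothClass.ATB
        out.append(dataclasses.replace(a, tooth_class=tc))
    return out


def _draw_geometry(rng: np.random.Generator, spec: ArchetypeSpec) -> LeverGeometry:
    cv = spec.geometry_cv
    for _ in range(100):
        L2M = rng.normal(spec.L2M_mean_um, cv * spec.L2M_mean_um)
        L1U = rng.normal(spec.L1U_mean_um, cv * spec.L1U_mean_um)
        L2F = rng.normal(spec.L2F_mean_um, cv * spec.L2F_mean_um)
        if not (0 < L1U < L2M and L2F > 0):
            continue
        x_ie_md = L2M - L1U  # mastication surface by the lever construction
        x_ie_fd = min(x_ie_md * rng.normal(1.0, 0.05), 0.999 * L2F)
        if x_ie_fd <= 0:
            continue
        alpha = float(np.clip(rng.normal(55.0, 5.0), 1.0, 179.0))
        return LeverGeometry(
            L1U=L1U, L2M=L2M, L2F=L2F,
            x_ie_md=x_ie_md, x_ie_fd=x_ie_fd, alpha_deg=alpha,
            F1AV=max(float(rng.normal(100.0, 10.0)), 0.0),
        )
    raise ValidationError(f"infeasible geometry spec for {spec.species_code} after 100 resamples")


# ---------------------------------------------------------------------------
# Specimen and cohort generation
# ---------------------------------------------------------------------------

def generate_specimen(
    spec: ArchetypeSpec, rng: np.random.Generator, specimen_id: str | None = None
) -> ChelaSpecimen:
    """Draw one specimen; fully determined by the generator state."""
    geom = _draw_geometry(rng, spec)
    span = 0.95 * min(geom.x_ie_md, geom.x_ie_fd)

    k = _draw_ztp(rng, spec.n_peaks_md)
    px = _peak_locations(rng, k, spec.mass_centroid, span)
    ph = spec.height_scale_um * rng.lognormal(0.0, 0.25, size=k)
    if spec.blade_fraction_md > 0.9:
        # blade-like digit: one dominant cutting edge, stereotyped at the
        # species mass centroid (specialist structures vary little)
        j = int(np.argmin(np.abs(px - spec.mass_centroid * span)))
        px[j] = spec.mass_centroid * span
        px.sort()
        ph[int(np.argmin(np.abs(px - spec.mass_centroid * span)))] *= 4.0

    # interleaved gullets; the tip-adjacent gullet floor sits exactly on the axis
    gx = np.empty(k + 1)
    gh = np.empty(k + 1)
    gx[0] = 0.5 * px[0]
    gh[0] = 0.0
    for i in range(1, k):
        gx[i] = 0.5 * (px[i - 1] + px[i])
        gh[i] = rng.uniform(0.05, 0.35) * min(ph[i - 1], ph[i])
    gx[k] = 0.5 * (px[-1] + span)
    gh[k] = rng.uniform(0.05, 0.35) * ph[-1]

    md_x = np.concatenate([gx, px])
    md_y = np.concatenate([gh, ph])
    md_kind = [AsperityKind.GULLET] * (k + 1) + [AsperityKind.PEAK] * k
    order = np.argsort(md_x)
    md_x, md_y = md_x[order], md_y[order]
    md_kind = [md_kind[i] for i in order]

    # fixed digit: occlusal complement (peaks at gullet sites, heights flipped)
    fd_x = md_x.copy()
    fd_y = md_y.max() - md_y
    fd_kind = [
        AsperityKind.PEAK if kk is AsperityKind.GULLET else AsperityKind.GULLET
        for kk in md_kind
    ]
    eps = 1.0 - spec.complementarity
    if eps > 0:
        fd_x = fd_x + rng.normal(0.0, eps * 0.06 * span, size=fd_x.size)
        fd_x = np.clip(fd_x, 0.02 * span, span)
        fd_y = np.clip(fd_y + rng.normal(0.0, eps * 0.4 * spec.height_scale_um, size=fd_y.size), 0.0, None)
        if spec.pockets_fd:
            pocket_x = np.array([0.50, 0.80]) * span
            pocket_y = np.zeros(2)  # pockets: deep zero-height features
            fd_x = np.concatenate([fd_x, pocket_x])
            fd_y = np.concatenate([fd_y, pocket_y])
            fd_kind = fd_kind + [AsperityKind.GULLET, AsperityKind.GULLET]
        order = np.argsort(fd_x)
        fd_x, fd_y = fd_x[order], fd_y[order]
        fd_kind = [fd_kind[i] for i in order]

    # calibrate the grid-profile roughness to the species target
    md_prof = _grid_profile(Digit.MOVEABLE, geom.L2M, [
        Asperity(x=float(x), y=float(y), kind=kk) for x, y, kk in zip(md_x, md_y, md_kind)
    ], tail_height=0.8 * spec.height_scale_um)
    fd_prof = _grid_profile(Digit.FIXED, geom.L2F, [
        Asperity(x=float(x), y=float(y), kind=kk) for x, y, kk in zip(fd_x, fd_y, fd_kind)
    ], tail_height=0.8 * spec.height_scale_um)

    def rescale(prof: GridProfile, x_ie: float, y_raw: np.ndarray, noise: float):
        mask = prof.x <= x_ie
        rq = float(np.sqrt(np.mean(prof.y[mask] ** 2)))
        s = spec.roughness_target_um * noise / max(rq, 1e-12)
        return GridProfile(prof.digit_kind, prof.x, prof.y * s), y_raw * s

    md_prof, md_y = rescale(md_prof, geom.x_ie_md, md_y, float(rng.lognormal(0.0, 0.10)))
    fd_prof, fd_y = rescale(fd_prof, geom.x_ie_fd, fd_y, float(rng.lognormal(0.0, 0.10)))

    md_asp = _assign_classes(rng, [
        Asperity(x=float(x), y=float(y), kind=kk) for x, y, kk in zip(md_x, md_y, md_kind)
    ], spec, Digit.MOVEABLE)
    fd_asp = _assign_classes(rng, [
        Asperity(x=float(x), y=float(y), kind=kk) for x, y, kk in zip(fd_x, fd_y, fd_kind)
    ], spec, Digit.FIXED)

    # tip offset: overbite with the preset probability, exact ties at the tie rate
    u = rng.uniform()
    if u < spec.overbite_prob:
        tip_offset = float(rng.exponential(spec.overbite_scale_um))
    elif u < spec.overbite_prob + spec.tie_prob:
        tip_offset = 0.0
    else:
        tip_offset = -float(rng.exponential(0.8 * spec.overbite_scale_um))

    socket = None if spec.socket_prob is None else bool(rng.uniform() < spec.socket_prob)
    snub = bool(rng.uniform() < spec.snub_prob)
    return ChelaSpecimen(
        specimen_id=specimen_id or f"{spec.species_code}-unnamed",
        species_code=spec.species_code,
        geometry=geom,
        md_profile=md_prof,
        fd_profile=fd_prof,
        md_asperities=md_asp,
        fd_asperities=fd_asp,
        tip_offset_um=tip_offset,
        tip_angle_md_deg=float(np.clip(rng.normal(50.0, 8.0), 5.0, 120.0)),
        tip_angle_fd_deg=float(np.clip(rng.normal(50.0, 8.0), 5.0, 120.0)),
        kerf_md_um=max(float(rng.normal(1.5, 0.3)), 0.1),
        kerf_fd_um=max(float(rng.normal(1.5, 0.3)), 0.1),
        socket_present=socket,
        snub_nose=snub,
        MvG_um3=None if spec.MvG_mean_um3 is None else float(rng.normal(spec.MvG_mean_um3, 0.1 * spec.MvG_mean_um3)),
        TMvG_um3=None if spec.TMvG_mean_um3 is None else float(rng.normal(spec.TMvG_mean_um3, 0.1 * spec.TMvG_mean_um3)),
    )


def generate_cohorts(
    presets: dict[str, ArchetypeSpec] | None = None,
    n_per_species: int = 20,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> list[Cohort]:
    """Reproducible cohorts for every preset, optionally written to CSV.

    With ``out_dir`` set, writes profiles.csv / specimens.csv /
    asperities.csv plus a manifest.json recording seed and parameters;
    identical seeds produce byte-identical files.
    """
    if presets is None:
        presets = archetype_presets()
    if n_per_species < 1:
        raise ValidationError("n_per_species must be >= 1")
    rng = np.random.default_rng(seed)
    cohorts = []
    for code in presets:
        spec = presets[code]
        specimens = [
            generate_specimen(spec, rng, specimen_id=f"{code}-{i + 1:03d}")
            for i in range(n_per_species)
        ]
        cohorts.append(Cohort(species_code=code, specimens=specimens))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_specimens(
            cohorts, out / "profiles.csv", out / "specimens.csv", out / "asperities.csv"
        )
        manifest = {
            "seed": int(seed),
            "n_per_species": int(n_per_species),
            "presets": {
                code: {
                    k: v for k, v in dataclasses.asdict(presets[code]).items()
                }
                for code in presets
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return cohorts


def perfect_complement_pair(
    locations: Sequence[float],
    heights: Sequence[float],
    geometry: LeverGeometry,
    species_code: str = "PC",
    specimen_id: str = "PC-001",
) -> ChelaSpecimen:
    """Digit pair with exactly matching opposite asperities (distance 0).

    The pinking-shears configuration: every moveable-digit asperity meets a
    complementary fixed-digit feature at the same axial position.  Heights
    are shifted so the gullet floor touches the reference axis (min 0) and
    the fixed digit stores the flipped heights max(y) - y; both runs of the
    occlusion encoding then produce identical weighted point sets.  For
    constant input heights the fixed-digit weight vector degenerates to
    zero and :func:`occlusion.occlusive_distance` must be called with its
    uniform-weight fallback enabled.
    """
    x = np.asarray(locations, dtype=float)
    y = np.asarray(heights, dtype=float)
    if x.size == 0 or y.size != x.size:
        raise ValidationError("need matching non-empty locations and heights")
    if np.any(x <= 0) or x.max() > min(geometry.x_ie_md, geometry.x_ie_fd):
        raise ValidationError("locations must lie in (0, x_ie] of both digits")
    order = np.argsort(x)
    x, y = x[order], y[order]
    if np.ptp(y) == 0:
        md_y = y.astype(float)
        fd_y = y.astype(float)
    else:
        md_y = y - y.min()
        fd_y = md_y.max() - md_y
    med = np.median(md_y)
    md_kind = [AsperityKind.PEAK if v >= med else AsperityKind.GULLET for v in md_y]
    fd_kind = [
        AsperityKind.GULLET if kk is AsperityKind.PEAK else AsperityKind.PEAK for kk in md_kind
    ]
    md_asp = [Asperity(x=float(a), y=float(b), kind=kk) for a, b, kk in zip(x, md_y, md_kind)]
    fd_asp = [Asperity(x=float(a), y=float(b), kind=kk) for a, b, kk in zip(x, fd_y, fd_kind)]
    tail = float(md_y.max()) if md_y.max() > 0 else 1.0
    return ChelaSpecimen(
        specimen_id=specimen_id,
        species_code=species_code,
        geometry=geometry,
        md_profile=_grid_profile(Digit.MOVEABLE, geometry.L2M, md_asp, tail_height=0.5 * tail),
        fd_profile=_grid_profile(Digit.FIXED, geometry.L2F, fd_asp, tail_height=0.5 * tail),
        md_asperities=md_asp,
        fd_asperities=fd_asp,
        tip_offset_um=0.0,
    )
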
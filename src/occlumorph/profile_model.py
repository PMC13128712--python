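"""Domain types and tabular I/O for chelal digit profiles.

The chela of an astigmatan mite is a pincer formed by a fixed digit and a
lever-driven moveable digit.  Each digit is described in a common *occlusal
coordinate frame*: ``x`` runs in micrometres from the digit tip (x = 0)
toward the articulating condyle along the digit's reference axis (length
``L2M`` for the moveable digit, ``L2F`` for the fixed digit); ``y`` is the
profile height perpendicular to that axis.  Fixed digits are stored after a
vertical flip so that their gullets read as positive relief and the
peak/gullet vocabulary is uniform across digits.

Three tabular schemas carry the data (one row per station / specimen /
asperity respectively):

* ``profiles.csv``  — specimen_id, species_code, digit {md,fd}, station
  (1..18), x_um, y_um
* ``specimens.csv`` — specimen_id, species_code, lever geometry, tip
  offsets/angles and optional measured fields
* ``asperities.csv`` — specimen_id, digit, kind {peak,gullet}, x_um, y_um,
  tooth_class {ATB,FT,NA}, ordered distal→proximal within (specimen, digit)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Digit",
    "AsperityKind",
    "ToothClass",
    "OcclumorphError",
    "ValidationError",
    "SchemaError",
    "NumericalError",
    "DegenerateMassError",
    "LeverGeometry",
    "GridProfile",
    "Asperity",
    "ChelaSpecimen",
    "Cohort",
    "N_STATIONS",
    "flip_to_occlusal_frame",
    "extract_asperities",
    "load_specimens",
    "write_specimens",
]

#: Number of equispaced sampling stations along a digit reference axis.
N_STATIONS = 18


class OcclumorphError(Exception):
    """Base class for all package errors."""


class ValidationError(OcclumorphError):
    """An input violates a documented invariant."""


class SchemaError(ValidationError):
    """A table is missing required columns or carries malformed values."""


class NumericalError(OcclumorphError):
    """A numerical operation left its documented tolerance band."""


class DegenerateMassError(OcclumorphError):
    """All transport weights vanished after the digit-specific adjustment.

    Typical cause: a constant-height fixed digit, whose weight vector
    ``max(y) - y`` is identically zero.  Callers may opt in to a uniform
    weight fallback via an explicit flag.
    """


class Digit(str, Enum):
    MOVEABLE = "md"
    FIXED = "fd"


class AsperityKind(str, Enum):
    PEAK = "peak"
    GULLET = "gullet"


class ToothClass(str, Enum):
    ATB = "ATB"  # alternate top-bevel like (saw-like) tooth
    FT = "FT"    # flat-top (blade-like) tooth


def _as_digit(value) -> Digit:
    if isinstance(value, Digit):
        return value
    try:
        return Digit(value)
    except ValueError as exc:
        raise ValidationError(f"unknown digit kind {value!r}") from exc


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeverGeometry:
    """Chelal lever-arm geometry in micrometres.

    ``L1U`` is the adductive input moment arm, ``L2M``/``L2F`` the
    moveable/fixed digit tip→condyle reference axes (output moment arms),
    ``x_ie_md``/``x_ie_fd`` the end of each digit's mastication surface
    along its axis, ``alpha_deg`` the measured subtended chela angle and
    ``F1AV`` an optional measured input force in arbitrary units.
    """

    L1U: float
    L2M: float
    L2F: float
    x_ie_md: float
    x_ie_fd: float
    alpha_deg: float
    F1AV: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.L1U < self.L2M):
            raise ValidationError(
                f"require 0 < L1U < L2M, got L1U={self.L1U}, L2M={self.L2M}"
            )
        if not (0.0 < self.x_ie_md <= self.L2M):
            raise ValidationError(
                f"require 0 < x_ie_md <= L2M, got x_ie_md={self.x_ie_md}"
            )
        if self.L2F <= 0 or not (0.0 < self.x_ie_fd <= self.L2F):
            raise ValidationError(
                f"require 0 < x_ie_fd <= L2F, got x_ie_fd={self.x_ie_fd}, L2F={self.L2F}"
            )
        if not (0.0 < self.alpha_deg < 180.0):
            raise ValidationError(f"alpha_deg must lie in (0, 180), got {self.alpha_deg}")
        if self.F1AV is not None and self.F1AV < 0:
            raise ValidationError("F1AV must be non-negative")


@dataclass(frozen=True)
class GridProfile:
    """Equispaced digit height profile in the occlusal frame.

    Station 1 is the digit tip with x = 0 and y = 0 by definition; x
    increases strictly toward the condyle on an equispaced grid (tolerance
    1e-6 of the axis length).
    """

    digit_kind: Digit
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "digit_kind", _as_digit(self.digit_kind))
        if x.ndim != 1 or x.shape != y.shape or x.size < 2:
            raise ValidationError("profile needs matching 1-D x and y with >= 2 stations")
        if not (np.isfinite(x).all() and np.isfinite(y).all()):
            raise ValidationError("profile coordinates must be finite")
        if x[0] != 0.0:
            raise ValidationError("station 1 must sit at the digit tip, x_1 = 0")
        if y[0] != 0.0:
            raise ValidationError("digit tip height must be exactly zero (y_1 = 0)")
        if np.any(np.diff(x) <= 0):
            raise ValidationError("station x must be strictly increasing toward the condyle")
        spacing = np.diff(x)
        if np.ptp(spacing) > 1e-6 * x[-1]:
            raise ValidationError("stations must be equispaced within 1e-6 of axis length")

    @property
    def n_stations(self) -> int:
        return int(self.x.size)

    def station_x(self, k: int) -> float:
        """x of 1-based station index ``k``."""
        return float(self.x[k - 1])


@dataclass(frozen=True)
class Asperity:
    """One scored relief feature (peak = tooth, gullet = valley)."""

    x: float
    y: float
    kind: AsperityKind
    tooth_class: Optional[ToothClass] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", AsperityKind(self.kind))
        if self.tooth_class is not None and not isinstance(self.tooth_class, ToothClass):
            object.__setattr__(self, "tooth_class", ToothClass(self.tooth_class))
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError("asperity coordinates must be finite")
        if self.x <= 0:
            raise ValidationError(f"asperity x must be > 0 (tip excluded), got {self.x}")
        if self.y < 0:
            raise ValidationError(f"asperity height must be >= 0 in the occlusal frame, got {self.y}")


@dataclass
class ChelaSpecimen:
    """One mite's paired digits with geometry and scored asperities.

    ``tip_offset_um`` sign convention: positive = fixed digit tip anterior
    of the moveable tip = overbite (negative = underbite, 0 = exact match).
    """

    specimen_id: str
    species_code: str
    geometry: LeverGeometry
    md_profile: GridProfile
    fd_profile: GridProfile
    md_asperities: list[Asperity]
    fd_asperities: list[Asperity]
    tip_offset_um: float
    tip_angle_md_deg: Optional[float] = None
    tip_angle_fd_deg: Optional[float] = None
    kerf_md_um: Optional[float] = None
    kerf_fd_um: Optional[float] = None
    socket_present: Optional[bool] = None
    snub_nose: Optional[bool] = None
    MvG_um3: Optional[float] = None
    TMvG_um3: Optional[float] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        tol = 1e-9
        for asp in self.md_asperities:
            if asp.x > self.geometry.x_ie_md * (1 + tol):
                raise ValidationError(
                    f"specimen {self.specimen_id}: moveable asperity at x={asp.x} "
                    f"beyond x_ie_md={self.geometry.x_ie_md}"
                )
        for asp in self.fd_asperities:
            if asp.x > self.geometry.x_ie_fd * (1 + tol):
                raise ValidationError(
                    f"specimen {self.specimen_id}: fixed asperity at x={asp.x} "
                    f"beyond x_ie_fd={self.geometry.x_ie_fd}"
                )
        if self.md_profile.digit_kind is not Digit.MOVEABLE:
            raise ValidationError(f"specimen {self.specimen_id}: md_profile has wrong digit kind")
        if self.fd_profile.digit_kind is not Digit.FIXED:
            raise ValidationError(f"specimen {self.specimen_id}: fd_profile has wrong digit kind")

    def profile(self, digit: Digit | str) -> GridProfile:
        return self.md_profile if _as_digit(digit) is Digit.MOVEABLE else self.fd_profile

    def asperities(self, digit: Digit | str) -> list[Asperity]:
        return self.md_asperities if _as_digit(digit) is Digit.MOVEABLE else self.fd_asperities

    def x_ie(self, digit: Digit | str) -> float:
        return (
            self.geometry.x_ie_md
            if _as_digit(digit) is Digit.MOVEABLE
            else self.geometry.x_ie_fd
        )


@dataclass
class Cohort:
    """All measured specimens of one species (typically n = 20 females)."""

    species_code: str
    specimens: list[ChelaSpecimen]

    def __post_init__(self) -> None:
        if not self.specimens:
            raise ValidationError("a cohort needs at least one specimen")
        ids = [s.specimen_id for s in self.specimens]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate specimen ids in cohort {self.species_code}")
        for s in self.specimens:
            if s.species_code != self.species_code:
                raise ValidationError(
                    f"specimen {s.specimen_id} species {s.species_code} != cohort {self.species_code}"
                )

    def __len__(self) -> int:
        return len(self.specimens)


# ---------------------------------------------------------------------------
# Frame handling and asperity extraction
# ---------------------------------------------------------------------------

def flip_to_occlusal_frame(raw_fd_heights: Sequence[float], x: Sequence[float] | None = None):
    """Vertically flip a fixed digit's native heights into the occlusal frame.

    In the fixed digit's native frame its gullets lie below the reference
    axis; the occlusal convention negates the heights so gullets read as
    positive relief.  The flip is an involution.

    Returns the negated height array, or a fixed-digit :class:`GridProfile`
    when station coordinates ``x`` are supplied.
    """
    y = np.asarray(raw_fd_heights, dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("fixed digit heights must be finite")
    flipped = -y
    # avoid the IEEE -0.0 artefact at the tip station
    flipped = flipped + 0.0
    if x is None:
        return flipped
    return GridProfile(digit_kind=Digit.FIXED, x=np.asarray(x, dtype=float), y=flipped)


def extract_asperities(profile: GridProfile, min_prominence: float = 0.0) -> list[Asperity]:
    """Derive peak/gullet asperities from a grid profile.

    Interior local maxima become peaks, interior local minima gullets, each
    filtered at topographic prominence >= ``min_prominence``; plateaus
    contribute a single asperity at the plateau midpoint.  The result is
    ordered by x and invariant to adding a constant to all heights.

    Asperities are normally scored by eye from micrographs; this derivation
    is a convenience and is never substituted for supplied asperity lists
    unless explicitly requested.
    """
    if min_prominence < 0:
        raise ValidationError("min_prominence must be >= 0")
    out: list[Asperity] = []
    for kind, signed in ((AsperityKind.PEAK, 1.0), (AsperityKind.GULLET, -1.0)):
        kwargs = {"plateau_size": (1, None)}
        if min_prominence > 0:
            kwargs["prominence"] = min_prominence
        idx, props = find_peaks(signed * profile.y, **kwargs)
        left = props["left_edges"]
        right = props["right_edges"]
        for i in range(idx.size):
            xm = 0.5 * (profile.x[left[i]] + profile.x[right[i]])
            if xm <= 0:
                continue
            out.append(Asperity(x=float(xm), y=float(profile.y[idx[i]]), kind=kind))
    out.sort(key=lambda a: a.x)
    return out


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_PROFILE_COLS = ["specimen_id", "species_code", "digit", "station", "x_um", "y_um"]
_SPECIMEN_COLS = [
    "specimen_id", "species_code", "L1U_um", "L2M_um", "L2F_um",
    "x_ie_md_um", "x_ie_fd_um", "alpha_deg", "tip_offset_um",
]
_SPECIMEN_OPT_COLS = [
    "tip_angle_md_deg", "tip_angle_fd_deg", "kerf_md_um", "kerf_fd_um",
    "socket", "snub", "F1AV", "MvG_um3", "TMvG_um3",
]
_ASPERITY_COLS = ["specimen_id", "digit", "kind", "x_um", "y_um", "tooth_class"]


def _require_columns(df: pd.DataFrame, cols: Iterable[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} is missing required column(s): {', '.join(missing)}")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def _opt_bool(value) -> Optional[bool]:
    v = _opt_float(value)
    return None if v is None else bool(round(v))


def load_specimens(profiles_table, specimens_table, asperities_table) -> list[Cohort]:
    """Read the three CSV schemas and return validated cohorts by species."""
    read = dict(float_precision="round_trip")
    profiles = pd.read_csv(profiles_table, **read)
    specimens = pd.read_csv(specimens_table, **read)
    asperities = pd.read_csv(asperities_table, **read)
    _require_columns(profiles, _PROFILE_COLS, "profiles table")
    _require_columns(specimens, _SPECIMEN_COLS, "specimens table")
    _require_columns(asperities, _ASPERITY_COLS, "asperities table")

    prof_groups = {k: g for k, g in profiles.groupby(["specimen_id", "digit"], sort=False)}
    asp_groups = {k: g for k, g in asperities.groupby(["specimen_id", "digit"], sort=False)}

    def build_profile(sid: str, digit: Digit) -> GridProfile:
        key = (sid, digit.value)
        if key not in prof_groups:
            raise ValidationError(f"specimen {sid}: no {digit.value} profile rows")
        g = prof_groups[key].sort_values("station")
        try:
            return GridProfile(
                digit_kind=digit,
                x=g["x_um"].to_numpy(float),
                y=g["y_um"].to_numpy(float),
            )
        except ValidationError as exc:
            raise ValidationError(f"specimen {sid} ({digit.value} profile): {exc}") from exc

    def build_asperities(sid: str, digit: Digit) -> list[Asperity]:
        key = (sid, digit.value)
        if key not in asp_groups:
            return []
        out = []
        for _, row in asp_groups[key].iterrows():
            tc = row["tooth_class"]
            tc = None if pd.isna(tc) or str(tc).upper() in {"NA", "NONE", ""} else ToothClass(str(tc))
            try:
                out.append(
                    Asperity(
                        x=float(row["x_um"]), y=float(row["y_um"]),
                        kind=AsperityKind(str(row["kind"])), tooth_class=tc,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"specimen {sid} ({digit.value} asperity): {exc}") from exc
        return out

    cohorts: dict[str, list[ChelaSpecimen]] = {}
    for _, row in specimens.iterrows():
        sid = str(row["specimen_id"])
        species = str(row["species_code"])
        try:
            geom = LeverGeometry(
                L1U=float(row["L1U_um"]), L2M=float(row["L2M_um"]), L2F=float(row["L2F_um"]),
                x_ie_md=float(row["x_ie_md_um"]), x_ie_fd=float(row["x_ie_fd_um"]),
                alpha_deg=float(row["alpha_deg"]),
                F1AV=_opt_float(row.get("F1AV")),
            )
            spec = ChelaSpecimen(
                specimen_id=sid,
                species_code=species,
                geometry=geom,
                md_profile=build_profile(sid, Digit.MOVEABLE),
                fd_profile=build_profile(sid, Digit.FIXED),
                md_asperities=build_asperities(sid, Digit.MOVEABLE),
                fd_asperities=build_asperities(sid, Digit.FIXED),
                tip_offset_um=float(row["tip_offset_um"]),
                tip_angle_md_deg=_opt_float(row.get("tip_angle_md_deg")),
                tip_angle_fd_deg=_opt_float(row.get("tip_angle_fd_deg")),
                kerf_md_um=_opt_float(row.get("kerf_md_um")),
                kerf_fd_um=_opt_float(row.get("kerf_fd_um")),
                socket_present=_opt_bool(row.get("socket")),
                snub_nose=_opt_bool(row.get("snub")),
                MvG_um3=_opt_float(row.get("MvG_um3")),
                TMvG_um3=_opt_float(row.get("TMvG_um3")),
            )
        except ValidationError as exc:
            raise ValidationError(f"specimen {sid}: {exc}") from exc
        cohorts.setdefault(species, []).append(spec)
    return [Cohort(species_code=sp, specimens=specs) for sp, specs in cohorts.items()]


def write_specimens(cohorts: Sequence[Cohort], profiles_table, specimens_table, asperities_table) -> None:
    """Write cohorts back to the three CSV schemas (units: μm / degrees)."""
    prof_rows, spec_rows, asp_rows = [], [], []
    for cohort in cohorts:
        for s in cohort.specimens:
            for digit in (Digit.MOVEABLE, Digit.FIXED):
                p = s.profile(digit)
                for k in range(p.n_stations):
                    prof_rows.append({
                        "specimen_id": s.specimen_id, "species_code": s.species_code,
                        "digit": digit.value, "station": k + 1,
                        "x_um": repr(float(p.x[k])), "y_um": repr(float(p.y[k])),
                    })
                for asp in s.asperities(digit):
                    asp_rows.append({
                        "specimen_id": s.specimen_id, "digit": digit.value,
                        "kind": asp.kind.value,
                        "x_um": repr(float(asp.x)), "y_um": repr(float(asp.y)),
                        "tooth_class": asp.tooth_class.value if asp.tooth_class else "NA",
                    })
            g = s.geometry
            spec_rows.append({
                "specimen_id": s.specimen_id, "species_code": s.species_code,
                "L1U_um": repr(g.L1U), "L2M_um": repr(g.L2M), "L2F_um": repr(g.L2F),
                "x_ie_md_um": repr(g.x_ie_md), "x_ie_fd_um": repr(g.x_ie_fd),
                "alpha_deg": repr(g.alpha_deg), "tip_offset_um": repr(s.tip_offset_um),
                "tip_angle_md_deg": "" if s.tip_angle_md_deg is None else repr(s.tip_angle_md_deg),
                "tip_angle_fd_deg": "" if s.tip_angle_fd_deg is None else repr(s.tip_angle_fd_deg),
                "kerf_md_um": "" if s.kerf_md_um is None else repr(s.kerf_md_um),
                "kerf_fd_um": "" if s.kerf_fd_um is None else repr(s.kerf_fd_um),
                "socket": "" if s.socket_present is None else int(s.socket_present),
                "snub": "" if s.snub_nose is None else int(s.snub_nose),
                "F1AV": "" if g.F1AV is None else repr(g.F1AV),
                "MvG_um3": "" if s.MvG_um3 is None else repr(s.MvG_um3),
                "TMvG_um3": "" if s.TMvG_um3 is None else repr(s.TMvG_um3),
            })
    pd.DataFrame(prof_rows, columns=_PROFILE_COLS).to_csv(profiles_table, index=False)
    pd.DataFrame(spec_rows, columns=_SPECIMEN_COLS + _SPECIMEN_OPT_COLS).to_csv(
        specimens_table, index=False
    )
    pd.DataFrame(asp_rows, columns=_ASPERITY_COLS).to_csv(asperities_table, index=False)
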
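"""Data model for chelal moveable-digit profiles and closed-form estimators.

A mite's chelal moveable digit is described by its dorsal (mastication
surface) profile projected onto the output-lever reference axis ``L2M``:
18 stations equally spaced from the digit tip (pinned at the origin) to
the condyle, with signed heights relative to the axis.  Alongside the
profile sit scalar chelal measurements (lever arms, cheliceral height and
length, digit depth, kerf, thickness, design angle, tip angles) from which
simple lever-mechanics force proxies are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

N_STATIONS = 18

__all__ = [
    "N_STATIONS",
    "DigitProfile",
    "ChelalMeasures",
    "ForceEstimates",
    "MalformedProfileError",
    "standardize_profile",
    "velocity_ratio",
    "tip_diameter",
    "curvature_b",
    "force_estimates",
    "classify_lever",
    "locate_x_ie",
]


class MalformedProfileError(ValueError):
    """Raised when raw landmark input violates the profile conventions."""


@dataclass(frozen=True)
class DigitProfile:
    """One individual's standardized 18-station moveable-digit profile.

    Attributes
    ----------
    taxon_id, individual_id:
        Text labels identifying the sample and the specimen.
    x:
        Station abscissae in µm along the L2M axis; strictly increasing
        with ``x[0] == 0`` at the digit tip.
    y:
        Signed profile heights in µm relative to the L2M axis;
        ``y[0] == 0`` (the tip is pinned at the origin).  Heights may be
        negative where the surface dips below the axis.
    """

    taxon_id: str
    individual_id: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != (N_STATIONS,) or y.shape != (N_STATIONS,):
            raise MalformedProfileError(
                f"profile needs exactly {N_STATIONS} (x, y) stations, "
                f"got {x.shape} / {y.shape}"
            )
        if not np.all(np.diff(x) > 0):
            raise MalformedProfileError("station abscissae must be strictly increasing")
        if x[0] != 0.0:
            raise MalformedProfileError("tip station must sit at x = 0")
        if y[0] != 0.0:
            raise MalformedProfileError("tip height must be pinned at y = 0")

    @property
    def l2m(self) -> float:
        """Length of the reference axis (abscissa of the condyle station)."""
        return float(self.x[-1])


@dataclass(frozen=True)
class ChelalMeasures:
    """Scalar chelal measurements for one individual.

    Lengths in µm, angles in degrees.  ``L1U``/``L2M`` are the input and
    output lever moment arms; ``CHI``/``CLI`` cheliceral height and length
    (reach); ``W`` the digit depth at the end of the mastication surface;
    ``kerf`` the sawn-groove width; ``thick`` the digit thickness;
    ``alpha`` the lever design angle; ``x_ie`` the abscissa of the end of
    the tooth row and ``e_index`` its 1-based station index.
    """

    L1U: float
    L2M: float
    CHI: float
    CLI: float
    W: float
    kerf: float
    thick: float
    alpha: float
    tip_angle: float
    distal_angle: float
    x_ie: float
    e_index: int

    def __post_init__(self) -> None:
        for name in ("L1U", "L2M", "CHI", "CLI", "W", "kerf", "thick"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.tip_angle < 180:
            raise ValueError("tip_angle must lie in (0, 180) degrees")
        if self.x_ie > self.L2M:
            raise ValueError("x_ie cannot exceed L2M")


@dataclass(frozen=True)
class ForceEstimates:
    """Adductive-force proxies from the static rigid-lever chelal model.

    ``F1*`` are input (tendon) forces under the pennate (``F1P ∝ CHI·CLI``)
    and circular (``F1C ∝ CHI²``) muscle-packing assumptions; ``F2* =
    VR·F1*`` are the output crunch forces at the digit; ``*AV`` are the
    two-assumption averages.  Units are arbitrary but mutually consistent.
    """

    F1P: float
    F1C: float
    F1AV: float
    F2P: float
    F2C: float
    F2AV: float
    VR: float


def standardize_profile(
    raw_points: np.ndarray,
    l2m: float,
    *,
    taxon_id: str = "",
    individual_id: str = "",
) -> DigitProfile:
    """Project a raw landmark polyline onto the 18 standard stations.

    The raw polyline (``(k, 2)`` array of (x, y) in µm, first point the
    tip) is linearly interpolated at 18 equally spaced stations on
    ``[0, l2m]``; the tip is pinned at the origin.

    Raises
    ------
    MalformedProfileError
        If fewer than two points are supplied or the raw abscissae are
        not strictly increasing.
    """
    pts = np.asarray(raw_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise MalformedProfileError("need at least two (x, y) raw points")
    if l2m <= 0:
        raise MalformedProfileError("L2M must be positive")
    rx, ry = pts[:, 0], pts[:, 1]
    if not np.all(np.diff(rx) > 0):
        raise MalformedProfileError("raw abscissae must be strictly increasing")
    stations = np.linspace(0.0, float(l2m), N_STATIONS)
    y = np.interp(stations, rx - rx[0], ry - ry[0])
    y[0] = 0.0
    return DigitProfile(taxon_id=taxon_id, individual_id=individual_id, x=stations, y=y)


def velocity_ratio(m: ChelalMeasures) -> float:
    """Chelal velocity ratio VR = L1U / L2M (ideal mechanical advantage)."""
    if m.L2M == 0:
        raise ZeroDivisionError("L2M must be nonzero")
    return m.L1U / m.L2M


def tip_diameter(tip_angle: float, delta: float = 1.0) -> float:
    """Digit tip diameter ``2·δ·tan(tip_angle / 2)`` at δ units behind the point.

    ``tip_angle`` in degrees, ``0 ≤ tip_angle < 180``.
    """
    if not 0 <= tip_angle < 180:
        raise ValueError("tip_angle must lie in [0, 180) degrees")
    return 2.0 * delta * math.tan(math.radians(tip_angle) / 2.0)


def curvature_b(w: float, base_depth: float) -> float:
    """Ventral curvature parameter b from saw depth W and dentition base depth.

    Inverts ``W ≈ base_depth / (1 − 1/b)`` to ``b = W / (W − base_depth)``;
    1/b is the common ratio of the implied geometric depth series.  By
    convention ``base_depth`` is the tip diameter at δ = 1 (a non-curved-up
    tip).  Requires ``0 < base_depth < W``.
    """
    if not 0 < base_depth < w:
        raise ValueError("undefined curvature: need 0 < base_depth < W")
    return w / (w - base_depth)


def force_estimates(
    m: ChelalMeasures, k_p: float = 1.0, k_c: float = 1.0
) -> ForceEstimates:
    """Static lever-model force proxies for one set of chelal measures.

    F1P = k_p·CHI·CLI (pennate packing), F1C = k_c·CHI² (circular packing);
    output forces are the inputs premultiplied by the velocity ratio.
    """
    vr = velocity_ratio(m)
    f1p = k_p * m.CHI * m.CLI
    f1c = k_c * m.CHI**2
    f2p = vr * f1p
    f2c = vr * f1c
    return ForceEstimates(
        F1P=f1p,
        F1C=f1c,
        F1AV=(f1p + f1c) / 2.0,
        F2P=f2p,
        F2C=f2c,
        F2AV=(f2p + f2c) / 2.0,
        VR=vr,
    )


def tip_force(m: ChelalMeasures) -> float:
    """Individual-level tip-force proxy VR·CHI² (circular-packing form)."""
    return velocity_ratio(m) * m.CHI**2


def classify_lever(alpha: float, threshold: float = 90.0) -> str:
    """Classify the chelal lever design from the α angle.

    ``class1_crushing`` for α ≤ threshold (boundary inclusive by
    convention), ``class3_cutting`` above.  No universal cutoff exists;
    the default 90° reflects the typical crushing-design α with cutting
    taxa elevated above it, and is configurable.
    """
    if not 0 < alpha < 180:
        raise ValueError("alpha must lie in (0, 180) degrees")
    return "class3_cutting" if alpha > threshold else "class1_crushing"


def locate_x_ie(p: DigitProfile) -> tuple[float, int]:
    """Locate the end of the mastication surface on a standardized profile.

    Returns ``(x_ie, e_index)`` where ``e_index`` (1-based) is the largest
    station at which the height last crosses or touches the L2M axis
    before the ascending-ramus rise; runs of exact zeros resolve to the
    last zero.  Falls back to the tip station if the profile never
    returns to the axis.
    """
    y = p.y
    last = 0  # 0-based index of last axis contact / sign change
    for i in range(1, N_STATIONS):
        if y[i] == 0.0 or (y[i - 1] != 0.0 and np.sign(y[i]) != np.sign(y[i - 1])):
            last = i
    return float(p.x[last]), last + 1


def with_derived_x_ie(m: ChelalMeasures, p: DigitProfile) -> ChelalMeasures:
    """Return measures with ``x_ie``/``e_index`` recomputed from the profile."""
    x_ie, e_index = locate_x_ie(p)
    return replace(m, x_ie=x_ie, e_index=e_index)
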
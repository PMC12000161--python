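"""Synthetic digit-profile cohorts with the structure the analysis assumes.

Real cohorts are 20 adult females per sample, each drawn and projected
onto 18 equally spaced stations along the L2M axis with the tip pinned at
the origin.  The generator emulates that design: a parametric species
template (tip wedge, mastication plateau, optional breasting swell, local
tooth/gullet modules, ascending-ramus rise into the basal ramus) plus
i.i.d. Gaussian within-species height noise at every unpinned station.
Replicate cohorts of the same template calibrate the replicate-spread
noise scale exactly as independent field samples of one species would.

Two constructions are provided for transect ground truth:

* :func:`generate_community` — profile-level cohorts, optionally with
  templates interpolated between two extremes, and a JSON-serializable
  manifest of what was planted;
* :func:`spd_community` — taxa planted directly in SPD space (commuting
  log-coordinates, so planted geodesics are exact), with tangent-space
  cohort noise; this is the fixture for transect-recovery tests, since
  profile-level templates cannot sit exactly on an affine-invariant
  geodesic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .omega import OmegaMatrix, consensus_omega
from .profile_model import ChelalMeasures, DigitProfile, N_STATIONS
from .spd import spd_exp

__all__ = [
    "SpeciesTemplate",
    "CommunityFixture",
    "template_heights",
    "generate_cohort",
    "generate_community",
    "interpolate_templates",
    "spd_community",
]


@dataclass(frozen=True)
class SpeciesTemplate:
    """Parametric species-level template for a moveable-digit profile.

    Geometry (µm unless noted): ``l2m`` reference-axis length; the
    mastication surface dips off the tip into a plateau ``plateau_depth``
    below the axis (``tip_sharpness`` in stations controls how fast),
    runs level to the end of the tooth row at station ``e_index``, then
    the ascending ramus rises through the axis to ``basal_height`` with a
    logistic profile of width ``roundness`` stations.  ``breasting`` adds
    a broad swell centred mid-tooth-row; ``modules`` are local Gaussian
    asperities ``(centre_station, amplitude, width_stations)`` with
    positive amplitude = apparent peak (tooth), negative = gullet.
    ``noise_sd`` is the within-cohort per-station height SD; ``ar1_rho``
    optionally correlates adjacent stations' noise; ``heavy_tails``
    switches to t(4) noise.  The remaining fields parameterize the
    companion chelal measures.
    """

    label: str
    l2m: float = 170.0
    e_index: int = 10
    plateau_depth: float = 7.0
    tip_sharpness: float = 0.8
    basal_height: float = 45.0
    roundness: float = 1.5
    breasting: float = 0.0
    modules: tuple[tuple[float, float, float], ...] = ()
    noise_sd: float = 1.5
    ar1_rho: float = 0.0
    heavy_tails: bool = False
    vr: float = 0.5
    chi_frac: float = 0.9
    cli_frac: float = 2.2
    w: float = 25.0
    kerf: float = 4.0
    thick: float = 6.0
    alpha: float = 90.0
    jitter_frac: float = 0.03
    transit_t: float | None = None

    def __post_init__(self) -> None:
        if not 8 <= self.e_index <= 12:
            raise ValueError("e_index must lie in 8..12")


def template_heights(t: SpeciesTemplate) -> np.ndarray:
    """Evaluate a template's 18 station heights (station 1 pinned at 0)."""
    s = np.arange(1, N_STATIONS + 1, dtype=float)
    wedge = 1.0 - np.exp(-(s - 1.0) / t.tip_sharpness)
    mid = t.e_index + (N_STATIONS - t.e_index) / 2.0
    ascend = t.basal_height / (1.0 + np.exp(-(s - mid) / t.roundness))
    y = -t.plateau_depth * wedge + ascend
    y += t.breasting * np.exp(-((s - 6.0) ** 2) / (2 * 2.5**2))
    for centre, amp, width in t.modules:
        y += amp * np.exp(-((s - centre) ** 2) / (2 * width**2))
    return y - y[0]


def _station_noise(t: SpeciesTemplate, n: int, rng: np.random.Generator) -> np.ndarray:
    if t.heavy_tails:
        raw = rng.standard_t(4, size=(n, N_STATIONS)) * t.noise_sd / math.sqrt(2.0)
    else:
        raw = rng.normal(0.0, t.noise_sd, size=(n, N_STATIONS))
    if t.ar1_rho:
        rho = t.ar1_rho
        out = np.empty_like(raw)
        out[:, 0] = raw[:, 0]
        for j in range(1, N_STATIONS):
            out[:, j] = rho * out[:, j - 1] + math.sqrt(1 - rho**2) * raw[:, j]
        raw = out
    raw[:, 0] = 0.0  # tip stays pinned
    return raw


def generate_cohort(
    t: SpeciesTemplate,
    n: int = 20,
    seed: int | np.random.Generator = 0,
    sample_id: str | None = None,
) -> tuple[list[DigitProfile], list[ChelalMeasures]]:
    """Simulate one cohort of ``n`` individuals from a species template.

    Heights are the template plus i.i.d. station noise (tip pinned);
    companion measures derive consistently from the template: the tip
    angle doubles the first-increment slope angle of the template, W is
    the template's digit depth at the tooth-row end, and VR (with the
    other scalars) carries a small multiplicative jitter per individual.
    Fully reproducible from the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sample_id is None:
        sample_id = t.label
    base = template_heights(t)
    x = np.linspace(0.0, t.l2m, N_STATIONS)
    h = x[1] - x[0]
    noise = _station_noise(t, n, rng)
    tip_angle = 2.0 * abs(math.degrees(math.atan2(abs(base[1] - base[0]), h)))
    tip_angle = min(max(tip_angle, 1.0), 179.0)
    profiles, measures = [], []
    for i in range(n):
        y = base + noise[i]
        y[0] = 0.0
        jit = 1.0 + t.jitter_frac * rng.standard_normal(8)
        l1u = t.vr * t.l2m * jit[0]
        profiles.append(
            DigitProfile(
                taxon_id=sample_id, individual_id=f"{sample_id}-{i + 1:02d}", x=x, y=y
            )
        )
        measures.append(
            ChelalMeasures(
                L1U=l1u,
                L2M=t.l2m,
                CHI=t.chi_frac * t.l2m * jit[1],
                CLI=t.cli_frac * t.l2m * jit[2],
                W=t.w * jit[3],
                kerf=t.kerf * jit[4],
                thick=t.thick * jit[5],
                alpha=t.alpha * jit[6],
                tip_angle=min(max(tip_angle * jit[7], 1.0), 179.0),
                distal_angle=min(tip_angle * 1.9, 179.0),
                x_ie=(t.e_index - 1) * h,
                e_index=t.e_index,
            )
        )
    return profiles, measures


@dataclass(frozen=True)
class CommunityFixture:
    """A full simulated study: labelled cohorts plus ground-truth manifest.

    ``cohorts`` maps sample label → (profiles, measures); replicate
    templates contribute two independently sampled cohorts whose labels
    are recorded in ``replicate_pairs``.  ``manifest`` records what was
    planted (template parameters, modules, interpolation positions) and
    is JSON-serializable.
    """

    cohorts: dict[str, tuple[list[DigitProfile], list[ChelalMeasures]]]
    replicate_pairs: list[tuple[str, str]]
    manifest: dict


def generate_community(
    templates: list[SpeciesTemplate],
    replicate_labels: tuple[str, ...] = (),
    seed: int = 0,
    n: int = 20,
) -> CommunityFixture:
    """Simulate cohorts for a community of templates.

    Templates named in ``replicate_labels`` are sampled twice
    independently (labels ``X~1``/``X~2``), mirroring a study design with
    duplicate field samples for noise calibration.
    """
    rng = np.random.default_rng(seed)
    cohorts: dict[str, tuple[list[DigitProfile], list[ChelalMeasures]]] = {}
    replicate_pairs: list[tuple[str, str]] = []
    for t in templates:
        if t.label in replicate_labels:
            labs = (f"{t.label}~1", f"{t.label}~2")
            for lab in labs:
                cohorts[lab] = generate_cohort(t, n=n, seed=rng, sample_id=lab)
            replicate_pairs.append(labs)
        else:
            cohorts[t.label] = generate_cohort(t, n=n, seed=rng, sample_id=t.label)
    manifest = {
        "seed": seed,
        "n_per_cohort": n,
        "replicate_pairs": [list(p) for p in replicate_pairs],
        "templates": {
            t.label: {
                k: (list(map(list, v)) if k == "modules" else v)
                for k, v in asdict(t).items()
            }
            for t in templates
        },
        "planted_modules": {t.label: [list(m) for m in t.modules] for t in templates},
        "planted_transit_t": {
            t.label: t.transit_t for t in templates if t.transit_t is not None
        },
    }
    return CommunityFixture(cohorts=cohorts, replicate_pairs=replicate_pairs, manifest=manifest)


def interpolate_templates(
    a: SpeciesTemplate, b: SpeciesTemplate, t: float, label: str | None = None
) -> SpeciesTemplate:
    """Linear interpolation between two templates (planted intermediate form).

    Numeric geometry and measure parameters interpolate linearly;
    modules from both parents are kept with amplitudes faded by
    ``1 − t`` and ``t``.  ``transit_t`` records the planted position.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("interpolation parameter must lie in [0, 1]")
    if label is None:
        label = f"{a.label}-{b.label}@{t:g}"
    lerp = lambda u, v: (1 - t) * u + t * v
    modules = tuple(
        (c, amp * (1 - t), w) for c, amp, w in a.modules
    ) + tuple((c, amp * t, w) for c, amp, w in b.modules)
    return SpeciesTemplate(
        label=label,
        l2m=lerp(a.l2m, b.l2m),
        e_index=round(lerp(a.e_index, b.e_index)),
        plateau_depth=lerp(a.plateau_depth, b.plateau_depth),
        tip_sharpness=lerp(a.tip_sharpness, b.tip_sharpness),
        basal_height=lerp(a.basal_height, b.basal_height),
        roundness=lerp(a.roundness, b.roundness),
        breasting=lerp(a.breasting, b.breasting),
        modules=modules,
        noise_sd=lerp(a.noise_sd, b.noise_sd),
        vr=lerp(a.vr, b.vr),
        chi_frac=lerp(a.chi_frac, b.chi_frac),
        cli_frac=lerp(a.cli_frac, b.cli_frac),
        w=lerp(a.w, b.w),
        kerf=lerp(a.kerf, b.kerf),
        thick=lerp(a.thick, b.thick),
        alpha=lerp(a.alpha, b.alpha),
        transit_t=t,
    )


# --- SPD-space planted community ------------------------------------------

def _orthonormal_directions(dim: int, k: int = 4) -> np.ndarray:
    """k fixed orthonormal diagonal-log directions (Gram-Schmidt of simple
    deterministic patterns), shared by every seed."""
    s = np.arange(dim, dtype=float)
    raw = np.stack(
        [
            np.ones(dim),
            np.where(s % 2 == 0, 1.0, -1.0),
            np.where(s < dim / 2, 1.0, -1.0),
            np.sin(2 * np.pi * (s + 0.5) / dim),
        ]
    )[:k]
    q, _ = np.linalg.qr(raw.T)
    return q.T  # (k, dim), orthonormal rows


def _noisy_omega(
    centre_log: np.ndarray, tau: float, rng: np.random.Generator, sample_id: str, n: int
) -> OmegaMatrix:
    dim = centre_log.size
    t_sqrt = np.diag(np.exp(centre_log / 2.0))
    g = rng.normal(0.0, tau, size=(dim, dim))
    e = (g + g.T) / 2.0
    mat = t_sqrt @ spd_exp(e) @ t_sqrt
    return OmegaMatrix(
        sample_id=sample_id,
        matrix=(mat + mat.T) / 2.0,
        n=n,
        stations=tuple(range(2, dim + 2)),
    )


def spd_community(
    seed: int = 0, dim: int = 17, tau: float = 0.02, n_nominal: int = 20
) -> tuple[dict[str, OmegaMatrix], list[tuple[OmegaMatrix, OmegaMatrix]], dict]:
    """Plant a six-taxon community directly on the SPD manifold.

    Taxa A..F have commuting (diagonal-log) centres, so planted geodesics
    are exact log-space segments: A and B are the most separated pair
    with C exactly at the geodesic midpoint; D and E are a second,
    closer pair offset well away from the A–B geodesic; F sits off every
    planted geodesic by several critical radii's worth — a singleton.
    Cohort sampling adds symmetric tangent noise of scale ``tau``;
    replicate cohort pairs are generated for C and F (calibrating
    dsigma), whose consensus matrices enter the analysis set.

    Returns ``(omegas, replicate_pairs, truth)`` where ``truth`` is the
    planted partition.
    """
    rng = np.random.default_rng(seed)
    u = _orthonormal_directions(dim)
    # one critical radius ≈ 1.645 × E‖E1 − E2‖_F for tangent noise of scale tau
    c_unit = 1.645 * tau * math.sqrt(dim * (dim + 1))
    coords = {
        "A": np.zeros(4),
        "B": np.array([10.0, 0.0, 0.0, 0.0]),
        "C": np.array([5.0, 0.0, 0.0, 0.0]),
        "D": np.array([5.0, 3.5, 0.0, 0.0]),
        "E": np.array([5.0, 3.5, 4.0, 0.0]),
        "F": np.array([5.0, 3.5, 2.0, 2.6]),
    }
    logs = {lab: c_unit * (coef @ u) for lab, coef in coords.items()}
    omegas: dict[str, OmegaMatrix] = {}
    replicate_pairs: list[tuple[OmegaMatrix, OmegaMatrix]] = []
    for lab in ("A", "B", "D", "E"):
        omegas[lab] = _noisy_omega(logs[lab], tau, rng, lab, n_nominal)
    for lab in ("C", "F"):
        rep = (
            _noisy_omega(logs[lab], tau, rng, f"{lab}~1", n_nominal),
            _noisy_omega(logs[lab], tau, rng, f"{lab}~2", n_nominal),
        )
        replicate_pairs.append(rep)
        omegas[lab] = consensus_omega(list(rep), sample_id=lab)
    truth = {
        "paths": [
            {"endpoints": ["A", "B"], "members": ["C"]},
            {"endpoints": ["D", "E"], "members": []},
        ],
        "singletons": ["F"],
        "member_t": {"C": 0.5},
        "tau": tau,
        "critical_unit": c_unit,
    }
    return omegas, replicate_pairs, truth
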
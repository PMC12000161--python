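"""Slope angles and the multi-scale quadratic-contrast battery.

The mastication surface of the moveable digit is summarised by the 17
inter-station slope angles φ_i = atan((y_i − y_{i−1})/(x_i − x_{i−1})),
reported in degrees.  Twelve planned contrasts over the first nine φ
values (the tooth row, up to station 10) probe differentiated features at
three spatial scales:

* contrast ``a`` — overall "breasting" of the whole surface,
  coefficients (1, 1, 1, −2, −2, −2, 1, 1, 1) scaled by 1/√18;
* contrasts ``b1``–``b4`` — six-position local modules, rows of a banded
  (1, 1, −2, −2, 1, 1) matrix scaled by 1/√12;
* contrasts ``c1``–``c7`` — "atomic" second-difference features,
  rows (1, −2, 1) scaled by 1/√6.

Each contrast row sums to zero, so a constant added to every slope angle
leaves the scalar unchanged.  Sign convention: a *negative* scalar marks
an apparent peak (tooth), a *positive* scalar an apparent gullet.  The
contrasts are centred along the L2M axis at stations
(6, 4.5, 5.5, 6.5, 7.5, 3, 4, 5, 6, 7, 8, 9) respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profile_model import DigitProfile, MalformedProfileError, N_STATIONS

__all__ = [
    "SlopeVector",
    "ContrastBattery",
    "ContrastTable",
    "slope_angles",
    "build_battery",
    "apply_battery",
    "battery_table",
    "species_summary",
    "replicate_consistency",
    "smoothed_surface",
    "CONTRAST_LABELS",
    "CONTRAST_CENTRES",
]

CONTRAST_LABELS = ("a", "b1", "b2", "b3", "b4", "c1", "c2", "c3", "c4", "c5", "c6", "c7")
CONTRAST_CENTRES = (6.0, 4.5, 5.5, 6.5, 7.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)
N_TOOTH_ROW = 9  # contrasts consume the first nine slope angles (stations 2..10)


@dataclass(frozen=True)
class SlopeVector:
    """Slopes of one standardized profile: raw slopes ``g`` (17), angles
    ``phi`` in degrees (17), and slope differences ``c`` (16)."""

    taxon_id: str
    individual_id: str
    g: np.ndarray
    phi: np.ndarray
    c: np.ndarray


@dataclass(frozen=True)
class ContrastBattery:
    """The 12 labelled, scaled contrast rows with their L2M-axis centres."""

    labels: tuple[str, ...]
    coefficients: np.ndarray  # (12, 9), already scaled
    raw_coefficients: np.ndarray  # (12, 9), integer rows before scaling
    scales: np.ndarray  # (12,)
    centres: np.ndarray  # (12,)


@dataclass(frozen=True)
class ContrastTable:
    """Per-individual contrast scalars plus per-(taxon, contrast) summaries.

    ``individual`` has columns taxon, individual, contrast, centre, value;
    ``species`` has columns taxon, contrast, centre, mean, band, call, flags
    where call ∈ {peak, gullet, level} by the sign rule: peak iff
    mean < −band, gullet iff mean > +band, level otherwise.
    """

    individual: pd.DataFrame
    species: pd.DataFrame
    level: float = 0.95


def slope_angles(p: DigitProfile) -> SlopeVector:
    """Compute the 17 inter-station slopes and slope angles of a profile.

    Angles are positive where the profile rises towards the condyle and
    negative where it falls; a flat increment gives φ = 0°.
    """
    dx = np.diff(p.x)
    if np.any(dx == 0):
        raise MalformedProfileError("zero station spacing")
    g = np.diff(p.y) / dx
    phi = np.degrees(np.arctan(g))
    return SlopeVector(
        taxon_id=p.taxon_id,
        individual_id=p.individual_id,
        g=g,
        phi=phi,
        c=np.diff(g),
    )


def build_battery() -> ContrastBattery:
    """Assemble the 12-contrast battery (rows, scalings, centres)."""
    a = [[1, 1, 1, -2, -2, -2, 1, 1, 1]]
    b = [
        [1, 1, -2, -2, 1, 1, 0, 0, 0],
        [0, 1, 1, -2, -2, 1, 1, 0, 0],
        [0, 0, 1, 1, -2, -2, 1, 1, 0],
        [0, 0, 0, 1, 1, -2, -2, 1, 1],
    ]
    c = [
        [1 if j == k else (-2 if j == k + 1 else (1 if j == k + 2 else 0)) for j in range(9)]
        for k in range(7)
    ]
    raw = np.array(a + b + c, dtype=float)
    scales = np.array([1 / np.sqrt(18)] + [1 / np.sqrt(12)] * 4 + [1 / np.sqrt(6)] * 7)
    return ContrastBattery(
        labels=CONTRAST_LABELS,
        coefficients=raw * scales[:, None],
        raw_coefficients=raw,
        scales=scales,
        centres=np.array(CONTRAST_CENTRES),
    )


def apply_battery(
    s: SlopeVector, battery: ContrastBattery | None = None, e_index: int | None = None
) -> tuple[np.ndarray, bool]:
    """Apply the 12 contrasts to the first nine slope angles of one individual.

    Returns ``(scalars, valid)``.  ``valid`` is False when the supplied
    tooth-row end index falls before station 10, in which case the
    contrast inputs extend beyond the mastication surface and the
    comparison may be invalid (the values are still returned).
    """
    if battery is None:
        battery = build_battery()
    phi9 = s.phi[:N_TOOTH_ROW]
    scalars = battery.coefficients @ phi9
    valid = True if e_index is None else e_index >= N_TOOTH_ROW + 1
    return scalars, valid


def battery_table(
    profiles: list[DigitProfile],
    battery: ContrastBattery | None = None,
    e_indices: dict[tuple[str, str], int] | None = None,
) -> pd.DataFrame:
    """Tidy per-individual contrast values for a list of profiles."""
    if battery is None:
        battery = build_battery()
    rows = []
    for p in profiles:
        s = slope_angles(p)
        e = None if e_indices is None else e_indices.get((p.taxon_id, p.individual_id))
        scalars, valid = apply_battery(s, battery, e)
        for lab, centre, val in zip(battery.labels, battery.centres, scalars):
            rows.append(
                {
                    "taxon": p.taxon_id,
                    "individual": p.individual_id,
                    "contrast": lab,
                    "centre": centre,
                    "value": float(val),
                    "valid": valid,
                }
            )
    return pd.DataFrame(rows)


def _pooled_residual_sd(values: pd.DataFrame) -> tuple[float, int]:
    """One-way-ANOVA residual SD of contrast values across taxa.

    Returns ``(s_pooled, df)`` pooling within-taxon squared deviations
    over all taxa with at least two individuals.
    """
    ss = 0.0
    df = 0
    for _, grp in values.groupby("taxon"):
        v = grp["value"].to_numpy()
        if v.size >= 2:
            ss += float(np.sum((v - v.mean()) ** 2))
            df += v.size - 1
    if df == 0:
        return float("nan"), 0
    return float(np.sqrt(ss / df)), df


def species_summary(
    individual: pd.DataFrame,
    level: float = 0.95,
    per_taxon_bands: bool = False,
    bonferroni: bool = False,
) -> ContrastTable:
    """Per-(taxon, contrast) means, 95% null bands and peak/gullet calls.

    The null band is ± t(df, 1 − (1 − level)/2) · s / √n around zero,
    with ``s`` by default the pooled one-way-ANOVA residual SD per
    contrast across all taxa (a single grey zone per contrast); set
    ``per_taxon_bands`` for within-taxon SDs instead.  ``bonferroni``
    divides the test level by the 12 contrasts.  Calls follow the sign
    rule (negative mean beyond the band = peak, positive = gullet).
    Single-individual taxa get an undefined band and a flagged "level"
    call.
    """
    eff_level = 1 - (1 - level) / len(CONTRAST_LABELS) if bonferroni else level
    out = []
    for contrast, cgrp in individual.groupby("contrast", sort=False):
        s_pooled, df_pooled = _pooled_residual_sd(cgrp)
        centre = float(cgrp["centre"].iloc[0])
        for taxon, tgrp in cgrp.groupby("taxon"):
            v = tgrp["value"].to_numpy()
            n = v.size
            mean = float(v.mean())
            flags = []
            if not tgrp["valid"].all():
                flags.append("short_tooth_row")
            if per_taxon_bands:
                s, df = (float(v.std(ddof=1)), n - 1) if n >= 2 else (float("nan"), 0)
            else:
                s, df = s_pooled, df_pooled
            if n < 2 or df == 0 or not np.isfinite(s):
                band = float("nan")
                call = "level"
                flags.append("band_undefined")
            else:
                band = float(stats.t.ppf(1 - (1 - eff_level) / 2, df) * s / np.sqrt(n))
                if mean < -band:
                    call = "peak"
                elif mean > band:
                    call = "gullet"
                else:
                    call = "level"
            out.append(
                {
                    "taxon": taxon,
                    "contrast": contrast,
                    "centre": centre,
                    "mean": mean,
                    "band": band,
                    "n": n,
                    "call": call,
                    "flags": ";".join(flags),
                }
            )
    species = pd.DataFrame(out)
    return ContrastTable(individual=individual, species=species, level=level)


def replicate_consistency(
    table: ContrastTable, replicate_pairs: list[tuple[str, str]]
) -> dict[str, list[tuple[str, str]]]:
    """Flag contrasts whose replicate samples call opposite band sides.

    For each pair of independent samples of the same species, a contrast
    is flagged when the two samples' calls disagree in a sign-relevant
    way (peak vs gullet, or signal vs level).  Flagged contrasts signal
    that the null bands understate the true between-sample variation and
    should be discounted or widened by the analyst; no automatic
    inflation is applied.
    """
    sp = table.species.set_index(["taxon", "contrast"])
    known = set(table.species["taxon"])
    flags: dict[str, list[tuple[str, str]]] = {}
    for lab_a, lab_b in replicate_pairs:
        for lab in (lab_a, lab_b):
            if lab not in known:
                raise KeyError(f"unknown replicate sample label: {lab!r}")
        for contrast in CONTRAST_LABELS:
            call_a = sp.loc[(lab_a, contrast), "call"]
            call_b = sp.loc[(lab_b, contrast), "call"]
            if call_a != call_b:
                flags.setdefault(contrast, []).append((lab_a, lab_b))
    return flags


def smoothed_surface(table: ContrastTable) -> pd.DataFrame:
    """Two-point moving average of centre-ordered per-taxon contrast means.

    Contrast means are ordered by contrast centre along the L2M axis and
    smoothed pairwise; the cross-taxon average curve is appended under
    the taxon label ``"__average__"``.  Returned columns: taxon, centre
    (midpoint of the smoothed pair), value.
    """
    sp = table.species.sort_values(["taxon", "centre", "contrast"])
    rows = []
    for taxon, grp in sp.groupby("taxon"):
        centres = grp["centre"].to_numpy()
        means = grp["mean"].to_numpy()
        sm_c = (centres[:-1] + centres[1:]) / 2
        sm_v = (means[:-1] + means[1:]) / 2
        for cc, vv in zip(sm_c, sm_v):
            rows.append({"taxon": taxon, "centre": float(cc), "value": float(vv)})
    out = pd.DataFrame(rows)
    avg = out.groupby("centre", as_index=False)["value"].mean()
    avg.insert(0, "taxon", "__average__")
    return pd.concat([out, avg], ignore_index=True)
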
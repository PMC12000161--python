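"""Per-sample Ω matrices: averaged SSCP of projected profile heights.

A cohort of standardized profiles from one sample (one species, one
collection) is summarised as Ω = (1/n) Σ y yᵀ over the selected height
coordinates — by default stations 2..18, since the tip station is pinned
at zero and would make the matrix singular.  Ω is the symmetric
positive-definite object that the Riemannian transect machinery consumes.

SSCP is computed about zero, not about the cohort mean: the profiles are
already registered to a common origin and axis, so the raw cross-products
carry the mean shape as well as its variation.  A mean-centred variant is
available for sensitivity analysis (``centred=True``), as is the n−1
divisor (``ddof=1``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile_model import DigitProfile, N_STATIONS
from .spd import frechet_mean, geodesic_point

__all__ = ["OmegaMatrix", "RankDeficiencyError", "build_omega", "consensus_omega"]

JITTER_REL = 1e-8  # diagonal jitter, relative to trace/dim, applied on PD failure


class RankDeficiencyError(ValueError):
    """Cohort too small for a full-rank Ω at the requested dimension."""


@dataclass(frozen=True)
class OmegaMatrix:
    """A sample's Ω matrix (µm²) with its provenance.

    ``stations`` records which 1-based profile stations the coordinates
    correspond to; ``jitter`` is the diagonal jitter added to restore
    positive-definiteness (0.0 when none was needed).
    """

    sample_id: str
    matrix: np.ndarray
    n: int
    stations: tuple[int, ...]
    jitter: float = 0.0

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def _is_pd(m: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(m)
        return True
    except np.linalg.LinAlgError:
        return False


def build_omega(
    profiles: list[DigitProfile],
    sample_id: str | None = None,
    stations: tuple[int, ...] | None = None,
    centred: bool = False,
    ddof: int = 0,
) -> OmegaMatrix:
    """Build the av(SSCP) Ω matrix for one cohort of standardized profiles.

    Parameters
    ----------
    profiles:
        The cohort; all individuals of one sample.  Needs strictly more
        individuals than retained coordinates for full rank.
    stations:
        1-based station subset to retain; default 2..18 (the pinned tip
        is excluded).  Use a smaller subset when coordinates are
        linearly dependent.
    centred:
        Subtract the cohort mean height vector first (sensitivity
        option; default is SSCP about zero).
    ddof:
        0 for division by n (default), 1 for n−1.

    Raises
    ------
    RankDeficiencyError
        When n ≤ dim; reduce the station subset.
    """
    if stations is None:
        stations = tuple(range(2, N_STATIONS + 1))
    idx = np.array(stations, dtype=int) - 1
    y = np.stack([p.y[idx] for p in profiles])  # (n, dim)
    n, dim = y.shape
    if n <= dim:
        raise RankDeficiencyError(
            f"n = {n} individuals cannot support a full-rank {dim}x{dim} Omega; "
            f"use a station subset with fewer than {n} coordinates"
        )
    if centred:
        y = y - y.mean(axis=0)
    omega = (y.T @ y) / (n - ddof)
    omega = (omega + omega.T) / 2.0
    jitter = 0.0
    if not _is_pd(omega):
        jitter = JITTER_REL * np.trace(omega) / dim
        omega = omega + jitter * np.eye(dim)
    if sample_id is None:
        sample_id = profiles[0].taxon_id
    return OmegaMatrix(sample_id=sample_id, matrix=omega, n=n, stations=tuple(stations), jitter=jitter)


def consensus_omega(omegas: list[OmegaMatrix], sample_id: str | None = None) -> OmegaMatrix:
    """Riemannian (Fréchet) consensus of replicate Ω matrices.

    For two matrices this is the affine-invariant geodesic midpoint; for
    more, the Fréchet mean.  Inputs must share dimension and station
    subset.
    """
    if len(omegas) < 2:
        raise ValueError("consensus needs at least two Omega matrices")
    dims = {o.dim for o in omegas}
    if len(dims) != 1:
        raise ValueError(f"dimension mismatch across inputs: {sorted(dims)}")
    stations = {o.stations for o in omegas}
    if len(stations) != 1:
        raise ValueError("station subsets differ across inputs")
    if len(omegas) == 2:
        mat = geodesic_point(omegas[0].matrix, omegas[1].matrix, 0.5)
    else:
        mat, info = frechet_mean([o.matrix for o in omegas])
        if not info["converged"]:
            raise RuntimeError(f"Frechet mean did not converge: {info}")
    if sample_id is None:
        sample_id = " & ".join(o.sample_id for o in omegas) + " consensus"
    return OmegaMatrix(
        sample_id=sample_id,
        matrix=mat,
        n=sum(o.n for o in omegas),
        stations=omegas[0].stations,
    )
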
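"""The TRANSECT algorithm: geodesic transitional paths between taxa.

Given one Ω matrix per taxon (replicate samples first merged to a
consensus, with the raw replicates reserved for noise calibration), the
algorithm repeatedly:

1. selects the remaining pair of taxa at maximal affine-invariant
   distance as the endpoints of a candidate transitional path (this rule
   makes the extracted path lengths non-increasing);
2. builds the geodesic between them;
3. assigns every other remaining taxon whose distance to the geodesic is
   within the critical region (1.645 × dsigma, the one-sided 95% normal
   band on the replicate-sampling noise scale) to that transit;
4. removes endpoints and members from the pool.

Leftover taxa that never join a path are reported as singletons.  dsigma
is the mean Riemannian distance between independent replicate cohorts of
the same species.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .omega import OmegaMatrix
from .spd import GeodesicPath, geodesic, point_to_geodesic, relative_eigenvectors, spd_distance

__all__ = [
    "CRITICAL_MULTIPLIER",
    "TransectPath",
    "TransectResult",
    "calibrate_dsigma",
    "run_transect",
    "order_along_geodesic",
]

CRITICAL_MULTIPLIER = 1.645  # one-sided 95% standard-normal quantile


@dataclass(frozen=True)
class TransectPath:
    """One extracted transitional path.

    ``members`` maps on-transit taxon labels to their (distance, t*)
    pairs; ``rel_eigvals_ab``/``rel_eigvec_ab`` summarise the first
    relative eigenpair of endpoint B with respect to endpoint A (and
    ``*_ba`` the reverse direction).
    """

    endpoints: tuple[str, str]
    length: float
    members: dict[str, tuple[float, float]]
    rel_eigvals_ab: np.ndarray
    rel_eigvec_ab: np.ndarray
    rel_eigvals_ba: np.ndarray
    rel_eigvec_ba: np.ndarray
    geodesic: GeodesicPath | None = None


@dataclass(frozen=True)
class TransectResult:
    """Full output of a transect run over a set of taxa."""

    dsigma: float
    critical: float
    paths: list[TransectPath]
    singletons: list[str]
    tie_breaks: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dsigma": self.dsigma,
            "critical": self.critical,
            "paths": [
                {
                    "endpoints": list(p.endpoints),
                    "lengeodesic": p.length,
                    "members": {
                        lab: {"distance": d, "t_star": t}
                        for lab, (d, t) in p.members.items()
                    },
                }
                for p in self.paths
            ],
            "singletons": list(self.singletons),
        }

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, **kwargs)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def calibrate_dsigma(replicate_pairs: list[tuple[OmegaMatrix, OmegaMatrix]]) -> float:
    """Noise scale: mean inter-sample distance over replicate cohort pairs."""
    if not replicate_pairs:
        raise ValueError("no replicate pairs: dsigma cannot be calibrated")
    return float(np.mean([spd_distance(a.matrix, b.matrix) for a, b in replicate_pairs]))


def run_transect(
    omegas: dict[str, OmegaMatrix],
    critical: float,
    m: int = 201,
    keep_geodesics: bool = False,
) -> TransectResult:
    """Extract candidate transitional paths from a labelled Ω set.

    ``omegas`` maps taxon label → consensus Ω (replicates must already be
    merged).  ``critical`` is the membership radius, normally
    1.645 × dsigma.  Ties in the maximal pairwise distance break
    deterministically by lexicographic label order and are recorded in
    the result.
    """
    if len(omegas) < 2:
        raise ValueError("transect needs at least two taxa")
    remaining = sorted(omegas)
    # full pairwise distances once; taxa are removed from the pool as used
    dist = {
        (p, q): spd_distance(omegas[p].matrix, omegas[q].matrix)
        for i, p in enumerate(remaining)
        for q in remaining[i + 1 :]
    }
    paths: list[TransectPath] = []
    tie_breaks: list[tuple[str, str]] = []
    while len(remaining) >= 2:
        pairs = [(p, q) for i, p in enumerate(remaining) for q in remaining[i + 1 :]]
        dmax = max(dist[pq] for pq in pairs)
        # ties at floating precision break lexicographically
        candidates = sorted(pq for pq in pairs if dist[pq] >= dmax * (1 - 1e-12))
        pa, pb = candidates[0]
        if len(candidates) > 1:
            tie_breaks.append((pa, pb))
        path = geodesic(omegas[pa].matrix, omegas[pb].matrix, m=m)
        members: dict[str, tuple[float, float]] = {}
        for lab in remaining:
            if lab in (pa, pb):
                continue
            d, t = point_to_geodesic(omegas[lab].matrix, path)
            if d <= critical:
                members[lab] = (d, t)
        va, ua, _ = relative_eigenvectors(omegas[pa].matrix, omegas[pb].matrix)
        vb, ub, _ = relative_eigenvectors(omegas[pb].matrix, omegas[pa].matrix)
        paths.append(
            TransectPath(
                endpoints=(pa, pb),
                length=path.length,
                members=members,
                rel_eigvals_ab=va,
                rel_eigvec_ab=ua[:, 0],
                rel_eigvals_ba=vb,
                rel_eigvec_ba=ub[:, 0],
                geodesic=path if keep_geodesics else None,
            )
        )
        used = {pa, pb, *members}
        remaining = [lab for lab in remaining if lab not in used]
    return TransectResult(
        dsigma=critical / CRITICAL_MULTIPLIER if critical > 0 else 0.0,
        critical=critical,
        paths=paths,
        singletons=remaining,
        tie_breaks=tie_breaks,
    )


def order_along_geodesic(path: TransectPath) -> list[tuple[str, float]]:
    """Taxa of one path ordered by position along its geodesic.

    Endpoints sit at t = 0 and t = 1; on-transit members interleave at
    their nearest-point parameters t*.
    """
    entries = [(path.endpoints[0], 0.0), (path.endpoints[1], 1.0)]
    entries += [(lab, t) for lab, (_, t) in path.members.items()]
    return sorted(entries, key=lambda e: (e[1], e[0]))
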
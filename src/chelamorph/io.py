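"""Readers and writers for the package's text formats.

Profiles and chelal measures travel as UTF-8 CSV with a header row,
decimal points, lengths in µm and angles in degrees.  Station columns
are 1-based (``station_1`` is the tip) to match the anatomical numbering
x₁…x₁₈.  Ω and distance matrices are labelled square CSVs; transect
results are JSON (see :meth:`~chelamorph.transect.TransectResult.to_json`);
dendrograms export as Newick (:func:`~chelamorph.summaries.linkage_to_newick`).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .omega import OmegaMatrix
from .profile_model import ChelalMeasures, DigitProfile, N_STATIONS
from .summaries import DistanceMatrix

__all__ = [
    "ProfileParseError",
    "read_profiles",
    "write_profiles",
    "read_measures",
    "write_measures",
    "write_omega",
    "read_omega",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_contrast_table",
]

STATION_COLUMNS = [f"station_{i}" for i in range(1, N_STATIONS + 1)]
MEASURE_COLUMNS = [
    "L1U", "L2M", "CHI", "CLI", "W", "kerf", "thick",
    "alpha", "tip_angle", "distal_angle", "x_ie", "e_index",
]


class ProfileParseError(ValueError):
    """Structured parse failure, carrying the offending file line."""


def write_profiles(profiles: list[DigitProfile], path) -> None:
    """Write profiles as CSV: taxon_id, individual_id, l2m, station_1..18.

    Heights are written with Python's shortest round-trip float
    representation, so a write→read cycle reproduces them bit-exactly.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(["taxon_id", "individual_id", "l2m", *STATION_COLUMNS]) + "\n")
        for p in profiles:
            cells = [p.taxon_id, p.individual_id, repr(p.l2m)]
            cells += [repr(float(v)) for v in p.y]
            fh.write(",".join(cells) + "\n")


def read_profiles(path) -> list[DigitProfile]:
    """Read a profiles CSV back into standardized :class:`DigitProfile`\\ s.

    Stations are reconstructed as equally spaced on [0, l2m].  Missing
    columns, non-numeric cells and malformed rows raise
    :class:`ProfileParseError` naming the file line.
    """
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty profile file", stacklevel=2)
        return []
    missing = [c for c in ["taxon_id", "individual_id", "l2m", *STATION_COLUMNS] if c not in frame.columns]
    if missing:
        raise ProfileParseError(f"{path}: missing column(s) {missing}")
    out = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        line = pos + 2  # header is line 1
        try:
            l2m = float(row["l2m"])
            y = np.array([float(row[c]) for c in STATION_COLUMNS])
            x = np.linspace(0.0, l2m, N_STATIONS)
            out.append(
                DigitProfile(
                    taxon_id=str(row["taxon_id"]),
                    individual_id=str(row["individual_id"]),
                    x=x,
                    y=y,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ProfileParseError(f"{path}, line {line}: {exc}") from exc
    return out


def write_measures(measures: list[tuple[str, str, ChelalMeasures]], path) -> None:
    """Write (taxon_id, individual_id, measures) records as CSV."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(["taxon_id", "individual_id", *MEASURE_COLUMNS]) + "\n")
        for taxon, ind, m in measures:
            cells = [taxon, ind]
            for c in MEASURE_COLUMNS:
                v = getattr(m, c)
                cells.append(str(int(v)) if c == "e_index" else repr(float(v)))
            fh.write(",".join(cells) + "\n")


def read_measures(path) -> list[tuple[str, str, ChelalMeasures]]:
    """Read a measures CSV into (taxon_id, individual_id, measures) records."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty measures file", stacklevel=2)
        return []
    missing = [c for c in ["taxon_id", "individual_id", *MEASURE_COLUMNS] if c not in frame.columns]
    if missing:
        raise ProfileParseError(f"{path}: missing column(s) {missing}")
    out = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        try:
            kwargs = {c: float(row[c]) for c in MEASURE_COLUMNS if c != "e_index"}
            kwargs["e_index"] = int(row["e_index"])
            out.append((str(row["taxon_id"]), str(row["individual_id"]), ChelalMeasures(**kwargs)))
        except (TypeError, ValueError) as exc:
            raise ProfileParseError(f"{path}, line {pos + 2}: {exc}") from exc
    return out


def write_omega(omega: OmegaMatrix, path) -> None:
    """Serialize an Ω matrix as square CSV with a one-line metadata header."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        # sample_id goes last: it may contain spaces (e.g. consensus labels)
        fh.write(f"# dim={omega.dim} n={omega.n} "
                 f"stations={','.join(map(str, omega.stations))} "
                 f"sample_id={omega.sample_id}\n")
        pd.DataFrame(omega.matrix).to_csv(fh, index=False, header=False)


def read_omega(path) -> OmegaMatrix:
    """Read an Ω matrix written by :func:`write_omega`."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ProfileParseError(f"{path}: missing metadata header line")
        body = header[1:].strip()
        meta = dict(tok.split("=", 1) for tok in body.split(" sample_id=")[0].split())
        meta["sample_id"] = body.split(" sample_id=", 1)[1]
        mat = np.loadtxt(fh, delimiter=",", ndmin=2)
    return OmegaMatrix(
        sample_id=meta["sample_id"],
        matrix=mat,
        n=int(meta["n"]),
        stations=tuple(int(s) for s in meta["stations"].split(",")),
    )


def write_distance_matrix(d: DistanceMatrix, path) -> None:
    d.to_frame().to_csv(path)


def read_distance_matrix(path) -> DistanceMatrix:
    frame = pd.read_csv(path, index_col=0)
    return DistanceMatrix(labels=tuple(frame.columns), values=frame.to_numpy(dtype=float))


def write_contrast_table(species_frame: pd.DataFrame, path) -> None:
    """Write the tidy per-(taxon, contrast) summary (mean, band, call, flags)."""
    cols = ["taxon", "contrast", "centre", "mean", "band", "n", "call", "flags"]
    species_frame[cols].to_csv(path, index=False)
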
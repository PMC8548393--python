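"""CSV dialects and atomic file writing for the pipeline artifacts.

All tables are UTF-8 CSV with a mandatory header row and "." as decimal
separator.  Species codes are ordered lexicographically wherever a table is
written.  Writers go through a temp-file-then-rename so a crashed run never
leaves a truncated artifact behind.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .persistence import PersistenceRecord
from .ricker import CommunityParams
from .synthetic import neighbor_columns


def _atomic_write(path: Path, writer) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    os.close(fd)
    try:
        writer(tmp)
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    _atomic_write(Path(path), lambda tmp: df.to_csv(tmp, index=index))


def write_json(obj, path: Path) -> None:
    _atomic_write(
        Path(path),
        lambda tmp: Path(tmp).write_text(json.dumps(obj, indent=2, default=str)),
    )


# -- observations -----------------------------------------------------------

OBS_FIXED_COLUMNS = ["year", "plot", "subplot", "focal", "seeds"]


def write_observations(obs: pd.DataFrame, path: Path) -> None:
    write_csv(obs, path)


def read_observations(path: Path) -> pd.DataFrame:
    obs = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in OBS_FIXED_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"malformed observations header: missing columns {missing}")
    n_cols = [c for c in obs.columns if c.startswith("n_")]
    if not n_cols:
        raise ValueError("malformed observations header: no neighbor-count columns")
    species = sorted(c[2:] for c in n_cols)
    unknown = set(obs["focal"].unique()) - set(species)
    if unknown:
        raise ValueError(f"unknown focal species code(s): {sorted(unknown)}")
    if (obs["seeds"] < 0).any():
        raise ValueError("negative seed counts in observation table")
    if obs[n_cols].lt(0).any().any():
        raise ValueError("negative neighbor counts in observation table")
    return obs


# -- interaction matrix and vital rates -------------------------------------


def write_alpha(alpha: np.ndarray, species: Iterable[str], path: Path) -> None:
    """Square matrix CSV: row = focal species i, column = neighbor j."""
    species = list(species)
    df = pd.DataFrame(np.asarray(alpha, dtype=float), index=species, columns=species)
    write_csv(df, path, index=True)


def read_alpha(path: Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"alpha matrix in {path} is not square: shape {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError(f"alpha matrix in {path}: row and column species differ")
    return df.to_numpy(dtype=float), [str(sp) for sp in df.columns]


def write_vitals(
    species: Iterable[str],
    log_lambda: np.ndarray,
    g: np.ndarray,
    s: np.ndarray,
    dispersion: np.ndarray,
    path: Path,
) -> None:
    df = pd.DataFrame(
        {
            "species": list(species),
            "log_lambda": np.asarray(log_lambda, dtype=float),
            "g": np.asarray(g, dtype=float),
            "s": np.asarray(s, dtype=float),
            "dispersion": np.asarray(dispersion, dtype=float),
        }
    )
    write_csv(df, path)


def read_vitals(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["species", "log_lambda", "g", "s", "dispersion"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"malformed vitals header: missing columns {missing}")
    return df


def write_params(params: CommunityParams, directory: Path, prefix: str = "") -> None:
    """One alpha.csv + vitals.csv pair for a fitted parameter set."""
    directory = Path(directory)
    write_alpha(params.alpha, params.species, directory / f"{prefix}alpha.csv")
    write_vitals(
        params.species,
        params.log_lambda,
        params.g,
        params.s,
        params.dispersion,
        directory / f"{prefix}vitals.csv",
    )


def read_params(
    directory: Path, year: object, plot: object, prefix: str = ""
) -> CommunityParams:
    directory = Path(directory)
    alpha, species = read_alpha(directory / f"{prefix}alpha.csv")
    vit = read_vitals(directory / f"{prefix}vitals.csv").set_index("species")
    if sorted(vit.index) != sorted(species):
        raise ValueError("vitals and alpha species lists differ")
    vit = vit.loc[species]
    return CommunityParams(
        year=year,
        plot=plot,
        species=tuple(species),
        log_lambda=vit["log_lambda"].to_numpy(),
        alpha=alpha,
        g=vit["g"].to_numpy(),
        s=vit["s"].to_numpy(),
        dispersion=vit["dispersion"].to_numpy(),
    )


# -- persistence records ----------------------------------------------------


def persistence_frame(
    records: Iterable[PersistenceRecord], parameterization: str
) -> pd.DataFrame:
    rows = [
        {
            "year": r.year,
            "plot": r.plot,
            "parameterization": parameterization,
            "species": r.species,
            "category": r.category,
            "witness_subset": ";".join(r.witness_subset),
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=["year", "plot", "parameterization", "species", "category", "witness_subset"],
    )


def read_persistence(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    expected = ["year", "plot", "parameterization", "species", "category", "witness_subset"]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"malformed persistence header: missing columns {missing}")
    return df


def records_from_frame(df: pd.DataFrame) -> list[PersistenceRecord]:
    return [
        PersistenceRecord(
            year=row.year,
            plot=row.plot,
            species=row.species,
            category=row.category,
            witness_subset=tuple(w for w in str(row.witness_subset).split(";") if w),
        )
        for row in df.itertuples()
    ]
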
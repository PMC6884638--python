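"""CSV serialization for kinetic datasets, conversion series and distributions.

Kinetic datasets are single-artifact CSV files: metadata travels in leading
``# key: value`` comment lines (M0_M, ratio, label, seed, replicate_id)
followed by a ``time_s,conversion`` table.  Round trips are lossless to
1e-12 (values are written with 17 significant digits).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import KineticDataset
from .model_core import InitialConditions
from .mwd import ChainLengthDistribution
from .simulate import ConversionSeries, Trajectory

__all__ = [
    "read_kinetic_csv",
    "write_kinetic_csv",
    "write_conversion_csv",
    "write_trajectory_csv",
    "write_distribution_csv",
]

_KNOWN_KEYS = {"M0_M", "ratio", "label", "seed", "replicate_id"}
_FLOAT_FMT = "%.17g"


def write_kinetic_csv(dataset: KineticDataset, path: str | Path) -> None:
    path = Path(path)
    lines = [
        f"# M0_M: {dataset.ic.M0!r}",
        f"# ratio: {dataset.ic.ratio!r}",
        f"# label: {dataset.label}",
    ]
    if dataset.replicate_id is not None:
        lines.append(f"# replicate_id: {dataset.replicate_id}")
    lines.append("time_s,conversion")
    for t, x in zip(dataset.times, dataset.conversion):
        lines.append(f"{t:.17g},{x:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_kinetic_csv(path: str | Path) -> KineticDataset:
    path = Path(path)
    meta: dict[str, str] = {}
    header_rows = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_rows += 1
            body = line[1:].strip()
            if ":" not in body:
                raise ValueError(f"malformed metadata line in {path}: {line!r}")
            key, _, value = body.partition(":")
            key = key.strip()
            if key not in _KNOWN_KEYS:
                raise ValueError(f"unknown metadata key {key!r} in {path}")
            meta[key] = value.strip()
    for required in ("M0_M", "ratio"):
        if required not in meta:
            raise ValueError(f"{path} is missing required metadata key {required!r}")
    df = pd.read_csv(path, skiprows=header_rows)
    for col in ("time_s", "conversion"):
        if col not in df.columns:
            raise ValueError(f"{path} is missing column {col!r}")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")
    ic = InitialConditions.from_ratio(float(meta["M0_M"]), float(meta["ratio"]))
    rep = int(meta["replicate_id"]) if "replicate_id" in meta else None
    return KineticDataset(
        times=times,
        conversion=df["conversion"].to_numpy(dtype=float),
        ic=ic,
        label=meta.get("label", ""),
        replicate_id=rep,
    )


def write_conversion_csv(series: ConversionSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": series.times, "conversion": series.conversion}
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Tidy long format: time_s, species (M / P<i> / C<i>), value (mol/L)."""
    net = traj.network
    names = (
        ["M"]
        + [f"P{i}" for i in range(net.n_P)]
        + [f"C{i}" for i in range(net.params.s, net.params.s + net.n_C)]
    )
    n_t = traj.times.size
    df = pd.DataFrame(
        {
            "time_s": np.repeat(traj.times, len(names)),
            "species": names * n_t,
            "value": traj.Y.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_distribution_csv(cld: ChainLengthDistribution, path: str | Path) -> None:
    pd.DataFrame(
        {
            "dp": cld.dp,
            "conc": cld.conc,
            "mass_fraction": cld.mass_fractions(),
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
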
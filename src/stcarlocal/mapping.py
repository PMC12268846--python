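"""Posterior relative-risk surfaces, cluster maps, rankings and export.

The fitted relative risk theta_ij compares each area-time unit's disease
rate to the overall study-wide rate; values above 1 flag elevated risk.
Alongside the usual posterior summaries this module reports, per cell, the
modal cluster label ("localized structure") and the exceedance probability
Pr(theta > 1) -- a standard disease-mapping output for flagging areas of
credible excess risk.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import StudyFrame
from .model import PosteriorSamples
from .selection import _modal_labels

__all__ = [
    "RiskSurface",
    "posterior_risk",
    "rank_areas",
    "cluster_size_table",
    "export_surface",
]


@dataclass
class RiskSurface:
    """Posterior relative-risk summaries and cluster labels per (area, time)."""

    area_ids: list[str]
    time_ids: list[str]
    rr_mean: np.ndarray      # (N, J)
    rr_median: np.ndarray
    rr_lo: np.ndarray        # 2.5%
    rr_hi: np.ndarray        # 97.5%
    ls: np.ndarray           # modal cluster label, int
    exceedance: np.ndarray   # Pr(theta > 1)

    def __post_init__(self) -> None:
        for arr in (self.rr_mean, self.rr_median, self.rr_lo, self.rr_hi):
            if np.any(np.asarray(arr) <= 0):
                raise ValueError("relative-risk summaries must be positive")
        if np.any((self.exceedance < 0) | (self.exceedance > 1)):
            raise ValueError("exceedance probabilities must lie in [0, 1]")

    @property
    def G(self) -> int:
        return int(self.ls.max())

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.area_ids):
            for j, t in enumerate(self.time_ids):
                rows.append(
                    {
                        "area": a,
                        "time": t,
                        "rr_mean": self.rr_mean[i, j],
                        "rr_median": self.rr_median[i, j],
                        "rr_lo": self.rr_lo[i, j],
                        "rr_hi": self.rr_hi[i, j],
                        "ls": int(self.ls[i, j]),
                        "exceedance": self.exceedance[i, j],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "RiskSurface":
        """Build a surface from a long table with columns area, time, rr [, ls].

        Point estimates from an external source (e.g. published tables) are
        used for all summaries; credible bounds collapse onto the point
        value and exceedance is the indicator rr > 1.
        """
        areas = sorted(df["area"].astype(str).unique())
        times = sorted(df["time"].astype(str).unique())
        N, J = len(areas), len(times)
        rr = np.full((N, J), np.nan)
        ls = np.ones((N, J), dtype=int)
        idx = df.assign(
            area=df["area"].astype(str), time=df["time"].astype(str)
        ).set_index(["area", "time"])
        for i, a in enumerate(areas):
            for j, t in enumerate(times):
                row = idx.loc[(a, t)]
                rr[i, j] = float(row["rr"])
                if "ls" in df.columns:
                    ls[i, j] = int(row["ls"])
        if np.any(~np.isfinite(rr)):
            raise ValueError("missing rr cells in table")
        return cls(
            areas, times, rr.copy(), rr.copy(), rr.copy(), rr.copy(),
            ls, (rr > 1).astype(float),
        )


def posterior_risk(samples: PosteriorSamples) -> RiskSurface:
    """Summarize the fitted relative-risk chains into a :class:`RiskSurface`.

    Per cell: posterior mean, median and central 95% interval of theta;
    the modal sampled cluster label (ties towards the smaller label); and
    the exceedance probability Pr(theta > 1).
    """
    if samples.S < 1:
        raise ValueError("no stored samples")
    th = samples.theta
    lo, med, hi = np.quantile(th, [0.025, 0.5, 0.975], axis=0)
    G = samples.lam.shape[1]
    return RiskSurface(
        list(samples.area_ids),
        list(samples.time_ids),
        th.mean(axis=0),
        med,
        lo,
        hi,
        _modal_labels(samples.Z, G),
        (th > 1.0).mean(axis=0),
    )


def rank_areas(
    surface: RiskSurface,
    time: str,
    k: int = 3,
    summary: str = "median",
) -> list[tuple[str, float]]:
    """Top-k areas by relative risk at one time point, descending.

    ``summary`` selects the point estimate ("median" by default, "mean"
    also available).  Ties are broken alphabetically by area label, so
    equal risks rank deterministically.
    """
    if time not in surface.time_ids:
        raise KeyError(f"unknown time label {time!r}")
    j = surface.time_ids.index(time)
    vals = {"median": surface.rr_median, "mean": surface.rr_mean}[summary][:, j]
    if k > len(surface.area_ids):
        warnings.warn(
            f"k={k} exceeds the number of areas ({len(surface.area_ids)}); truncating",
            stacklevel=2,
        )
        k = len(surface.area_ids)
    order = sorted(
        range(len(surface.area_ids)),
        key=lambda i: (-vals[i], surface.area_ids[i]),
    )
    return [(surface.area_ids[i], float(vals[i])) for i in order[:k]]


def cluster_size_table(surface: RiskSurface, G: int | None = None) -> np.ndarray:
    """Number of (area, time) cells carrying each modal label; sums to N*J."""
    G = G or surface.G
    if surface.ls.min() < 1 or surface.ls.max() > G:
        raise ValueError("labels out of range 1..G")
    return np.bincount(surface.ls.reshape(-1), minlength=G + 1)[1:]


def export_surface(
    surface: RiskSurface,
    out_dir: str | Path,
    geojson: str | Path | None = None,
) -> list[Path]:
    """Write the surface as long-format CSV, optionally joined onto a GeoJSON.

    When a GeoJSON feature collection is supplied, each feature must carry
    an ``area`` property matching a surface area label; per-time rr/ls/
    exceedance values are added to its properties and a choropleth-ready
    ``surface.geojson`` is written next to the CSV.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    csv_path = out / "surface.csv"
    surface.to_long().to_csv(csv_path, index=False)
    written.append(csv_path)
    if geojson is not None:
        gj = json.loads(Path(geojson).read_text())
        feat_areas = [
            str(f.get("properties", {}).get("area")) for f in gj.get("features", [])
        ]
        missing = sorted(set(surface.area_ids) - set(feat_areas))
        if missing:
            raise ValueError(f"GeoJSON lacks features for areas: {missing}")
        long = surface.to_long().set_index(["area", "time"])
        for f in gj["features"]:
            a = str(f["properties"]["area"])
            for t in surface.time_ids:
                row = long.loc[(a, t)]
                f["properties"][f"rr_{t}"] = float(row["rr_median"])
                f["properties"][f"ls_{t}"] = int(row["ls"])
                f["properties"][f"exceedance_{t}"] = float(row["exceedance"])
        gj_path = out / "surface.geojson"
        gj_path.write_text(json.dumps(gj))
        written.append(gj_path)
    return written
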
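"""Reading, validation and preprocessing of area-time count panels.

The package works on a complete N x J panel of disease counts: for every
area i and time point j we need the observed case count ``y_ij``, the
population at risk ``n_ij`` and (optionally) covariate values ``x_ij``.
Spatial structure enters through a binary adjacency relation among the N
areas, read either from a GAL spatial-weights file or from an edge list.

Expected counts ``E_ij`` -- the Poisson offsets of the disease-mapping
model -- are derived by applying the overall study-wide incidence rate to
each local at-risk population, so that the expected counts sum exactly to
the observed total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


class PanelIncompleteError(ValueError):
    """Raised when the area x time panel has missing cells."""


class ValidationError(ValueError):
    """Raised when input data violate a structural requirement."""


@dataclass
class StudyFrame:
    """A complete area x time panel of counts, at-risk totals and covariates.

    Attributes
    ----------
    area_ids : list of str
        Ordered area labels (length N).  All matrices in the package use
        this single canonical ordering.
    time_ids : list of str
        Ordered time labels (length J).
    y : ndarray of shape (N, J)
        Observed case counts.
    n : ndarray of shape (N, J)
        Population at risk (positive integers).
    X : ndarray of shape (N, J, p)
        Covariate values; ``p`` may be zero.
    covariates : list of str
        Covariate names (length p).
    E : ndarray of shape (N, J) or None
        Expected counts under the overall rate; populated by
        :func:`compute_expected_counts`.
    """

    area_ids: list[str]
    time_ids: list[str]
    y: np.ndarray
    n: np.ndarray
    X: np.ndarray
    covariates: list[str] = field(default_factory=list)
    E: np.ndarray | None = None

    @property
    def N(self) -> int:
        return len(self.area_ids)

    @property
    def J(self) -> int:
        return len(self.time_ids)

    @property
    def p(self) -> int:
        return len(self.covariates)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        self.n = np.asarray(self.n)
        N, J = self.N, self.J
        if self.y.shape != (N, J) or self.n.shape != (N, J):
            raise ValidationError(
                f"y and n must have shape ({N}, {J}); got {self.y.shape} and {self.n.shape}"
            )
        self.X = np.asarray(self.X, dtype=float).reshape(N, J, self.p)
        if np.any(self.y < 0):
            raise ValidationError("negative counts in y")
        if np.any(self.n <= 0):
            raise ValidationError("non-positive at-risk totals in n")
        bad = np.argwhere(self.y > self.n)
        if bad.size:
            i, j = bad[0]
            raise ValidationError(
                f"y > n at area {self.area_ids[i]!r}, time {self.time_ids[j]!r}"
            )

    def select_covariates(self, names: Sequence[str]) -> "StudyFrame":
        """Return a copy restricted to the given covariates (possibly none)."""
        idx = [self.covariates.index(nm) for nm in names]
        return replace(
            self, X=self.X[:, :, idx].copy(), covariates=list(names),
            E=None if self.E is None else self.E.copy(),
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format DataFrame with columns area, time, y, n, covariates[, E]."""
        rows = []
        for i, a in enumerate(self.area_ids):
            for j, t in enumerate(self.time_ids):
                row = {"area": a, "time": t, "y": self.y[i, j], "n": self.n[i, j]}
                for c, nm in enumerate(self.covariates):
                    row[nm] = self.X[i, j, c]
                if self.E is not None:
                    row["E"] = self.E[i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_long().to_csv(path, index=False)


@dataclass
class AdjacencyGraph:
    """Symmetric binary neighbourhood structure among areas.

    ``W`` is the N x N 0/1 adjacency matrix with zero diagonal; ``degree``
    gives per-area neighbour counts.  Areas without neighbours (islands)
    are rejected because the intrinsic CAR prior is undefined for them.
    """

    area_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        W = np.asarray(self.W)
        N = len(self.area_ids)
        if W.shape != (N, N):
            raise ValidationError(f"W must be {N}x{N}, got {W.shape}")
        if np.any(np.diag(W) != 0):
            raise ValidationError("W has non-zero diagonal entries")
        if not np.array_equal(W, W.T):
            raise ValidationError("W is not symmetric")
        if not np.all(np.isin(W, (0, 1))):
            raise ValidationError("W must be binary")
        deg = W.sum(axis=1)
        islands = [self.area_ids[i] for i in np.flatnonzero(deg == 0)]
        if islands:
            raise ValidationError(f"island areas with no neighbours: {islands}")
        self.W = W.astype(np.int8)
        if not self._connected():
            warnings.warn("adjacency graph is not connected", stacklevel=2)

    def _connected(self) -> bool:
        import networkx as nx

        return nx.is_connected(nx.from_numpy_array(self.W.astype(int)))

    @property
    def N(self) -> int:
        return len(self.area_ids)

    @property
    def degree(self) -> np.ndarray:
        return self.W.sum(axis=1).astype(int)

    @property
    def Q(self) -> np.ndarray:
        """Intrinsic CAR precision Q = D - W (singular, rank N-1 if connected)."""
        if not hasattr(self, "_Q"):
            self._Q = np.diag(self.degree).astype(float) - self.W.astype(float)
        return self._Q

    def write_gal(self, path: str | Path) -> None:
        lines = [f"0 {self.N} areas area"]
        for i, a in enumerate(self.area_ids):
            nbrs = [self.area_ids[k] for k in np.flatnonzero(self.W[i])]
            lines.append(f"{a} {len(nbrs)}")
            lines.append(" ".join(nbrs))
        Path(path).write_text("\n".join(lines) + "\n")


def read_study_frame(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    covariates: Sequence[str] | None = None,
    area_order: Sequence[str] | None = None,
    time_order: Sequence[str] | None = None,
) -> StudyFrame:
    """Read an area-time count table from CSV into a :class:`StudyFrame`.

    The file must contain one row per (area, time) cell with columns for the
    area label, time label, observed count and at-risk total; every remaining
    column is treated as a covariate unless ``covariates`` restricts the set.
    ``schema`` remaps non-default column names, e.g.
    ``{"area": "province", "y": "cases"}``.

    Orderings are deterministic: lexicographic by label unless an explicit
    ``area_order`` / ``time_order`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = {"area": "area", "time": "time", "y": "y", "n": "n"}
    if schema:
        cols.update(schema)
    df = pd.read_csv(path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})
    df["area"] = df["area"].astype(str)
    df["time"] = df["time"].astype(str)

    reserved = {"area", "time", "y", "n", "E"}
    cov_names = (
        list(covariates)
        if covariates is not None
        else [c for c in df.columns if c not in reserved]
    )
    area_ids = list(area_order) if area_order else sorted(df["area"].unique())
    time_ids = list(time_order) if time_order else sorted(df["time"].unique())

    idx = df.set_index(["area", "time"])
    if idx.index.has_duplicates:
        dup = idx.index[idx.index.duplicated()][0]
        raise ValidationError(f"duplicate cell for (area, time) = {dup}")
    N, J = len(area_ids), len(time_ids)
    y = np.zeros((N, J), dtype=np.int64)
    n = np.zeros((N, J), dtype=np.int64)
    X = np.zeros((N, J, len(cov_names)))
    for i, a in enumerate(area_ids):
        for j, t in enumerate(time_ids):
            try:
                row = idx.loc[(a, t)]
            except KeyError:
                raise PanelIncompleteError(
                    f"panel incomplete: no row for (area={a!r}, time={t!r})"
                ) from None
            y[i, j] = int(row["y"])
            n[i, j] = int(row["n"])
            for c, nm in enumerate(cov_names):
                X[i, j, c] = float(row[nm])
    return StudyFrame(area_ids, time_ids, y, n, X, cov_names)


def _read_gal(path: Path) -> tuple[list[str], dict[str, set[str]]]:
    tokens_lines = [
        ln.strip() for ln in path.read_text().splitlines() if ln.strip()
    ]
    header = tokens_lines[0].split()
    # accepted dialects: "N" or "0 N <title> <areakey>"
    if len(header) == 1:
        n_areas = int(header[0])
    else:
        n_areas = int(header[1])
    nbrs: dict[str, set[str]] = {}
    order: list[str] = []
    k = 1
    while k < len(tokens_lines):
        name, cnt = tokens_lines[k].split()[:2]
        cnt = int(cnt)
        neigh = tokens_lines[k + 1].split() if cnt > 0 else []
        if len(neigh) != cnt:
            raise ValidationError(
                f"GAL record for {name!r} announces {cnt} neighbours, lists {len(neigh)}"
            )
        nbrs[name] = set(neigh)
        order.append(name)
        k += 2 if cnt > 0 else 2
    if len(order) != n_areas:
        raise ValidationError(
            f"GAL header announces {n_areas} areas, file lists {len(order)}"
        )
    return order, nbrs


def read_adjacency(
    path: str | Path, area_ids: Sequence[str] | None = None
) -> AdjacencyGraph:
    """Read spatial adjacency from a GAL weights file or a 2-column edge list.

    Files ending in ``.gal`` are parsed as GAL; anything else is read as a
    CSV edge list (two columns of area labels, with or without a header).
    Asymmetric input is symmetrized with a warning.  When ``area_ids`` is
    given, labels are checked against it and the matrix uses its ordering;
    otherwise areas are ordered lexicographically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".gal":
        order, nbrs = _read_gal(path)
        pairs = [(a, b) for a, bs in nbrs.items() for b in bs]
        seen = list(order)
    else:
        df = pd.read_csv(path, header=None, dtype=str)
        first = df.iloc[0]
        # tolerate a header row such as "from,to"
        if {str(first[0]).lower(), str(first[1]).lower()} & {"from", "to", "source", "target", "area1", "area2"}:
            df = df.iloc[1:]
        pairs = [(str(a), str(b)) for a, b in zip(df[0], df[1])]
        seen = sorted({x for p in pairs for x in p})

    if area_ids is not None:
        unknown = sorted({x for p in pairs for x in p} - set(area_ids))
        if unknown:
            raise ValidationError(f"unknown area labels in adjacency: {unknown}")
        labels = list(area_ids)
    else:
        labels = sorted(seen)
    pos = {a: i for i, a in enumerate(labels)}
    N = len(labels)
    W = np.zeros((N, N), dtype=np.int8)
    for a, b in pairs:
        if a == b:
            raise ValidationError(f"self-neighbour for area {a!r}")
        W[pos[a], pos[b]] = 1
    if not np.array_equal(W, W.T):
        warnings.warn(
            "adjacency input is asymmetric; symmetrizing (an edge in either "
            "direction counts as a neighbour pair)",
            stacklevel=2,
        )
        W = np.maximum(W, W.T)
    return AdjacencyGraph(labels, W)


def compute_expected_counts(frame: StudyFrame) -> StudyFrame:
    """Populate expected counts E_ij = (sum y / sum n) * n_ij.

    The overall incidence rate across all areas and times is applied to each
    local at-risk total, so the expected counts conserve the observed total:
    sum(E) == sum(y) exactly (up to floating point).
    """
    total_n = frame.n.sum()
    if total_n <= 0:
        raise ValidationError("degenerate input: total at-risk population is zero")
    rate = frame.y.sum() / total_n
    E = rate * frame.n.astype(float)
    return replace(frame, E=E)


def spearman_screen(
    X: StudyFrame | pd.DataFrame,
    threshold: float = 0.5,
) -> tuple[list[str], list[str], pd.DataFrame]:
    """Screen covariates for collinearity by pairwise Spearman correlation.

    All (area, time) cells are pooled as observations.  Covariates are then
    removed greedily: while any pair of retained covariates has |rho| above
    ``threshold``, drop the covariate participating in the most
    super-threshold pairs; ties are broken towards the covariate with the
    larger maximum |rho| among those pairs, then towards the larger column
    index.  Constant covariates, for which rank correlation is undefined,
    are excluded up front with a warning.

    Returns ``(kept, dropped, table)`` where ``table`` lists every pair with
    its rho and whether both members survived.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if isinstance(X, StudyFrame):
        names = list(X.covariates)
        data = X.X.reshape(-1, X.p)
    else:
        names = list(X.columns)
        data = X.to_numpy(dtype=float)
    if not names:
        raise ValueError("no covariates to screen")

    dropped: list[str] = []
    for c, nm in enumerate(names):
        if np.ptp(data[:, c]) == 0:
            warnings.warn(
                f"covariate {nm!r} is constant; rank correlation undefined; excluded",
                stacklevel=2,
            )
            dropped.append(nm)
    active = [nm for nm in names if nm not in dropped]

    p = len(names)
    rho = np.eye(p)
    for a in range(p):
        for b in range(a + 1, p):
            if names[a] in dropped or names[b] in dropped:
                r = np.nan
            else:
                r = stats.spearmanr(data[:, a], data[:, b]).statistic
            rho[a, b] = rho[b, a] = r

    def _super_pairs(active_names: list[str]) -> list[tuple[str, str, float]]:
        out = []
        for ia, a in enumerate(active_names):
            for b in active_names[ia + 1:]:
                r = rho[names.index(a), names.index(b)]
                if np.isfinite(r) and abs(r) > threshold:
                    out.append((a, b, abs(r)))
        return out

    while True:
        bad = _super_pairs(active)
        if not bad:
            break
        count: dict[str, int] = {nm: 0 for nm in active}
        maxr: dict[str, float] = {nm: 0.0 for nm in active}
        for a, b, r in bad:
            for nm in (a, b):
                count[nm] += 1
                maxr[nm] = max(maxr[nm], r)
        victim = max(
            active, key=lambda nm: (count[nm], maxr[nm], names.index(nm))
        )
        dropped.append(victim)
        active.remove(victim)

    records = []
    kept_set = set(active)
    for a in range(p):
        for b in range(a + 1, p):
            records.append(
                {
                    "cov_a": names[a],
                    "cov_b": names[b],
                    "rho": rho[a, b],
                    "both_kept": names[a] in kept_set and names[b] in kept_set,
                }
            )
    table = pd.DataFrame(records)
    return active, dropped, table
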
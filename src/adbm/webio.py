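"""Core data types for communities and predation matrices, plus text I/O.

A :class:`Community` is an ordered list of nodes with body masses in grams.
Communities are canonically sorted by non-decreasing mass (ties broken by
label) so that predation matrices always display with body size increasing
left to right and top to bottom.

A :class:`PredationMatrix` is an S x S binary matrix with rows as resources
and columns as consumers: entry (i, j) = 1 means consumer j eats resource i.
The diagonal is a legal place for links (cannibalism), and the number of
potential links is counted as S**2 throughout.

File formats are delimited text, comma- or tab-separated by extension
(``.csv`` -> comma, anything else -> tab):

* community table: columns ``node_id``, ``body_mass``;
* web matrix: node labels on the first row and column, cells 0/1;
* edge list: columns ``resource``, ``consumer``;
* link-frequency matrix: as the web matrix with real counts, preceded by a
  ``# n_webs = N`` header line.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError

__all__ = [
    "Community",
    "PredationMatrix",
    "LinkFrequency",
    "read_community",
    "write_community",
    "read_web",
    "write_web",
    "read_link_frequency",
    "write_link_frequency",
    "connectance",
]


def _sep_for(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


@dataclass(frozen=True)
class Community:
    """Ordered set of nodes with body masses (grams), sorted by mass.

    Parameters
    ----------
    node_ids
        Unique node labels, in canonical (mass-sorted) order.
    masses
        Strictly positive, finite body masses, same order as ``node_ids``.
    input_order
        Optional original label order of the source file, kept so output can
        round-trip in the order the user supplied.
    """

    node_ids: tuple[str, ...]
    masses: np.ndarray
    input_order: tuple[str, ...] | None = field(default=None, compare=False)

    def __post_init__(self):
        masses = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "masses", masses)
        object.__setattr__(self, "node_ids", tuple(str(n) for n in self.node_ids))
        if len(self.node_ids) != masses.size:
            raise FormatError("node_ids and masses must have equal length")
        if len(self.node_ids) < 2:
            raise FormatError("a community needs at least two nodes")
        if len(set(self.node_ids)) != len(self.node_ids):
            dupes = sorted({n for n in self.node_ids if self.node_ids.count(n) > 1})
            raise FormatError(f"duplicate node_id(s): {', '.join(dupes)}")
        bad = ~(np.isfinite(masses) & (masses > 0))
        if bad.any():
            name = self.node_ids[int(np.argmax(bad))]
            raise FormatError(f"non-positive or non-finite body mass for node {name!r}")
        order = sorted(range(masses.size), key=lambda i: (masses[i], self.node_ids[i]))
        if order != list(range(masses.size)):
            raise FormatError("Community must be constructed via Community.from_data")

    @classmethod
    def from_data(
        cls,
        node_ids: Sequence[str],
        masses: Sequence[float],
        input_order: Sequence[str] | None = None,
    ) -> "Community":
        """Build a community, sorting nodes by (mass, label)."""
        ids = [str(n) for n in node_ids]
        m = np.asarray(masses, dtype=float)
        if len(ids) != m.size:
            raise FormatError("node_ids and masses must have equal length")
        order = sorted(range(m.size), key=lambda i: (m[i], ids[i]))
        return cls(
            node_ids=tuple(ids[i] for i in order),
            masses=m[order],
            input_order=tuple(input_order) if input_order is not None else tuple(ids),
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Community)
            and self.node_ids == other.node_ids
            and np.array_equal(self.masses, other.masses)
        )

    @property
    def size(self) -> int:
        return len(self.node_ids)

    def index_of(self, label: str) -> int:
        try:
            return self.node_ids.index(label)
        except ValueError:
            raise FormatError(f"node {label!r} is not in the community") from None


@dataclass(frozen=True)
class PredationMatrix:
    """Binary S x S predation matrix: entry (i, j) = 1 if consumer j eats i."""

    community: Community
    links: np.ndarray

    def __post_init__(self):
        links = np.asarray(self.links)
        if links.ndim != 2 or links.shape[0] != links.shape[1]:
            raise FormatError("links must be a square matrix")
        if links.shape[0] != self.community.size:
            raise FormatError("matrix dimension does not match the community")
        if not np.isin(links, (0, 1)).all():
            raise FormatError("predation matrix entries must be 0 or 1")
        object.__setattr__(self, "links", links.astype(np.int8))

    @property
    def size(self) -> int:
        return self.community.size

    @property
    def n_links(self) -> int:
        return int(self.links.sum())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PredationMatrix)
            and self.community.node_ids == other.community.node_ids
            and np.array_equal(self.links, other.links)
        )


@dataclass(frozen=True)
class LinkFrequency:
    """Per-cell link counts aggregated over ``n_webs`` predicted webs."""

    community: Community
    counts: np.ndarray
    n_webs: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (self.community.size, self.community.size):
            raise FormatError("counts shape does not match the community")
        if self.n_webs < 1:
            raise FormatError("n_webs must be >= 1")
        if counts.min() < 0 or counts.max() > self.n_webs:
            raise FormatError("counts must lie in [0, n_webs]")
        object.__setattr__(self, "counts", counts)

    @property
    def proportions(self) -> np.ndarray:
        return self.counts / self.n_webs

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, LinkFrequency)
            and self.community.node_ids == other.community.node_ids
            and self.n_webs == other.n_webs
            and np.array_equal(self.counts, other.counts)
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_MASS_FACTORS = {"g": 1.0, "mg": 1e-3, "kg": 1e3}


def read_community(path: str | Path, mass_unit: str = "g") -> Community:
    """Read a community table with columns ``node_id`` and ``body_mass``.

    Masses are converted to grams according to ``mass_unit`` ("g", "mg" or
    "kg"). Nodes are returned in canonical mass-sorted order; the file order
    is retained for round-trip output.
    """
    if mass_unit not in _MASS_FACTORS:
        raise FormatError(f"unknown mass unit {mass_unit!r}; use one of {sorted(_MASS_FACTORS)}")
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"node_id": str})
    for col in ("node_id", "body_mass"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    ids = df["node_id"].tolist()
    masses = pd.to_numeric(df["body_mass"], errors="coerce").to_numpy(dtype=float)
    for row, (name, m) in enumerate(zip(ids, masses), start=2):
        if not np.isfinite(m) or m <= 0:
            raise FormatError(f"{path}: row {row}: non-positive body mass for node {name!r}")
    seen: set[str] = set()
    for row, name in enumerate(ids, start=2):
        if name in seen:
            raise FormatError(f"{path}: row {row}: duplicate node_id {name!r}")
        seen.add(name)
    return Community.from_data(ids, masses * _MASS_FACTORS[mass_unit], input_order=ids)


def write_community(community: Community, path: str | Path) -> None:
    """Write a community table, preserving the original file order if known."""
    order = community.input_order or community.node_ids
    idx = [community.index_of(n) for n in order]
    df = pd.DataFrame(
        {"node_id": [community.node_ids[i] for i in idx], "body_mass": community.masses[idx]}
    )
    df.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")


def read_web(
    path: str | Path, community: Community, dialect: str = "matrix"
) -> PredationMatrix:
    """Read an observed web as a labelled matrix or a resource→consumer edge list.

    The result is aligned to the community's mass-sorted order regardless of
    the order of labels in the file.
    """
    if dialect == "matrix":
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
        df.index = df.index.map(str)
        df.columns = df.columns.map(str)
        if set(df.index) != set(df.columns):
            raise FormatError(f"{path}: row and column label sets differ")
        unknown = set(df.index) - set(community.node_ids)
        if unknown:
            raise FormatError(f"{path}: label(s) not in community: {sorted(unknown)}")
        if set(df.index) != set(community.node_ids):
            missing = set(community.node_ids) - set(df.index)
            raise FormatError(f"{path}: community node(s) missing from matrix: {sorted(missing)}")
        aligned = df.loc[list(community.node_ids), list(community.node_ids)]
        vals = aligned.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise FormatError(f"{path}: non-binary cell in web matrix")
        return PredationMatrix(community, vals)
    if dialect == "edgelist":
        df = pd.read_csv(path, sep=_sep_for(path), dtype=str)
        for col in ("resource", "consumer"):
            if col not in df.columns:
                raise FormatError(f"{path}: missing required column {col!r}")
        links = np.zeros((community.size, community.size), dtype=np.int8)
        for _, row in df.iterrows():
            i = community.index_of(row["resource"])
            j = community.index_of(row["consumer"])
            links[i, j] = 1
        return PredationMatrix(community, links)
    raise FormatError(f"unknown dialect {dialect!r}; use 'matrix' or 'edgelist'")


def _matrix_frame(community: Community, values: np.ndarray) -> pd.DataFrame:
    labels = list(community.node_ids)
    return pd.DataFrame(values, index=labels, columns=labels)


def write_web(web: PredationMatrix, path: str | Path, dialect: str = "matrix") -> None:
    """Write a predation matrix; round-trips exactly through :func:`read_web`."""
    if dialect == "matrix":
        _matrix_frame(web.community, web.links).to_csv(
            path, sep=_sep_for(path), lineterminator="\n"
        )
        return
    if dialect == "edgelist":
        rows, cols = np.nonzero(web.links)
        df = pd.DataFrame(
            {
                "resource": [web.community.node_ids[i] for i in rows],
                "consumer": [web.community.node_ids[j] for j in cols],
            }
        )
        df.to_csv(path, sep=_sep_for(path), index=False, lineterminator="\n")
        return
    raise FormatError(f"unknown dialect {dialect!r}; use 'matrix' or 'edgelist'")


def write_link_frequency(freq: LinkFrequency, path: str | Path) -> None:
    buf = io.StringIO()
    buf.write(f"# n_webs = {freq.n_webs}\n")
    _matrix_frame(freq.community, freq.counts).to_csv(
        buf, sep=_sep_for(path), lineterminator="\n"
    )
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_link_frequency(path: str | Path, community: Community) -> LinkFrequency:
    text = Path(path).read_text(encoding="utf-8")
    first, _, rest = text.partition("\n")
    if not first.startswith("#") or "n_webs" not in first:
        raise FormatError(f"{path}: missing '# n_webs = N' header line")
    try:
        n_webs = int(first.split("=")[1])
    except (IndexError, ValueError):
        raise FormatError(f"{path}: malformed n_webs header {first!r}") from None
    df = pd.read_csv(io.StringIO(rest), sep=_sep_for(path), index_col=0)
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    if set(df.index) != set(community.node_ids) or set(df.columns) != set(community.node_ids):
        raise FormatError(f"{path}: labels do not match the community")
    aligned = df.loc[list(community.node_ids), list(community.node_ids)]
    return LinkFrequency(community, aligned.to_numpy(), n_webs)


def connectance(web: PredationMatrix) -> float:
    """Realized links divided by potential links, L / S**2 (diagonal counted)."""
    return web.n_links / web.size**2
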
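"""Dyadic association matrices from detection events.

Two matrices are built, following the gambit of the group at two spatial
scales:

* **cohabitation** — weight(i, j) = number of roost-days on which both
  tags were detected at an *entryway* antenna of the same roost
  ("frequency of cohabitation", in days);
* **intraroost** — weight(i, j) = number of distinct (roost-day,
  ceiling antenna, 5-minute bin) cells in which both tags were scanned
  ("time roosting together", in 5-minute units).

Entry scans are traversal events and never feed the intraroost matrix;
ceiling scans never feed the cohabitation matrix. Each matrix's node
list is every tag detected at least once *by that matrix's data
source*, so the two node sets legitimately differ. Both matrices are
symmetric with zero diagonal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import CEILING, ENTRY, AntennaRegistry, DetectionEvent, StudyWindow

BIN_SECONDS = 300
BINS_PER_DAY = 86400 // BIN_SECONDS  # 288


@dataclass(frozen=True)
class AssociationMatrix:
    """Symmetric non-negative integer dyadic matrix over an ordered node list."""

    nodes: tuple[str, ...]
    weights: np.ndarray
    kind: str  # "cohabitation" | "intraroost"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise ValueError("node list contains duplicates")
        if w.shape != (n, n):
            raise ValueError(f"weights shape {w.shape} does not match {n} nodes")
        if not np.array_equal(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def weight(self, a: str, b: str) -> int:
        return int(self.weights[self.nodes.index(a), self.nodes.index(b)])

    def is_binary(self) -> bool:
        return bool(np.isin(self.weights, (0, 1)).all())

    def reorder(self, nodes: Sequence[str]) -> "AssociationMatrix":
        """Same matrix over ``nodes``; nodes absent from self get zero rows."""
        idx = {t: i for i, t in enumerate(self.nodes)}
        n = len(nodes)
        out = np.zeros((n, n), dtype=self.weights.dtype)
        present = [(k, idx[t]) for k, t in enumerate(nodes) if t in idx]
        if present:
            ks, js = map(np.array, zip(*present))
            out[np.ix_(ks, ks)] = self.weights[np.ix_(js, js)]
        return AssociationMatrix(tuple(nodes), out, self.kind)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=list(self.nodes), columns=list(self.nodes))

    def to_csv(self, path: str | Path) -> None:
        """Square CSV with tag_id header row and column."""
        self.to_frame().to_csv(path, index_label="tag_id")

    @classmethod
    def read_csv(cls, path: str | Path, kind: str = "cohabitation") -> "AssociationMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls(tuple(df.index), df.to_numpy(dtype=int), kind)

    def to_edge_list(self) -> pd.DataFrame:
        """Long-format ``tag_a,tag_b,weight`` over nonzero upper-triangle dyads."""
        iu = np.triu_indices(self.n_nodes, k=1)
        rows = [
            (self.nodes[i], self.nodes[j], int(self.weights[i, j]))
            for i, j in zip(*iu)
            if self.weights[i, j] > 0
        ]
        return pd.DataFrame(rows, columns=["tag_a", "tag_b", "weight"])

    def dyad_vector(self) -> np.ndarray:
        """Upper-triangle weights as a flat vector of n(n-1)/2 dyads."""
        return self.weights[np.triu_indices(self.n_nodes, k=1)]


def daily_presence(
    events: Sequence[DetectionEvent],
    registry: AntennaRegistry,
    window: StudyWindow,
) -> pd.DataFrame:
    """Distinct (tag_id, roost_day, roost_id) triples from entry detections.

    A triple exists iff the tag has at least one scan at any entryway
    antenna of that roost on that roost-day; ceiling scans contribute
    nothing here.
    """
    entry = registry.antennas_with_role(ENTRY)
    triples = {
        (e.tag_id, window.roost_day(e.timestamp), registry.roost_of[e.antenna_id])
        for e in events
        if e.antenna_id in entry and window.contains(e.timestamp)
    }
    df = pd.DataFrame(sorted(triples), columns=["tag_id", "roost_day", "roost_id"])
    return df


def bin_detections(
    events: Sequence[DetectionEvent],
    registry: AntennaRegistry,
    window: StudyWindow,
) -> pd.DataFrame:
    """Distinct (tag_id, roost_day, antenna_id, bin_index) from ceiling scans.

    Bins are fixed clock-aligned 300-second windows anchored at roost-day
    midnight; bin_index runs 0..287. Many raw 4 Hz scans collapse to one
    occupancy triple per bin.
    """
    ceiling = registry.antennas_with_role(CEILING)
    quads = set()
    for e in events:
        if e.antenna_id not in ceiling or not window.contains(e.timestamp):
            continue
        day = window.roost_day(e.timestamp)
        secs = (e.timestamp - window.roost_day_midnight(e.timestamp)).total_seconds()
        quads.add((e.tag_id, day, e.antenna_id, int(secs // BIN_SECONDS)))
    return pd.DataFrame(
        sorted(quads), columns=["tag_id", "roost_day", "antenna_id", "bin_index"]
    )


def _co_occurrence_matrix(
    table: pd.DataFrame, group_cols: list[str], kind: str
) -> AssociationMatrix:
    """Count, per dyad, the distinct group cells containing both tags."""
    if table.empty:
        raise ValueError(f"cannot build a {kind} matrix from an empty table")
    nodes = tuple(sorted(table["tag_id"].unique()))
    idx = {t: i for i, t in enumerate(nodes)}
    n = len(nodes)
    w = np.zeros((n, n), dtype=int)
    for _, members in table.groupby(group_cols)["tag_id"]:
        present = sorted({idx[t] for t in members})
        for a, b in itertools.combinations(present, 2):
            w[a, b] += 1
            w[b, a] += 1
    return AssociationMatrix(nodes, w, kind)


def build_cohabitation(presence: pd.DataFrame) -> AssociationMatrix:
    """Cohabitation matrix: days each dyad shared a roost, via entryways.

    Node list is every tag with at least one presence triple — any bat
    detected at least once is part of the network, even if its row ends
    up all zero.
    """
    return _co_occurrence_matrix(presence, ["roost_day", "roost_id"], "cohabitation")


def build_intraroost(bins: pd.DataFrame) -> AssociationMatrix:
    """Intraroost matrix: shared 5-min bins at the same ceiling antenna."""
    return _co_occurrence_matrix(
        bins, ["roost_day", "antenna_id", "bin_index"], "intraroost"
    )


def dichotomize(m: AssociationMatrix, threshold: int = 1) -> AssociationMatrix:
    """Binary ties: 1 where weight >= threshold, else 0. Node list unchanged."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    return AssociationMatrix(m.nodes, (m.weights >= threshold).astype(int), m.kind)


def align_matrices(
    a: AssociationMatrix,
    b: AssociationMatrix,
    mode: Literal["union", "intersection"] = "union",
) -> tuple[AssociationMatrix, AssociationMatrix]:
    """Re-express both matrices over one shared, sorted node list.

    ``union`` pads nodes absent from one matrix with zero rows/columns
    (an undetected bat simply has no ties there); ``intersection``
    restricts to nodes present in both. Weights on shared dyads are
    preserved exactly.
    """
    if mode == "union":
        nodes = sorted(set(a.nodes) | set(b.nodes))
    elif mode == "intersection":
        nodes = sorted(set(a.nodes) & set(b.nodes))
        if not nodes:
            raise ValueError("intersection alignment with disjoint node sets")
    else:
        raise ValueError(f"unknown alignment mode {mode!r}")
    return a.reorder(nodes), b.reorder(nodes)
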
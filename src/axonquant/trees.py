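"""Rooted axon trees and SWC file I/O.

An :class:`AxonTree` stores one reconstructed (or simulated) axon as arrays
of 3D node coordinates (µm), per-node radii, and parent pointers — the same
topology model as the SWC morphology format. Roots sit at the crush/entry
plane; terminal tips are the leaves.

SWC dialect: standard 7 columns (id, type, x, y, z, radius, parent), µm
units, 1-based node ids, parent −1 for roots, parents precede children.
Several trees may share one file (a forest, one tree per axon). The type
field is 2 (axon) throughout; comment header lines carry per-axon labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

__all__ = ["AxonTree", "SWCFormatError", "read_swc", "write_swc"]


class SWCFormatError(ValueError):
    """Malformed SWC content (cyclic/dangling parents, bad columns)."""


@dataclass
class AxonTree:
    """One axon as a rooted tree of 3D points.

    Attributes
    ----------
    nodes : (n, 3) float array, µm.
    radius : (n,) float array, µm — local half-width.
    parent : (n,) int array — index of each node's parent, −1 for the root.
    labels : free-form per-axon metadata (ground-truth flags, quality flags).
    """

    nodes: np.ndarray
    radius: np.ndarray
    parent: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float).reshape(-1, 3)
        n = len(self.nodes)
        self.radius = np.asarray(self.radius, dtype=float).reshape(n)
        self.parent = np.asarray(self.parent, dtype=int).reshape(n)
        roots = np.flatnonzero(self.parent < 0)
        if n and len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if np.any(self.parent >= np.arange(n)):
            raise ValueError("parents must precede children")

    # -- topology ---------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    def children(self) -> Dict[int, List[int]]:
        ch: Dict[int, List[int]] = {i: [] for i in range(self.n_nodes)}
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[int(p)].append(i)
        return ch

    def tips(self) -> List[int]:
        """Leaf nodes (no children). The root is never counted as a tip."""
        has_child = np.zeros(self.n_nodes, dtype=bool)
        for p in self.parent:
            if p >= 0:
                has_child[p] = True
        return [i for i in range(self.n_nodes) if not has_child[i] and i != self.root]

    def branch_points(self) -> List[int]:
        n_children = np.zeros(self.n_nodes, dtype=int)
        for p in self.parent:
            if p >= 0:
                n_children[p] += 1
        return [i for i in range(self.n_nodes) if n_children[i] >= 2]

    def n_tips(self) -> int:
        return max(1, len(self.tips())) if self.n_nodes else 0

    # -- geometry ---------------------------------------------------------
    def edge_lengths(self) -> np.ndarray:
        """Per-node length of the edge to the parent (0 for the root)."""
        out = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        idx = np.flatnonzero(mask)
        out[idx] = np.linalg.norm(
            self.nodes[idx] - self.nodes[self.parent[idx]], axis=1
        )
        return out

    def path_length_to_root(self) -> np.ndarray:
        """Cumulative arc length from the root to every node."""
        el = self.edge_lengths()
        out = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parent[i]
            if p >= 0:
                out[i] = out[p] + el[i]
        return out

    def path_to_root(self, node: int) -> List[int]:
        path = [node]
        while self.parent[path[-1]] >= 0:
            path.append(int(self.parent[path[-1]]))
        return path

    def longest_path(self) -> List[int]:
        """Root-to-tip node index path maximizing arc length (root first).

        Ties broken by node index for determinism.
        """
        dist = self.path_length_to_root()
        tips = self.tips() or [self.root]
        best = min(tips, key=lambda t: (-dist[t], t))
        return self.path_to_root(best)[::-1]

    def length(self) -> float:
        """Arc length of the longest root-to-tip path (µm)."""
        if self.n_nodes == 0:
            return 0.0
        return float(self.path_length_to_root().max())

    def total_cable(self) -> float:
        return float(self.edge_lengths().sum())

    def terminal_direction(self, window: float = 20.0) -> np.ndarray:
        """Unit chord from the point `window` µm before the terminal to it.

        Follows the longest root-to-tip path; used for U-turn scoring.
        """
        path = self.longest_path()
        pts = self.nodes[path]
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        total = arc[-1]
        if total <= 0:
            raise ValueError("degenerate path: zero arc length")
        target = max(total - window, 0.0)
        # interpolate the point at arc length `target`
        j = int(np.searchsorted(arc, target, side="right") - 1)
        j = min(j, len(pts) - 2)
        t = (target - arc[j]) / (arc[j + 1] - arc[j]) if seg[j] > 0 else 0.0
        start = pts[j] + t * (pts[j + 1] - pts[j])
        vec = pts[-1] - start
        nrm = np.linalg.norm(vec)
        if nrm == 0:
            raise ValueError("degenerate terminal direction (zero-length vector)")
        return vec / nrm

    def resample_path_points(self, path: Sequence[int]) -> np.ndarray:
        return self.nodes[list(path)]


# -- SWC I/O --------------------------------------------------------------

def write_swc(trees: Iterable[AxonTree], path, header: Optional[str] = None) -> None:
    """Write a forest of axon trees to one SWC file.

    Per-axon labels are emitted as ``# axon <k> key=value ...`` comments so a
    ground-truth file round-trips its flags.
    """
    trees = list(trees)
    lines = []
    if header:
        for h in header.splitlines():
            lines.append(f"# {h}")
    lines.append("# id type x y z radius parent  (units um)")
    for k, tree in enumerate(trees):
        if tree.labels:
            kv = " ".join(f"{key}={tree.labels[key]}" for key in sorted(tree.labels))
            lines.append(f"# axon {k} {kv}")
    offset = 0
    for tree in trees:
        for i in range(tree.n_nodes):
            x, y, z = tree.nodes[i]
            p = tree.parent[i]
            pid = -1 if p < 0 else p + 1 + offset
            lines.append(
                f"{i + 1 + offset} 2 {x:.6g} {y:.6g} {z:.6g} "
                f"{tree.radius[i]:.6g} {pid}"
            )
        offset += tree.n_nodes
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_labels(comment_lines: List[str]) -> Dict[int, dict]:
    out: Dict[int, dict] = {}
    for line in comment_lines:
        parts = line.lstrip("#").split()
        if len(parts) >= 2 and parts[0] == "axon" and parts[1].isdigit():
            labels = {}
            for token in parts[2:]:
                if "=" in token:
                    key, val = token.split("=", 1)
                    labels[key] = _coerce(val)
            out[int(parts[1])] = labels
    return out


def _coerce(val: str):
    if val in ("True", "False"):
        return val == "True"
    try:
        f = float(val)
        return int(f) if f.is_integer() and "." not in val and "e" not in val else f
    except ValueError:
        return val


def read_swc(path) -> List[AxonTree]:
    """Read an SWC file into a list of axon trees (one per root).

    Raises :class:`SWCFormatError` naming the offending line for dangling or
    cyclic parent pointers.
    """
    comment_lines: List[str] = []
    ids: List[int] = []
    rows: List[tuple] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comment_lines.append(line)
            continue
        parts = line.split()
        if len(parts) < 7:
            raise SWCFormatError(f"line {lineno}: expected 7 columns, got {len(parts)}")
        try:
            nid = int(parts[0])
            x, y, z, r = (float(v) for v in parts[2:6])
            pid = int(parts[6])
        except ValueError as exc:
            raise SWCFormatError(f"line {lineno}: {exc}") from None
        ids.append(nid)
        rows.append((lineno, nid, x, y, z, r, pid))

    id_to_pos = {nid: i for i, (_, nid, *_rest) in enumerate(rows)}
    if len(id_to_pos) != len(rows):
        raise SWCFormatError("duplicate node ids")
    for lineno, nid, *_xyzr, pid in rows:
        if pid != -1 and pid not in id_to_pos:
            raise SWCFormatError(f"line {lineno}: dangling parent {pid}")
        if pid != -1 and id_to_pos[pid] >= id_to_pos[nid]:
            raise SWCFormatError(
                f"line {lineno}: parent {pid} does not precede node {nid}"
            )

    # group by root-connected component, preserving file order
    comp = {}
    order: List[int] = []
    for _lineno, nid, *_xyzr, pid in rows:
        if pid == -1:
            comp[nid] = len(order)
            order.append(nid)
        else:
            comp[nid] = comp[pid]

    labels = _parse_labels(comment_lines)
    trees: List[AxonTree] = []
    for k in range(len(order)):
        members = [row for row in rows if comp[row[1]] == k]
        local = {row[1]: i for i, row in enumerate(members)}
        nodes = np.array([[r[2], r[3], r[4]] for r in members])
        radius = np.array([r[5] for r in members])
        parent = np.array(
            [-1 if r[6] == -1 else local[r[6]] for r in members], dtype=int
        )
        trees.append(
            AxonTree(nodes=nodes, radius=radius, parent=parent,
                     labels=labels.get(k, {}))
        )
    return trees
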
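"""Pairwise evolutionary distances and neighbor-joining trees.

Three models are supported on pre-aligned sequences: uncorrected p-distance
("simple"), Jukes-Cantor (JC69) and Kimura two-parameter (K2P). Sites with a
gap or ambiguity code in either sequence are excluded pair by pair (pairwise
deletion). Saturated pairs — where the model correction's logarithm is
undefined — abort with an error listing the offending pairs rather than
producing NA, so downstream partitions never rest on partial matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DomainError, SaturationError

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}  # A=0 C=1 G=2 T=3
_PURINE = {0, 2}


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes; anything outside ACGT becomes -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


@dataclass(frozen=True)
class SitePairCounts:
    """Comparable-site summary of one aligned sequence pair."""

    n: int
    P: float  # transition proportion
    Q: float  # transversion proportion

    def __post_init__(self):
        if self.n < 1:
            raise DomainError("no comparable sites")
        if self.P < 0 or self.Q < 0 or self.P + self.Q > 1 + 1e-12:
            raise DomainError(f"invalid proportions P={self.P}, Q={self.Q}")

    @property
    def p(self) -> float:
        """Total mismatch proportion (p-distance numerator)."""
        return self.P + self.Q


def count_site_patterns(a: str, b: str) -> SitePairCounts:
    """Count transitions and transversions between two aligned sequences.

    Pairwise deletion: sites where either sequence has a gap, N or any
    ambiguity code are dropped before counting.
    """
    if len(a) != len(b):
        raise DomainError(f"aligned lengths differ: {len(a)} vs {len(b)}")
    ca, cb = _encode(a), _encode(b)
    valid = (ca >= 0) & (cb >= 0)
    n = int(valid.sum())
    if n == 0:
        raise DomainError("zero comparable sites after pairwise deletion")
    ca, cb = ca[valid], cb[valid]
    diff = ca != cb
    # transition = purine<->purine or pyrimidine<->pyrimidine: codes differ by 2
    ts = diff & (np.abs(ca - cb) == 2)
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return SitePairCounts(n=n, P=n_ts / n, Q=n_tv / n)


def k2p(counts: SitePairCounts) -> float:
    """Kimura two-parameter distance: d = −½·ln(1−2P−Q) − ¼·ln(1−2Q)."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P undefined for P={counts.P:.4f}, Q={counts.Q:.4f} (saturation)"
        )
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def jc69(p: float) -> float:
    """Jukes-Cantor distance: d = −¾·ln(1 − 4p/3), defined for p < 0.75."""
    if p < 0:
        raise DomainError(f"mismatch proportion negative: {p}")
    if p >= 0.75:
        raise SaturationError(f"JC69 undefined for p={p:.4f} (saturation)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


MODELS = ("p", "JC69", "K2P")


def _pair_distance(counts: SitePairCounts, model: str) -> float:
    if model == "p":
        return counts.p
    if model == "JC69":
        return jc69(counts.p)
    if model == "K2P":
        return k2p(counts)
    raise DomainError(f"unknown distance model: {model!r}")


@dataclass
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise distances under a named model."""

    labels: list[str]
    values: np.ndarray
    model: str = "p"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DomainError("label count does not match matrix shape")
        if not np.allclose(self.values, self.values.T):
            raise DomainError("matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise DomainError("matrix diagonal not zero")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("matrix has non-finite entries")

    def __len__(self):
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (scipy condensed order)."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def submatrix(self, labels) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(
            list(labels), self.values[np.ix_(idx, idx)], self.model
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(
            path, float_format="%.10g"
        )

    @classmethod
    def from_csv(cls, path, model="p") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), model)


def distance_matrix(records, model="K2P") -> DistanceMatrix:
    """All-pairs distance matrix for one marker's aligned records.

    Raises :class:`SaturationError` listing every saturated pair instead of
    silently emitting missing values.
    """
    records = list(records)
    if len(records) < 2:
        raise DomainError("need at least 2 records")
    markers = {r.marker for r in records}
    if len(markers) > 1:
        raise DomainError(f"mixed markers in one matrix: {sorted(markers)}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) > 1:
        raise DomainError("records not aligned (unequal lengths)")
    n = len(records)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            counts = count_site_patterns(records[i].seq, records[j].seq)
            try:
                d[i, j] = d[j, i] = _pair_distance(counts, model)
            except SaturationError:
                saturated.append((records[i].sample_id, records[j].sample_id))
    if saturated:
        raise SaturationError(
            f"{len(saturated)} saturated pair(s) under {model}: {saturated[:5]}",
            pairs=saturated,
        )
    return DistanceMatrix([r.sample_id for r in records], d, model)


# --------------------------------------------------------------------------
# Neighbor joining
# --------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Minimal rooted view of an (unrooted) NJ tree.

    ``children`` holds (child, branch_length) pairs; leaves carry ``name``.
    """

    name: str | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaf_names())
        return out

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths between every leaf pair (additivity check)."""
        depths: dict[str, float] = {}

        def collect(node):
            # returns {leaf: depth below node}
            if node.is_leaf:
                return {node.name: 0.0}
            merged = {}
            groups = []
            for child, blen in node.children:
                sub = {k: v + blen for k, v in collect(child).items()}
                groups.append(sub)
                merged.update(sub)
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for la, da in groups[gi].items():
                        for lb, db in groups[gj].items():
                            key = (la, lb) if la < lb else (lb, la)
                            depths[key] = da + db
            return merged

        collect(self)
        return depths


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining agglomeration of a distance matrix.

    Negative branch lengths are clamped to zero and the deficit is moved to
    the sister edge, preserving the joined pair's summed length.
    """
    n = len(dm)
    if n < 3:
        raise DomainError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=l) for l in dm.labels]
    d = dm.values.astype(float).copy()
    active = list(range(n))

    def clamp(li, lj):
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        a, b = active[i_], active[j_]
        dij = d[a, b]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[(nodes[a], li), (nodes[b], lj)])
        # distances from the new node to every other active node
        new_row = 0.5 * (d[a] + d[b] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :-1] = new_row
        d[:-1, -1] = new_row
        nodes.append(parent)
        active = [k for k in active if k not in (a, b)] + [len(nodes) - 1]

    # resolve the final three nodes around an unrooted center
    x, y, z = active
    lx = 0.5 * (d[x, y] + d[x, z] - d[y, z])
    ly = 0.5 * (d[x, y] + d[y, z] - d[x, z])
    lz = 0.5 * (d[x, z] + d[y, z] - d[x, y])
    lengths = [max(l, 0.0) for l in (lx, ly, lz)]
    return TreeNode(children=list(zip((nodes[x], nodes[y], nodes[z]), lengths)))


def to_newick(tree: TreeNode) -> str:
    """Newick string with branch lengths to 6 decimals."""

    def render(node):
        if node.is_leaf:
            return node.name
        inner = ",".join(
            f"{render(child)}:{blen:.6f}" for child, blen in node.children
        )
        return f"({inner})"

    return render(tree) + ";"


def write_newick(tree: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")
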
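"""Automatic barcode-gap species delimitation.

Specimens of one species accumulate small pairwise distances; distances
between species are larger. When the two distributions do not overlap, the
ranked distances show a "barcode gap": a stretch of consecutive ranked
distances much wider than its neighbors. This module detects that gap above
a prior maximal intraspecific divergence P, partitions specimens by single
linkage below the detected threshold, recurses within the resulting groups,
and sweeps the prior over a range (the relative gap width X and the P range
0.001-0.100 mirror the study settings of the original web-based procedure).

The original gap-detection internals are not published in usable detail; the
deterministic rule here flags the first inter-distance interval whose width
exceeds X times the mean width of the preceding (up to W, at least 3)
intervals. A detected threshold is the interval midpoint. Absence of a gap
is a valid outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .exceptions import DomainError


@dataclass
class Partition:
    """Specimen -> group assignment with the parameters that produced it."""

    assignment: dict[str, str]
    prior_P: float | None
    threshold: float | None
    n_groups: int

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for spec, grp in self.assignment.items():
            out.setdefault(grp, []).append(spec)
        return {g: sorted(m) for g, m in out.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": list(self.assignment),
                "group_id": list(self.assignment.values()),
                "prior_P": self.prior_P,
                "threshold": self.threshold,
            }
        )


@dataclass
class GapReport:
    """Sorted distances, histogram and ranked-distance curve for one matrix."""

    sorted_distances: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    gap_interval: tuple[float, float] | None = None

    @property
    def ranked(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.sorted_distances) + 1),
                "distance": self.sorted_distances,
            }
        )


@dataclass
class SweepResult:
    """Partitions across a log-spaced sweep of the prior divergence."""

    priors: list[float]
    partitions: list[Partition]
    X: float

    def n_groups_by_prior(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"prior_P": self.priors, "n_groups": [p.n_groups for p in self.partitions]}
        )


def gap_report(dm: DistanceMatrix, n_bins: int = 20) -> GapReport:
    """Sorted pairwise distances plus an equal-width histogram over [0, max]."""
    if len(dm) < 2:
        raise DomainError("need at least 2 specimens")
    dists = np.sort(dm.condensed())
    upper = dists[-1] if dists[-1] > 0 else 1.0
    counts, edges = np.histogram(dists, bins=n_bins, range=(0.0, upper))
    return GapReport(sorted_distances=dists, hist_counts=counts, hist_edges=edges)


def detect_gap(sorted_distances, prior_P: float, X: float = 1.5, W: int = 10):
    """Find the barcode-gap threshold above ``prior_P``, or None.

    Scans consecutive intervals of the ascending *unique* distance values
    (ties collapse to one rank — aligned sequences give a discrete distance
    lattice, and tied values would otherwise make every step look like a
    gap). An interval is a gap when its midpoint exceeds the prior and its
    width exceeds ``X`` times BOTH (a) the maximum width in the preceding
    window of up to ``W`` intervals and (b) the prior itself; at least 3
    preceding intervals are required for the comparison (the window may
    reach below the prior). The window maximum, not the mean, is the local
    reference because corrected distances from aligned sequences form a
    near-lattice whose near-tied values would otherwise shrink the reference
    width and turn ordinary lattice steps into spurious gaps; the
    ``X * prior`` floor encodes that a barcode gap must be wide relative to
    the assumed intraspecific divergence, not merely to local spacing.
    Returns the interval midpoint, which is the single-linkage threshold.
    """
    if prior_P <= 0:
        raise DomainError("prior_P must be positive")
    if X <= 0:
        raise DomainError("X must be positive")
    d = np.asarray(sorted_distances, dtype=float)
    if np.any(np.diff(d) < 0):
        raise DomainError("distances must be sorted ascending")
    d = np.unique(d)
    if len(d) < 2:
        return None
    widths = np.diff(d)
    for i, w in enumerate(widths):
        mid = 0.5 * (d[i] + d[i + 1])
        if mid <= prior_P:
            continue
        if i < 3:
            continue
        window = widths[max(0, i - W):i]
        if w > X * window.max() and w > X * prior_P:
            return float(mid)
    return None


def single_linkage_partition(dm: DistanceMatrix, threshold: float) -> Partition:
    """Groups = connected components of the graph joining pairs with d < threshold.

    Group ids are the lexicographically smallest member label, making results
    stable across specimen orderings.
    """
    if threshold <= 0:
        raise DomainError("threshold must be positive")
    n = len(dm)
    adj = csr_matrix(dm.values < threshold)
    _, comp = connected_components(adj, directed=False)
    members: dict[int, list[str]] = {}
    for label, c in zip(dm.labels, comp):
        members.setdefault(int(c), []).append(label)
    assignment = {}
    for labels in members.values():
        gid = min(labels)
        for l in labels:
            assignment[l] = gid
    return Partition(
        assignment=assignment,
        prior_P=None,
        threshold=threshold,
        n_groups=len(members),
    )


def recursive_delimit(
    dm: DistanceMatrix,
    prior_P: float,
    X: float = 1.5,
    W: int = 10,
    max_depth: int = 10,
    min_group_size: int = 4,
) -> Partition:
    """Gap detection + single linkage, re-applied within each group.

    Recursion inside a group stops when no gap is found there, the group has
    fewer than ``min_group_size`` members, the split is trivial (one group),
    or ``max_depth`` is reached.
    """
    thresholds: list[float] = []

    def split(sub: DistanceMatrix, depth: int) -> dict[str, str]:
        whole = {l: min(sub.labels) for l in sub.labels}
        if depth >= max_depth or len(sub) < min_group_size:
            return whole
        t = detect_gap(np.sort(sub.condensed()), prior_P, X=X, W=W)
        if t is None:
            return whole
        part = single_linkage_partition(sub, t)
        if part.n_groups == 1:
            return whole
        thresholds.append(t)
        assignment = {}
        for members in part.groups().values():
            assignment.update(split(sub.submatrix(members), depth + 1))
        return assignment

    assignment = split(dm, 0)
    return Partition(
        assignment=assignment,
        prior_P=prior_P,
        threshold=thresholds[0] if thresholds else None,
        n_groups=len(set(assignment.values())),
    )


def prior_sweep(
    dm: DistanceMatrix,
    P_min: float = 0.001,
    P_max: float = 0.100,
    n_steps: int = 10,
    X: float = 1.5,
    W: int = 10,
) -> SweepResult:
    """One recursive delimitation per log-spaced prior in [P_min, P_max]."""
    if not (0 < P_min < P_max):
        raise DomainError("need 0 < P_min < P_max")
    priors = np.geomspace(P_min, P_max, n_steps)
    partitions = [recursive_delimit(dm, float(p), X=X, W=W) for p in priors]
    return SweepResult(priors=[float(p) for p in priors], partitions=partitions, X=X)
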
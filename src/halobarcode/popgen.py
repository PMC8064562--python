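"""Population-genetic structure from molecular distances.

One-level AMOVA partitions squared pairwise distances into among- and
within-population components (populations within the total, the design the
study reports). The fixation index Fst is the among-population fraction of
total molecular variance; its significance comes from a nonparametric
permutation test that shuffles individuals among populations while
preserving sample sizes (1023 randomizations by default). Nei's standard
genetic distance is computed from haplotype frequency vectors.

Sums of squared deviations follow the classical identity
SSD = sum_{i<j} d_ij^2 / n for a group of n individuals, so the whole
analysis runs directly from a distance matrix without coordinates:

    SSD_total  = sum_{i<j} d_ij^2 / N
    SSD_within = sum_pop sum_{i<j in pop} d_ij^2 / n_pop
    SSD_among  = SSD_total - SSD_within
    sigma2_w   = SSD_within / (N - P)
    n_bar      = (N - sum n_p^2 / N) / (P - 1)
    sigma2_a   = (SSD_among / (P - 1) - sigma2_w) / n_bar
    Fst        = sigma2_a / (sigma2_a + sigma2_w)

Negative variance components are clamped to zero for the reported Fst; the
raw values are kept on the result object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .exceptions import DomainError


@dataclass
class AmovaResult:
    """Variance decomposition and fixation index for one marker."""

    df_among: int
    df_within: int
    ssd_among: float
    ssd_within: float
    sigma2_a: float
    sigma2_w: float
    pct_among: float
    pct_within: float
    fst: float
    fst_raw: float
    p_value: float | None = None
    n_permutations: int | None = None

    @property
    def ssd_total(self) -> float:
        return self.ssd_among + self.ssd_within

    def summary(self) -> pd.DataFrame:
        """Standard AMOVA table (source, df, SSD, variance, % of total)."""
        return pd.DataFrame(
            {
                "source": ["Among populations", "Within populations", "Total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "SSD": [self.ssd_among, self.ssd_within, self.ssd_total],
                "variance": [self.sigma2_a, self.sigma2_w, self.sigma2_a + self.sigma2_w],
                "pct": [self.pct_among, self.pct_within, 100.0],
            }
        )


def _codes_and_sizes(dm: DistanceMatrix, pops: dict[str, str]):
    unmapped = [l for l in dm.labels if l not in pops]
    if unmapped:
        raise DomainError(f"specimens without a population: {unmapped[:5]}")
    pop_names = sorted(set(pops[l] for l in dm.labels))
    code_of = {p: i for i, p in enumerate(pop_names)}
    codes = np.array([code_of[pops[l]] for l in dm.labels])
    sizes = np.bincount(codes, minlength=len(pop_names))
    return codes, sizes, pop_names


def _fst_components(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray):
    """(ssd_among, ssd_within, sigma2_a, sigma2_w) for squared distances d2."""
    n = len(codes)
    n_pops = len(sizes)
    ssd_total = d2.sum() / (2.0 * n)
    ssd_within = 0.0
    for p in range(n_pops):
        idx = np.flatnonzero(codes == p)
        ssd_within += d2[np.ix_(idx, idx)].sum() / (2.0 * sizes[p])
    ssd_among = ssd_total - ssd_within
    df_among = n_pops - 1
    df_within = n - n_pops
    sigma2_w = ssd_within / df_within
    n_bar = (n - (sizes**2).sum() / n) / df_among
    sigma2_a = (ssd_among / df_among - sigma2_w) / n_bar
    return ssd_among, ssd_within, sigma2_a, sigma2_w


def _fst_from(sigma2_a: float, sigma2_w: float) -> tuple[float, float]:
    """(clamped fst, raw fst); all-zero variance reports 0 by convention."""
    total = sigma2_a + sigma2_w
    if total == 0:
        return 0.0, 0.0
    raw = sigma2_a / total
    a, w = max(sigma2_a, 0.0), max(sigma2_w, 0.0)
    clamped = 0.0 if a + w == 0 else a / (a + w)
    return clamped, raw


def amova_one_level(dm: DistanceMatrix, pops: dict[str, str]) -> AmovaResult:
    """One-level AMOVA (populations within total) from a distance matrix."""
    codes, sizes, _ = _codes_and_sizes(dm, pops)
    if len(sizes) < 2:
        raise DomainError("AMOVA needs at least 2 populations")
    if np.any(sizes == 0):
        raise DomainError("empty population")
    n = len(codes)
    if n - len(sizes) == 0:
        raise DomainError("df_within is zero (all populations are singletons)")
    d2 = dm.values**2
    ssd_among, ssd_within, sigma2_a, sigma2_w = _fst_components(d2, codes, sizes)
    fst, fst_raw = _fst_from(sigma2_a, sigma2_w)
    total_var = max(sigma2_a, 0.0) + max(sigma2_w, 0.0)
    pct_among = 100.0 * fst
    return AmovaResult(
        df_among=len(sizes) - 1,
        df_within=n - len(sizes),
        ssd_among=ssd_among,
        ssd_within=ssd_within,
        sigma2_a=sigma2_a,
        sigma2_w=sigma2_w,
        pct_among=pct_among,
        pct_within=100.0 - pct_among,
        fst=fst,
        fst_raw=fst_raw,
    )


def fst_permutation_test(
    dm: DistanceMatrix, pops: dict[str, str], n_perm: int = 1023, seed=None
) -> float:
    """Permutation p-value for Fst.

    Individuals are shuffled among populations preserving sample sizes;
    p = (1 + #{permuted Fst >= observed}) / (n_perm + 1). The raw
    (unclamped) Fst is the test statistic — clamping negative variance
    components to zero would pile ties at zero and make null p-values
    non-uniform. Deterministic under a fixed seed.
    """
    codes, sizes, _ = _codes_and_sizes(dm, pops)
    d2 = dm.values**2
    _, obs = _fst_from(*_fst_components(d2, codes, sizes)[2:])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        _, f = _fst_from(*_fst_components(d2, perm, sizes)[2:])
        if f >= obs - 1e-12:
            count += 1
    return (1 + count) / (n_perm + 1)


def haplotype_frequencies(records_by_pop: dict[str, list]) -> pd.DataFrame:
    """Collapse identical sequences to haplotypes; frequencies per population.

    Columns that are gaps in every sequence are dropped first; remaining
    sequences must match exactly (ambiguity codes mismatch unless identical).
    Returns a population x haplotype frequency table over the union index.
    """
    if any(len(v) == 0 for v in records_by_pop.values()):
        empties = [k for k, v in records_by_pop.items() if not v]
        raise DomainError(f"empty population(s): {empties}")
    all_seqs = [r.seq for recs in records_by_pop.values() for r in recs]
    lengths = {len(s) for s in all_seqs}
    if len(lengths) > 1:
        raise DomainError("sequences not aligned (unequal lengths)")
    arr = np.array([list(s) for s in all_seqs])
    keep = ~np.all(arr == "-", axis=0)
    stripped = ["".join(np.array(list(s))[keep]) for s in all_seqs]
    haplotypes = sorted(set(stripped))
    hap_index = {h: i for i, h in enumerate(haplotypes)}
    freqs = {}
    pos = 0
    for pop, recs in records_by_pop.items():
        counts = np.zeros(len(haplotypes))
        for _ in recs:
            counts[hap_index[stripped[pos]]] += 1
            pos += 1
        freqs[pop] = counts / counts.sum()
    return pd.DataFrame(freqs).T.set_axis(
        [f"hap{i+1}" for i in range(len(haplotypes))], axis=1
    )


def nei_distance(freq_x, freq_y) -> float:
    """Nei's standard genetic distance D = -ln I between two populations.

    I = sum(x_i y_i) / sqrt(sum x_i^2 * sum y_i^2) over a shared haplotype
    index; disjoint haplotype pools give I = 0 and D = infinity.
    """
    x = np.asarray(freq_x, dtype=float)
    y = np.asarray(freq_y, dtype=float)
    if x.shape != y.shape:
        raise DomainError("frequency vectors over different haplotype indices")
    if np.any(x < 0) or np.any(y < 0):
        raise DomainError("negative haplotype frequency")
    for v in (x, y):
        if abs(v.sum() - 1.0) > 1e-9:
            raise DomainError(f"frequencies sum to {v.sum()}, not 1")
    identity = (x * y).sum() / math.sqrt((x**2).sum() * (y**2).sum())
    if identity == 0:
        return math.inf
    return -math.log(min(identity, 1.0))


def nei_matrix(freq_table: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Nei distance matrix from a population x haplotype table."""
    pops = list(freq_table.index)
    n = len(pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_distance(
                freq_table.iloc[i].to_numpy(), freq_table.iloc[j].to_numpy()
            )
    return pd.DataFrame(d, index=pops, columns=pops)
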
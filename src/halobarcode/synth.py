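"""Seeded synthetic-data generators with known truth for every stage.

Sequence sets are simulated on a star phylogeny under the Kimura
two-parameter substitution process: a random root, one ancestor per species
at branch length (inter - intra)/2 from the root, and individuals at
intra/2 below their ancestor. Branch lengths are expected substitutions per
site, and each site draws its child base from the exact K80 transition
probabilities, so the K2P estimator recovers the generating divergences
without bias: expected pairwise distance is ``intra`` within species and
``inter`` between species. The transition:transversion odds are kappa:1.

This is deliberately not a coalescent — it is sufficient to exercise
distance corrections (which only need transition/transversion structure)
and guarantees a barcode gap whenever inter > 2*intra by construction.

Landscape generation draws Gaussian random fields (white noise smoothed by
a Gaussian kernel), standardizes them over valid cells, defines the true
suitability as the Gibbs density exp(coeffs . z) over cells, and samples
presence cells without replacement proportionally to it. A one-cell nodata
border ring exercises masking throughout the SDM stack.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .exceptions import DomainError
from .io import SequenceRecord
from .sdm import EnvGrid, NODATA_DEFAULT
from .taxassign import HitRecord

_BASES = np.array(list("ACGT"))
_TRANSITION = np.array([2, 3, 0, 1])  # A<->G, C<->T
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass
class SpeciesTruth:
    """Specimen -> true species label, plus the generating parameters."""

    assignment: dict[str, str]
    params: dict = field(default_factory=dict)

    @property
    def n_species(self) -> int:
        return len(set(self.assignment.values()))

    def species_of(self, sample_id: str) -> str:
        return self.assignment[sample_id]


@dataclass
class LandscapeTruth:
    """Generating coefficients and true suitability of a synthetic landscape."""

    coeffs: np.ndarray
    suitability: EnvGrid
    seed: int | None
    params: dict = field(default_factory=dict)


def _k80_probs(d: float, kappa: float) -> np.ndarray:
    """Per-site K80 substitution probabilities for branch length d.

    Returns [p_same, p_transition, p_each_transversion]; the rates are
    scaled so d is the expected number of substitutions per site and the
    instantaneous transition:transversion odds are kappa:1.
    """
    bt = d / (kappa + 2.0)  # beta * t
    at = kappa * bt  # alpha * t
    e1 = np.exp(-2.0 * (at + bt))
    e2 = np.exp(-4.0 * bt)
    p_ts = 0.25 + 0.25 * e2 - 0.5 * e1
    p_tv = 0.25 - 0.25 * e2  # each of the two transversions
    return np.array([1.0 - p_ts - 2.0 * p_tv, p_ts, p_tv])


def _evolve(parent: np.ndarray, d: float, kappa: float, rng) -> np.ndarray:
    """One K80 step of expected length d substitutions/site along a branch."""
    if d == 0:
        return parent.copy()
    p_same, p_ts, p_tv = _k80_probs(d, kappa)
    u = rng.random(parent.size)
    child = parent.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    child[ts] = _TRANSITION[parent[ts]]
    tv = u >= p_same + p_ts
    which = (u[tv] - (p_same + p_ts) < p_tv).astype(int)
    child[tv] = _TRANSVERSIONS[parent[tv], 1 - which]
    return child


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def simulate_species_sequences(
    k: int = 4,
    n_per: int = 8,
    L: int = 600,
    intra: float = 0.005,
    inter: float = 0.08,
    kappa: float = 2.0,
    seed=None,
    marker: str = "rbcL",
    site_ids=None,
) -> tuple[list[SequenceRecord], SpeciesTruth]:
    """Multi-species barcode set with controlled intra/inter divergence.

    Expected pairwise distance is ``intra`` within a species and ``inter``
    between species; ``inter > 2*intra`` is required so the barcode gap
    exists by construction. ``site_ids`` optionally assigns a site label per
    specimen (cycled); default is one pseudo-site per species.
    """
    if inter <= 2 * intra:
        raise DomainError(f"need inter > 2*intra (got {inter} <= {2 * intra})")
    if L < 200:
        raise DomainError("L must be >= 200")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=L)
    ancestor_branch = (inter - intra) / 2.0
    tip_branch = intra / 2.0
    records, assignment = [], {}
    idx = 0
    for s in range(1, k + 1):
        species = f"species{s}"
        ancestor = _evolve(root, ancestor_branch, kappa, rng)
        for i in range(1, n_per + 1):
            tip = _evolve(ancestor, tip_branch, kappa, rng)
            sample_id = f"sp{s}_i{i:02d}"
            site = (
                site_ids[idx % len(site_ids)] if site_ids else f"site_sp{s}"
            )
            records.append(SequenceRecord(sample_id, site, marker, _decode(tip)))
            assignment[sample_id] = species
            idx += 1
    truth = SpeciesTruth(
        assignment=assignment,
        params=dict(
            k=k, n_per=n_per, L=L, intra=intra, inter=inter, kappa=kappa,
            seed=seed, marker=marker,
        ),
    )
    return records, truth


def simulate_population_structure(
    n_pops: int = 4,
    n_per: int = 8,
    migration_mix: float = 0.5,
    L: int = 300,
    pool_divergence: float = 0.1,
    kappa: float = 2.0,
    seed=None,
    marker: str = "rbcL",
) -> tuple[list[SequenceRecord], dict[str, str], dict]:
    """Population samples drawn from blended haplotype pools.

    Each population owns one private haplotype; with probability
    ``migration_mix`` an individual instead draws uniformly from the shared
    pool of all haplotypes. mix=0 leaves populations fixed for distinct
    haplotypes (downstream Fst = 1); mix=1 gives one panmictic pool
    (Fst near 0); expected Fst decreases monotonically in between.
    """
    if not (0 <= migration_mix <= 1):
        raise DomainError("migration_mix must be in [0,1]")
    rng = np.random.default_rng(seed)
    root = rng.integers(0, 4, size=L)
    haplotypes = [
        _evolve(root, pool_divergence / 2.0, kappa, rng) for _ in range(n_pops)
    ]
    records, popmap = [], {}
    for p in range(1, n_pops + 1):
        pop = f"pop{p}"
        for i in range(1, n_per + 1):
            if rng.random() < migration_mix:
                hap = haplotypes[rng.integers(0, n_pops)]
            else:
                hap = haplotypes[p - 1]
            sample_id = f"{pop}_i{i:02d}"
            records.append(SequenceRecord(sample_id, pop, marker, _decode(hap)))
            popmap[sample_id] = pop
    descriptor = dict(
        n_pops=n_pops, n_per=n_per, migration_mix=migration_mix,
        pool_divergence=pool_divergence, seed=seed,
        expected_regime="fst=1" if migration_mix == 0 else (
            "fst~0" if migration_mix == 1 else "intermediate"
        ),
    )
    return records, popmap, descriptor

# Confamilial decoys outside the focal genus (Amaranthaceae relatives).
_CONFAMILIAL = [
    ("Arthrocnemum macrostachyum", "Arthrocnemum"),
    ("Suaeda maritima", "Suaeda"),
    ("Halocnemum strobilaceum", "Halocnemum"),
]


def simulate_hit_table(
    truth: SpeciesTruth,
    score_noise_sd: float = 0.0,
    decoy_rate: float = 0.0,
    seed=None,
    species_names=None,
    genus: str = "Salicornia",
    family: str = "Amaranthaceae",
    n_congeneric: int = 6,
) -> list[HitRecord]:
    """Offline stand-in for BLAST output with configurable confusability.

    Per query: one true-species hit on top, congeneric decoys at scores
    consistent with the generating inter-specific divergence, and
    confamilial decoys further down. ``score_noise_sd`` jitters every bit
    score; with probability ``decoy_rate`` one congeneric decoy is drawn
    within 1% of the top score (exercising the multi-species deviation-set
    branches of the assignment ladder). Deterministic under seed.
    """
    if score_noise_sd < 0:
        raise DomainError("score_noise_sd must be >= 0")
    if not (0 <= decoy_rate < 1):
        raise DomainError("decoy_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    L = truth.params.get("L", 600)
    intra = truth.params.get("intra", 0.005)
    inter = truth.params.get("inter", 0.08)
    species_labels = sorted(set(truth.assignment.values()))
    if species_names is None:
        species_names = {
            s: f"{genus} {s}" for s in species_labels
        }
    hits = []
    for sample_id in sorted(truth.assignment):
        true_sp = truth.assignment[sample_id]
        top_identity = min(100.0, 100.0 * (1 - intra) + rng.normal(0, 0.1))
        top_score = 1.8 * L * top_identity / 100.0 + rng.normal(0, score_noise_sd)
        hits.append(
            HitRecord(
                query_id=sample_id,
                subject_id=f"acc_{true_sp}_ref",
                subject_species=species_names[true_sp],
                genus=genus,
                family=family,
                max_score=round(max(top_score, 1.0), 1),
                query_cover=100.0,
                identity=round(max(min(top_identity, 100.0), 0.1), 2),
            )
        )
        decoy_pool = [s for s in species_labels if s != true_sp]
        close_decoy = rng.random() < decoy_rate
        for j in range(n_congeneric):
            sp = decoy_pool[j % len(decoy_pool)] if decoy_pool else true_sp
            if close_decoy and j == 0:
                # a hit within the 1% band under both ranking scores
                score = top_score * (1 - rng.uniform(0.0, 0.005))
                ident = top_identity - rng.uniform(0.0, 0.3)
                qcov = 100.0
            else:
                ident = 100.0 * (1 - inter) + rng.normal(0, 0.5)
                score = 1.8 * L * ident / 100.0 + rng.normal(0, score_noise_sd)
                score = min(score, top_score * 0.97)
                # coverage tracks identity so the weighted score stays
                # proportional to the bit score for genuine distant hits
                qcov = float(np.clip(rng.normal(ident, 1.0), 50, 100))
            hits.append(
                HitRecord(
                    query_id=sample_id,
                    subject_id=f"acc_{sp}_{j}",
                    subject_species=species_names[sp],
                    genus=genus,
                    family=family,
                    max_score=round(max(score, 1.0), 1),
                    query_cover=round(qcov, 1),
                    identity=round(max(min(ident, 100.0), 0.1), 2),
                )
            )
        for name, dec_genus in _CONFAMILIAL:
            ident = 100.0 * (1 - 2.5 * inter) + rng.normal(0, 0.5)
            score = 1.8 * L * ident / 100.0 + rng.normal(0, score_noise_sd)
            hits.append(
                HitRecord(
                    query_id=sample_id,
                    subject_id=f"acc_{dec_genus}",
                    subject_species=name,
                    genus=dec_genus,
                    family=family,
                    max_score=round(max(min(score, top_score * 0.9), 1.0), 1),
                    query_cover=round(float(np.clip(rng.normal(ident, 2.0), 50, 100)), 1),
                    identity=round(max(min(ident, 100.0), 0.1), 2),
                )
            )
    return hits


def simulate_study(
    sites: pd.DataFrame,
    k_species: int = 4,
    specimens_per_site=(2, 5),
    markers=None,
    intra: float = 0.005,
    inter: float = 0.08,
    kappa: float = 2.0,
    seed=None,
):
    """A full multi-site, multi-marker study with one species per site.

    Sites (rows of a sample table) are assigned to ``k_species`` species
    round-robin by site number; each site contributes a uniform 2-5 (by
    default) specimens. Every marker is simulated independently on the same
    species/specimen structure. Returns
    ``(records_by_marker, population_map, truth)``.
    """
    if markers is None:
        markers = {"rbcL": 600, "matK": 800, "trnH-psbA": 450, "ITS2": 350,
                   "ycf": 500}
    lo, hi = specimens_per_site
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng = np.random.default_rng(ss.spawn(1)[0])
    site_rows = list(sites.itertuples())
    n_spec = {
        int(r.site_no): int(rng.integers(lo, hi + 1)) for r in site_rows
    }
    species_of_site = {
        int(r.site_no): f"species{(int(r.site_no) - 1) % k_species + 1}"
        for r in site_rows
    }
    specimens = []  # (sample_id, site_label, species)
    for r in site_rows:
        site_no = int(r.site_no)
        for i in range(1, n_spec[site_no] + 1):
            specimens.append(
                (f"s{site_no:02d}_{i}", f"site{site_no:02d}",
                 species_of_site[site_no])
            )
    assignment = {sid: sp for sid, _, sp in specimens}
    popmap = {sid: site for sid, site, _ in specimens}

    ancestor_branch = (inter - intra) / 2.0
    tip_branch = intra / 2.0
    records_by_marker = {}
    marker_seeds = ss.spawn(1 + len(markers))[1:]
    for (marker, L), mseed in zip(markers.items(), marker_seeds):
        mrng = np.random.default_rng(mseed)
        root = mrng.integers(0, 4, size=L)
        ancestors = {
            f"species{s}": _evolve(root, ancestor_branch, kappa, mrng)
            for s in range(1, k_species + 1)
        }
        recs = []
        for sid, site, sp in specimens:
            tip = _evolve(ancestors[sp], tip_branch, kappa, mrng)
            recs.append(SequenceRecord(sid, site, marker, _decode(tip)))
        records_by_marker[marker] = recs
    truth = SpeciesTruth(
        assignment=assignment,
        params=dict(
            k=k_species, intra=intra, inter=inter, kappa=kappa, seed=seed,
            L=int(np.mean(list(markers.values()))), markers=dict(markers),
        ),
    )
    return records_by_marker, popmap, truth


def simulate_landscape(
    n_vars: int = 19,
    nrows: int = 60,
    ncols: int = 60,
    coeffs=None,
    n_presence: int = 200,
    seed=None,
    smooth_frac: float = 0.1,
    cellsize: float = 0.05,
    xllcorner: float = 45.0,
    yllcorner: float = 30.0,
    nodata_border: int = 1,
) -> tuple[list[EnvGrid], pd.DataFrame, LandscapeTruth]:
    """Smooth random environmental layers plus suitability-sampled presences.

    Layers are white noise smoothed with a Gaussian kernel of width
    ``smooth_frac`` of the grid extent, standardized over valid cells. True
    suitability over valid cells is proportional to exp(coeffs . z); the
    ``n_presence`` occurrence points are cell centers sampled without
    replacement with that probability. A ``nodata_border``-cell ring is
    masked in every layer. Zero coefficients mark pure noise variables.
    """
    rng = np.random.default_rng(seed)
    if coeffs is None:
        coeffs = np.zeros(n_vars)
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size != n_vars:
        raise DomainError(f"coeffs length {coeffs.size} != n_vars {n_vars}")
    sigma = smooth_frac * min(nrows, ncols)
    mask = np.zeros((nrows, ncols), dtype=bool)
    b = nodata_border
    if b > 0:
        mask[:] = False
        mask[b:-b, b:-b] = True
    else:
        mask[:] = True

    grids, z_fields = [], []
    for v in range(n_vars):
        field_ = gaussian_filter(rng.standard_normal((nrows, ncols)), sigma=sigma)
        vals = field_[mask]
        z = (field_ - vals.mean()) / vals.std()
        z_fields.append(z)
        values = np.where(mask, z, NODATA_DEFAULT)
        grids.append(
            EnvGrid(
                ncols=ncols,
                nrows=nrows,
                xllcorner=xllcorner,
                yllcorner=yllcorner,
                cellsize=cellsize,
                nodata_value=NODATA_DEFAULT,
                values=values,
                name=f"bio{v + 1:02d}",
            )
        )

    eta = np.zeros((nrows, ncols))
    for c, z in zip(coeffs, z_fields):
        eta += c * z
    eta_valid = eta[mask]
    w = np.exp(eta_valid - eta_valid.max())
    prob = w / w.sum()
    rows, cols = np.nonzero(mask)
    if n_presence > len(rows):
        raise DomainError("n_presence exceeds the number of valid cells")
    pick = rng.choice(len(rows), size=n_presence, replace=False, p=prob)
    lon_grid, lat_grid = grids[0].cell_centers()
    occurrences = pd.DataFrame(
        {
            "lon": lon_grid[rows[pick], cols[pick]],
            "lat": lat_grid[rows[pick], cols[pick]],
        }
    )
    suit_values = np.where(mask, np.exp(eta) , NODATA_DEFAULT)
    suit_values[mask] = suit_values[mask] / suit_values[mask].sum()
    truth = LandscapeTruth(
        coeffs=coeffs,
        suitability=EnvGrid(
            ncols=ncols,
            nrows=nrows,
            xllcorner=xllcorner,
            yllcorner=yllcorner,
            cellsize=cellsize,
            nodata_value=NODATA_DEFAULT,
            values=suit_values,
            name="true_suitability",
        ),
        seed=seed,
        params=dict(
            n_vars=n_vars, nrows=nrows, ncols=ncols, n_presence=n_presence,
            smooth_frac=smooth_frac, nodata_border=nodata_border,
        ),
    )
    return grids, occurrences, truth
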
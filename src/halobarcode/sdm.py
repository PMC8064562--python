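"""Presence-only ecological niche modeling at desk scale.

The workflow mirrors a standard MaxEnt study: environmental layers arrive as
ESRI ASCII grids, occurrence records are screened for climatic outliers with
a reverse-jackknife rule, a random 25% of localities is held out for
testing, a maximum-entropy model with linear + quadratic features is fitted
over background cells under an L1 penalty, and the model is evaluated by
rank-based AUC with the conventional interpretation bands (<0.5 random,
0.5-0.7 poor, 0.7-0.9 moderate, >=0.9 good) plus a jackknife
variable-importance report (each variable alone / excluded).

Model
-----
Over background cells x with feature vector f(x) (each variable's value
standardized on the background, plus its square), the model is the Gibbs
distribution p(x) = exp(lambda . f(x)) / Z. Fitting maximizes the mean
presence log-likelihood minus an L1 penalty:

    J(lambda) = mean_presence [lambda . f(x)] - log Z(lambda)
                - sum_j beta_j |lambda_j|

J is concave; a proximal-gradient (FISTA) iteration with backtracking and a
soft-threshold step gives exact zeros for uninformative features. The L1
penalty is applied on this per-presence scale (beta = 1.0 per feature by
default), so a feature enters only when its presence mean shifts from the
background mean by more than ~beta standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, softmax
from sklearn.metrics import roc_auc_score

from .exceptions import DomainError, GridFormatError

NODATA_DEFAULT = -9999.0


@dataclass
class EnvGrid:
    """One environmental raster layer (row 0 is the northernmost row)."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata_value: float
    values: np.ndarray
    name: str = "env"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.nrows, self.ncols):
            raise GridFormatError(
                f"{self.name}: values shape {self.values.shape} != "
                f"({self.nrows}, {self.ncols})"
            )
        if self.cellsize <= 0:
            raise GridFormatError(f"{self.name}: cellsize must be positive")

    @property
    def mask(self) -> np.ndarray:
        """True where a cell holds data."""
        return self.values != self.nodata_value

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def same_extent(self, other: "EnvGrid") -> bool:
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_of(self, lon: float, lat: float):
        """(row, col) of the containing cell, half-open intervals anchored at
        the lower-left corner; a point on a shared edge belongs to the
        higher-index cell. Returns None outside the extent."""
        col = int(np.floor((lon - self.xllcorner) / self.cellsize))
        row_south = int(np.floor((lat - self.yllcorner) / self.cellsize))
        if not (0 <= col < self.ncols and 0 <= row_south < self.nrows):
            return None
        return self.nrows - 1 - row_south, col

    def cell_centers(self):
        """(lon, lat) arrays of all cell centers, matching ``values`` layout."""
        cols = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        rows_south = self.yllcorner + (np.arange(self.nrows) + 0.5) * self.cellsize
        lats = rows_south[::-1]
        lon_grid, lat_grid = np.meshgrid(cols, lats)
        return lon_grid, lat_grid


def read_esri_ascii(path, name=None) -> EnvGrid:
    """Read a 6-line-header ESRI ASCII grid (north row first)."""
    header = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2:
                raise GridFormatError(f"{path}: bad header line {line!r}")
            header[parts[0].lower()] = parts[1]
        try:
            ncols = int(header["ncols"])
            nrows = int(header["nrows"])
            xll = float(header["xllcorner"])
            yll = float(header["yllcorner"])
            cellsize = float(header["cellsize"])
            nodata = float(header["nodata_value"])
        except KeyError as exc:
            raise GridFormatError(f"{path}: missing header key {exc}") from exc
        tokens = fh.read().split()
        try:
            body = np.array(tokens, dtype=float)
        except ValueError as exc:
            raise GridFormatError(f"{path}: non-numeric value ({exc})") from exc
    if body.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {body.size}"
        )
    return EnvGrid(
        ncols=ncols,
        nrows=nrows,
        xllcorner=xll,
        yllcorner=yll,
        cellsize=cellsize,
        nodata_value=nodata,
        values=body.reshape(nrows, ncols),
        name=name or str(path),
    )


def write_esri_ascii(grid: EnvGrid, path) -> None:
    """Write the 6-line header then row-major values (north row first).

    Values are written with ``repr`` so the read/write round trip is exact.
    """
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner!r}\n")
        fh.write(f"yllcorner {grid.yllcorner!r}\n")
        fh.write(f"cellsize {grid.cellsize!r}\n")
        fh.write(f"NODATA_value {grid.nodata_value!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def extract_env(occurrences: pd.DataFrame, grids) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Occurrence x variable matrix by nearest-cell lookup.

    ``occurrences`` needs ``lon``/``lat`` columns; all grids must share one
    extent. Records outside the extent or landing on nodata in any layer are
    dropped and reported. Returns (matrix, report); the report flags each
    input record as kept or names the reason it was dropped.
    """
    grids = list(grids)
    base = grids[0]
    for g in grids[1:]:
        if not base.same_extent(g):
            raise DomainError(f"grid extent mismatch: {g.name} vs {base.name}")
    rows, reasons = [], []
    for _, rec in occurrences.iterrows():
        cell = base.cell_of(float(rec["lon"]), float(rec["lat"]))
        if cell is None:
            reasons.append("outside_extent")
            rows.append(None)
            continue
        vals = [g.values[cell] for g in grids]
        if any(v == g.nodata_value for v, g in zip(vals, grids)):
            reasons.append("nodata")
            rows.append(None)
        else:
            reasons.append("kept")
            rows.append(vals)
    report = occurrences.copy()
    report["status"] = reasons
    kept = [i for i, r in enumerate(rows) if r is not None]
    matrix = pd.DataFrame(
        [rows[i] for i in kept],
        columns=[g.name for g in grids],
        index=occurrences.index[kept],
    )
    return matrix, report


def reverse_jackknife_outliers(values) -> np.ndarray:
    """Flag gap-separated tail values of one environmental variable.

    Values are sorted; the critical gap is
    ``t = (0.95 * sqrt(n) + 0.2) * (range / 50)``. Walking inward from each
    extreme, a value stays flagged while the gap separating it from the
    remaining body exceeds both ``t`` and twice the mean spacing
    ``range / (n - 1)`` (the relative condition keeps evenly spread small
    samples from being flagged wholesale). A constant vector has no
    outliers. Returns a boolean array aligned with the input order.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5 or not np.all(np.isfinite(x)):
        raise DomainError("need at least 5 finite values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    rng_ = xs[-1] - xs[0]
    flags_sorted = np.zeros(x.size, dtype=bool)
    if rng_ > 0:
        n = x.size
        t = (0.95 * np.sqrt(n) + 0.2) * (rng_ / 50.0)
        rel = 2.0 * rng_ / (n - 1)
        crit = max(t, rel)
        for i in range(n - 1, 0, -1):  # upper tail
            if xs[i] - xs[i - 1] > crit:
                flags_sorted[i:] = True
            else:
                break
        for i in range(0, n - 1):  # lower tail
            if xs[i + 1] - xs[i] > crit:
                flags_sorted[: i + 1] = True
            else:
                break
    flags = np.zeros(x.size, dtype=bool)
    flags[order] = flags_sorted
    return flags


def clean_occurrences(matrix: pd.DataFrame, min_flagged_vars: int = 3):
    """Drop records flagged as outliers in >= ``min_flagged_vars`` variables.

    Returns (cleaned matrix, report) where the report counts per-record
    flags and marks removals. The default of 3 of the (typically 19)
    bioclimatic variables matches the study's screening rule.
    """
    flags = np.column_stack(
        [reverse_jackknife_outliers(matrix[c].to_numpy()) for c in matrix.columns]
    )
    n_flagged = flags.sum(axis=1)
    removed = n_flagged >= min_flagged_vars
    report = pd.DataFrame(
        {"n_flagged_vars": n_flagged, "removed": removed}, index=matrix.index
    )
    return matrix.loc[~removed], report


def split_train_test(occurrences, test_fraction: float = 0.25, seed=None):
    """Uniform random train/test split of occurrence records.

    Test size is ``round(N * test_fraction)``, at least 1; reproducible
    under a fixed seed. Accepts a DataFrame (split by row) or an array.
    """
    if not (0 < test_fraction < 1):
        raise DomainError(f"test_fraction must be in (0,1): {test_fraction}")
    n = len(occurrences)
    if n < 4:
        raise DomainError("need at least 4 occurrences to split")
    n_test = max(1, int(round(n * test_fraction)))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test_idx, train_idx = np.sort(perm[:n_test]), np.sort(perm[n_test:])
    if isinstance(occurrences, pd.DataFrame):
        return occurrences.iloc[train_idx], occurrences.iloc[test_idx]
    arr = np.asarray(occurrences)
    return arr[train_idx], arr[test_idx]


# --------------------------------------------------------------------------
# Maximum-entropy model
# --------------------------------------------------------------------------

@dataclass
class MaxentModel:
    """Fitted maximum-entropy niche model (linear + quadratic features)."""

    var_names: list[str]
    bg_mean: np.ndarray
    bg_sd: np.ndarray
    lambda_: np.ndarray
    beta: float
    quadratic: bool
    background: np.ndarray  # raw background variable matrix (reference)
    log_z: float
    converged: bool
    n_iter: int
    objective: float

    def features(self, X) -> np.ndarray:
        """Standardized linear + quadratic feature matrix for raw variables X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.var_names):
            raise DomainError(
                f"expected {len(self.var_names)} variables, got {X.shape[1]}"
            )
        z = (X - self.bg_mean) / self.bg_sd
        return np.hstack([z, z**2]) if self.quadratic else z

    def linear_predictor(self, X) -> np.ndarray:
        return self.features(X) @ self.lambda_

    def raw_scores(self, X) -> np.ndarray:
        """exp(lambda . f(x)) / Z; sums to 1 over the background reference."""
        return np.exp(self.linear_predictor(X) - self.log_z)


def _feature_matrix(X, mean, sd, quadratic=True):
    z = (np.asarray(X, dtype=float) - mean) / sd
    return np.hstack([z, z**2]) if quadratic else z


def fit_maxent(
    presences,
    background,
    var_names=None,
    beta: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
    quadratic: bool = True,
) -> MaxentModel:
    """Fit the L1-penalized maximum-entropy model.

    ``presences`` and ``background`` are record x variable matrices of raw
    environmental values (DataFrames or arrays over the same columns).
    Features are standardized on the background mean/sd. Optimization is
    proximal-gradient (FISTA) with backtracking; convergence is declared
    when the objective improves by less than ``tol``. Non-convergence at
    ``max_iter`` warns (with the final gradient norm) but still returns the
    model.
    """
    if isinstance(presences, pd.DataFrame):
        var_names = var_names or list(presences.columns)
        presences = presences.to_numpy(dtype=float)
    if isinstance(background, pd.DataFrame):
        var_names = var_names or list(background.columns)
        background = background.to_numpy(dtype=float)
    presences = np.atleast_2d(presences)
    background = np.atleast_2d(background)
    if presences.shape[0] < 2:
        raise DomainError("need at least 2 presence records")
    if var_names is None:
        var_names = [f"var{i+1}" for i in range(presences.shape[1])]

    mean = background.mean(axis=0)
    sd = background.std(axis=0)
    sd[sd == 0] = 1.0  # constant layers contribute null features
    f_pres = _feature_matrix(presences, mean, sd, quadratic)
    f_bg = _feature_matrix(background, mean, sd, quadratic)
    f_bar = f_pres.mean(axis=0)
    k = f_bg.shape[1]

    def smooth_loss(lam):
        # -(lam . f_bar) + log Z  (negated concave part)
        a = f_bg @ lam
        return logsumexp(a) - lam @ f_bar

    def smooth_grad(lam):
        a = f_bg @ lam
        p = softmax(a)
        return f_bg.T @ p - f_bar

    lam = np.zeros(k)
    y = lam.copy()
    t_mom = 1.0
    step = 1.0
    prev_obj = smooth_loss(lam) + beta * np.abs(lam).sum()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = smooth_grad(y)
        fy = smooth_loss(y)
        while True:  # backtracking on the smooth part
            cand = y - step * g
            cand = np.sign(cand) * np.maximum(np.abs(cand) - step * beta, 0.0)
            diff = cand - y
            if smooth_loss(cand) <= fy + g @ diff + (diff @ diff) / (2 * step):
                break
            step *= 0.5
            if step < 1e-12:
                break
        t_next = 0.5 * (1 + np.sqrt(1 + 4 * t_mom**2))
        y = cand + ((t_mom - 1) / t_next) * (cand - lam)
        lam, t_mom = cand, t_next
        obj = smooth_loss(lam) + beta * np.abs(lam).sum()
        if prev_obj - obj < tol and prev_obj >= obj:
            converged = True
            break
        prev_obj = min(prev_obj, obj)

    if not converged:
        warnings.warn(
            f"maxent did not converge in {max_iter} iterations "
            f"(|grad| = {np.linalg.norm(smooth_grad(lam)):.3g})",
            stacklevel=2,
        )
    log_z = float(logsumexp(f_bg @ lam))
    model = MaxentModel(
        var_names=list(var_names),
        bg_mean=mean,
        bg_sd=sd,
        lambda_=lam,
        beta=beta,
        quadratic=quadratic,
        background=background,
        log_z=log_z,
        converged=converged,
        n_iter=it,
        objective=float(-(smooth_loss(lam)) - beta * np.abs(lam).sum()),
    )
    total = model.raw_scores(background).sum()
    if abs(total - 1.0) > 1e-6:
        raise DomainError(f"background normalization violated: sum = {total}")
    return model


def sample_background(grids, n_background: int = 10_000, seed=None):
    """Uniform sample of valid (non-nodata in every layer) cells.

    Returns (matrix DataFrame, (row, col) indices). All cells are used when
    fewer than ``n_background`` are valid.
    """
    grids = list(grids)
    base = grids[0]
    mask = np.ones_like(base.mask)
    for g in grids:
        if not base.same_extent(g):
            raise DomainError(f"grid extent mismatch: {g.name}")
        mask &= g.mask
    rows, cols = np.nonzero(mask)
    if len(rows) > n_background:
        rng = np.random.default_rng(seed)
        pick = np.sort(rng.choice(len(rows), size=n_background, replace=False))
        rows, cols = rows[pick], cols[pick]
    matrix = pd.DataFrame(
        {g.name: g.values[rows, cols] for g in grids}
    )
    return matrix, np.column_stack([rows, cols])


def predict_suitability(model: MaxentModel, grids, output: str = "raw") -> EnvGrid:
    """Per-cell suitability grid from a fitted model.

    ``raw`` is exp(lambda . f(x))/Z, normalized over the model's background
    reference; ``cumulative`` maps each cell to 100 x the summed raw value
    of all valid cells scoring at or below it. Nodata propagates.
    """
    grids = list(grids)
    names = [g.name for g in grids]
    if names != model.var_names:
        raise DomainError(
            f"grids {names} do not match model variables {model.var_names}"
        )
    base = grids[0]
    mask = np.ones_like(base.mask)
    for g in grids:
        mask &= g.mask
    rows, cols = np.nonzero(mask)
    X = np.column_stack([g.values[rows, cols] for g in grids])
    raw = model.raw_scores(X)
    if output == "cumulative":
        order = np.argsort(raw, kind="stable")
        csum = np.cumsum(raw[order])
        # cells with equal raw value share the highest cumulative sum
        out_sorted = np.empty_like(raw)
        i = 0
        while i < len(raw):
            j = i
            while j + 1 < len(raw) and raw[order[j + 1]] == raw[order[i]]:
                j += 1
            out_sorted[i : j + 1] = csum[j]
            i = j + 1
        scores = np.empty_like(raw)
        scores[order] = 100.0 * out_sorted
    elif output == "raw":
        scores = raw
    else:
        raise DomainError(f"unknown output transform: {output!r}")
    values = np.full(base.values.shape, base.nodata_value)
    values[rows, cols] = scores
    return EnvGrid(
        ncols=base.ncols,
        nrows=base.nrows,
        xllcorner=base.xllcorner,
        yllcorner=base.yllcorner,
        cellsize=base.cellsize,
        nodata_value=base.nodata_value,
        values=values,
        name=f"suitability_{output}",
    )


def auc(presence_scores, background_scores) -> float:
    """Rank-based AUC: probability a random presence outscores a random
    background cell; ties count one half."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size < 1 or b.size < 2:
        raise DomainError("need >=1 presence and >=2 background scores")
    labels = np.concatenate([np.ones(p.size), np.zeros(b.size)])
    return float(roc_auc_score(labels, np.concatenate([p, b])))


AUC_BANDS = (
    (0.5, "random"),
    (0.7, "poor"),
    (0.9, "moderate"),
    (np.inf, "good"),
)


def interpret_auc(value: float) -> str:
    """Band an AUC value: <0.5 random, [0.5,0.7) poor, [0.7,0.9) moderate,
    >=0.9 good."""
    if value < 0.5:
        return "random"
    if value < 0.7:
        return "poor"
    if value < 0.9:
        return "moderate"
    return "good"


@dataclass
class SDMEval:
    """Train/test AUC with the banding of the test value."""

    train_auc: float
    test_auc: float
    band: str
    test_fraction: float

    def to_dict(self):
        return {
            "train_auc": self.train_auc,
            "test_auc": self.test_auc,
            "band": self.band,
            "test_fraction": self.test_fraction,
        }


def evaluate(model: MaxentModel, train_X, test_X, background_X,
             test_fraction: float = 0.25) -> SDMEval:
    """Score train and test presences against the background."""
    bg_scores = model.raw_scores(background_X)
    train_auc = auc(model.raw_scores(train_X), bg_scores)
    test_auc = auc(model.raw_scores(test_X), bg_scores)
    return SDMEval(
        train_auc=train_auc,
        test_auc=test_auc,
        band=interpret_auc(test_auc),
        test_fraction=test_fraction,
    )


def jackknife_importance(
    train_X: pd.DataFrame,
    test_X: pd.DataFrame,
    background_X: pd.DataFrame,
    beta: float = 1.0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-variable with-only / without test AUC, ranked by ``auc_only``.

    Each variable is fitted alone (``auc_only``) and excluded
    (``auc_without``) on the training presences; both models are scored on
    the test presences. Requires at least two variables.
    """
    cols = list(train_X.columns)
    if len(cols) < 2:
        raise DomainError("jackknife needs at least 2 variables")
    rows = []
    for c in cols:
        only = fit_maxent(train_X[[c]], background_X[[c]], beta=beta,
                          max_iter=max_iter, tol=tol)
        auc_only = auc(
            only.raw_scores(test_X[[c]]), only.raw_scores(background_X[[c]])
        )
        others = [o for o in cols if o != c]
        without = fit_maxent(train_X[others], background_X[others], beta=beta,
                             max_iter=max_iter, tol=tol)
        auc_without = auc(
            without.raw_scores(test_X[others]),
            without.raw_scores(background_X[others]),
        )
        rows.append({"variable": c, "auc_only": auc_only,
                     "auc_without": auc_without})
    df = pd.DataFrame(rows).sort_values(
        ["auc_only", "variable"], ascending=[False, True]
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)
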
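"""Resource-selection functions and abundance extrapolation.

An exponential RSF, score(x) = exp(beta' x) without intercept, is
fitted by used-available logistic regression on standardized
covariates. Scores over the landscape are max-scaled into (0, 1],
reclassified into 10 equal-width bins, and the relative probability of
use of bin i is

    U(x_i) = w(x_i) A(x_i) / sum_j w(x_j) A(x_j)

with w the bin midpoint and A the bin area. Anchored on a reference
area assumed at carrying capacity with an independent abundance
estimate N-hat, bin abundance is N_i = N-hat * U(x_i) and density
D_i = N_i / A(x_i); CIs substitute the reference CI bounds for N-hat.
Predictive skill is measured by repeated k-fold cross-validation with
Spearman rank correlation between bin rank and area-adjusted
frequencies of withheld used points.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import spearmanr
from shapely.geometry import Point, Polygon

_SEPARATION_BOUND = 30.0  # |coef| beyond this on a standardized scale


# ---------------------------------------------------------------------------
# model


@dataclass
class RSFModel:
    """Fitted used-available RSF.

    ``coef`` is indexed by design-column name and includes the
    intercept, which the score function ignores; standardization
    constants are stored so fit-time and predict-time designs match.
    """

    terms: tuple
    coef: pd.Series
    means: pd.Series
    sds: pd.Series
    aic: float
    se: pd.Series | None = None
    converged: bool = True
    name: str = ""

    @property
    def n_params(self) -> int:
        return len(self.coef)

    def design(self, df: pd.DataFrame, intercept: bool = True) -> pd.DataFrame:
        X = _build_design(df, self.terms)
        for col in self.means.index:
            X[col] = (X[col] - self.means[col]) / self.sds[col]
        if intercept:
            X.insert(0, "const", 1.0)
        missing = set(self.coef.index) - {"const"} - set(X.columns)
        if missing:
            raise ValueError(f"covariates missing at predict time: {missing}")
        return X

    def score(self, df: pd.DataFrame) -> np.ndarray:
        """Exponential RSF score exp(beta' x), intercept excluded."""
        X = self.design(df, intercept=False)
        beta = self.coef.drop("const")
        return np.exp(X[beta.index].to_numpy(float) @ beta.to_numpy(float))


def _build_design(df: pd.DataFrame, terms) -> pd.DataFrame:
    cols = {}
    for term in terms:
        if term == "tenure":
            ten = df["tenure"].to_numpy()
            for level in ("private", "crown"):  # reference: protected
                cols[f"tenure[{level}]"] = (ten == level).astype(float)
        else:
            if term not in df.columns:
                raise ValueError(f"covariate {term!r} missing from data")
            cols[term] = df[term].to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def fit_rsf(used: pd.DataFrame, available: pd.DataFrame, terms) -> RSFModel:
    """Maximum-likelihood logistic fit of used (1) vs available (0).

    Continuous covariates are standardized to mean 0, sd 1 on the
    pooled design; categorical indicator columns are left as is.
    Complete separation and rank deficiency raise errors naming the
    offending covariate(s).
    """
    if used.empty or available.empty:
        raise ValueError("both used and available points are required")
    terms = tuple(terms)
    pooled = pd.concat([used, available], ignore_index=True)
    X = _build_design(pooled, terms)
    cont = [
        c for c in X.columns
        if not c.startswith("tenure[") and X[c].nunique() > 2
    ]
    means = X[cont].mean()
    sds = X[cont].std(ddof=0)
    zero = sds[sds == 0].index.tolist()
    if zero:
        raise ValueError(f"constant covariate(s) cannot be standardized: {zero}")
    for c in cont:
        X[c] = (X[c] - means[c]) / sds[c]
    Xd = sm.add_constant(X, prepend=True)
    if np.linalg.matrix_rank(Xd.to_numpy(float)) < Xd.shape[1]:
        raise ValueError(f"rank-deficient design for terms {terms}")
    y = np.r_[np.ones(len(used)), np.zeros(len(available))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        except Exception as exc:
            raise ValueError(f"logistic fit failed for terms {terms}: {exc}")
    coef = pd.Series(res.params, index=Xd.columns)
    runaway = coef.drop("const").abs()
    if (runaway > _SEPARATION_BOUND).any() or not np.isfinite(coef).all():
        bad = runaway[runaway > _SEPARATION_BOUND].index.tolist()
        raise ValueError(f"complete separation on covariate(s) {bad}")
    return RSFModel(
        terms=terms,
        coef=coef,
        means=means,
        sds=sds,
        aic=float(res.aic),
        se=pd.Series(res.bse, index=Xd.columns),
        converged=bool(res.mle_retvals.get("converged", True)),
    )


def select_rsf(
    candidates: dict, used: pd.DataFrame, available: pd.DataFrame
) -> tuple[RSFModel, pd.DataFrame]:
    """Fit all candidate formulas and pick the minimum-AIC model.

    ``candidates`` maps model name -> term tuple. Ties resolve in
    favor of fewer parameters. Returns (best model, AIC table).
    """
    fits, rows = {}, []
    for name, terms in candidates.items():
        try:
            model = fit_rsf(used, available, terms)
        except ValueError as exc:
            rows.append({"model": name, "K": np.nan, "AIC": np.nan,
                         "error": str(exc)})
            continue
        model.name = name
        fits[name] = model
        rows.append({"model": name, "K": model.n_params, "AIC": model.aic,
                     "error": ""})
    if not fits:
        raise ValueError("all candidate RSF models failed")
    tab = pd.DataFrame(rows)
    ok = tab.dropna(subset=["AIC"]).copy()
    ok["dAIC"] = ok["AIC"] - ok["AIC"].min()
    tab = tab.merge(ok[["model", "dAIC"]], on="model", how="left")
    tab = tab.sort_values(["AIC", "K"], kind="mergesort").reset_index(drop=True)
    best_name = ok.sort_values(["AIC", "K"], kind="mergesort")["model"].iloc[0]
    return fits[best_name], tab


# ---------------------------------------------------------------------------
# availability sampling


def sample_available(
    domain: Polygon, n_used: int, ratio: int, seed: int = 0
) -> np.ndarray:
    """Uniform random points inside `domain`: n_used * ratio of them."""
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    if domain.is_empty or domain.area <= 0:
        raise ValueError("degenerate availability domain")
    n = n_used * ratio
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = domain.bounds
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(int((n - filled) * 2.5), 64)
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = np.fromiter(
            (domain.contains(Point(p)) for p in cand), bool, count=m
        )
        good = cand[keep]
        take = min(n - filled, len(good))
        out[filled: filled + take] = good[:take]
        filled += take
    return out


# ---------------------------------------------------------------------------
# binning and extrapolation


@dataclass
class BinTable:
    """Ten-bin reclassification of max-scaled RSF scores.

    ``table`` columns: bin (1..n), lo, hi, w (midpoint), n_cells,
    A (km^2), and after `expected_use` also U. ``bin_of_cell`` holds
    each input cell's 1-based bin index.
    """

    table: pd.DataFrame
    bin_of_cell: np.ndarray
    n_bins: int = 10
    meta: dict = field(default_factory=dict)


def bin_scores(scores, cell_area, n_bins: int = 10) -> BinTable:
    """Scale scores by their maximum into (0, 1] and cut into
    equal-width bins; w(x_i) is the bin midpoint, A(x_i) the summed
    cell area. ``cell_area`` is scalar (uniform cells) or per-cell."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no cells to bin")
    if not np.all(np.isfinite(scores)) or scores.max() <= 0:
        raise ValueError("scores must be finite with a positive maximum")
    areas = np.broadcast_to(np.asarray(cell_area, dtype=float), scores.shape)
    scaled = scores / scores.max()
    idx = np.minimum((scaled * n_bins).astype(int), n_bins - 1) + 1
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    rows = []
    for b in range(1, n_bins + 1):
        in_bin = idx == b
        rows.append(
            {
                "bin": b,
                "lo": edges[b - 1],
                "hi": edges[b],
                "w": 0.5 * (edges[b - 1] + edges[b]),
                "n_cells": int(in_bin.sum()),
                "A": float(areas[in_bin].sum()),
            }
        )
    return BinTable(pd.DataFrame(rows), idx, n_bins)


def expected_use(bins: BinTable) -> BinTable:
    """Attach U(x_i) = w A / sum(w A); U sums to one."""
    tab = bins.table.copy()
    wa = tab["w"] * tab["A"]
    total = wa.sum()
    if total <= 0:
        raise ValueError("sum of w(x_i) A(x_i) is zero")
    tab["U"] = wa / total
    return BinTable(tab, bins.bin_of_cell, bins.n_bins, dict(bins.meta))


def bins_within(bins: BinTable, keep: np.ndarray, cell_area) -> BinTable:
    """Recompute bin cell counts and areas over the cells in ``keep``,
    retaining the global bin edges and midpoints (e.g. to restrict a
    domain-wide binning to the reference area)."""
    keep = np.asarray(keep, dtype=bool)
    areas = np.broadcast_to(
        np.asarray(cell_area, dtype=float), bins.bin_of_cell.shape
    )
    tab = bins.table.copy()
    sub = bins.bin_of_cell[keep]
    sub_area = areas[keep]
    tab["n_cells"] = [int((sub == b).sum()) for b in tab["bin"]]
    tab["A"] = [float(sub_area[sub == b].sum()) for b in tab["bin"]]
    if "U" in tab.columns:
        tab = tab.drop(columns="U")
    return BinTable(tab, sub, bins.n_bins, dict(bins.meta))


def area_of_inference(bins: BinTable, drop_lowest: int = 3) -> np.ndarray:
    """Boolean cell mask keeping bins above the `drop_lowest` lowest.

    The lowest-score bins are interpreted as outside the region the
    selection model can speak to.
    """
    if drop_lowest >= bins.n_bins:
        raise ValueError("cannot drop every bin")
    return bins.bin_of_cell > drop_lowest


@dataclass
class ReferenceEstimate:
    """Independent density estimate for the reference area, per
    1,000 km^2, with its 95% CI and the reference area in km^2."""

    density: float
    lo: float
    hi: float
    area_km2: float

    def __post_init__(self):
        if not self.lo <= self.density <= self.hi:
            raise ValueError("reference CI must bracket the point estimate")

    @property
    def nhat(self) -> float:
        return self.density * self.area_km2 / 1000.0

    @property
    def nhat_lo(self) -> float:
        return self.lo * self.area_km2 / 1000.0

    @property
    def nhat_hi(self) -> float:
        return self.hi * self.area_km2 / 1000.0


def bin_densities(reference: ReferenceEstimate, ref_bins: BinTable) -> pd.DataFrame:
    """Per-bin abundance and density within the reference area.

    N_i = N-hat * U(x_i), D_i = N_i / A(x_i) (bears/km^2); lo/hi
    columns substitute the reference CI bounds for N-hat.
    """
    tab = ref_bins.table
    if "U" not in tab.columns:
        tab = expected_use(ref_bins).table
    out = tab[["bin", "w", "A", "U"]].copy()
    for label, nhat in (
        ("", reference.nhat), ("_lo", reference.nhat_lo),
        ("_hi", reference.nhat_hi),
    ):
        out[f"N{label}"] = nhat * out["U"]
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"D{label}"] = np.where(
                out["A"] > 0, out[f"N{label}"] / out["A"], np.nan
            )
    return out


def extrapolate_density(
    reference: ReferenceEstimate,
    ref_bins: BinTable,
    target_bin: np.ndarray,
) -> pd.DataFrame:
    """Carry per-bin reference densities onto target cells by bin
    membership.

    Target cells in a bin unpopulated within the reference area take
    the nearest populated bin's density, with a warning. Returns a
    frame (bin, D, D_lo, D_hi) per target cell, bears/km^2.
    """
    per_bin = bin_densities(reference, ref_bins).set_index("bin")
    populated = per_bin.index[per_bin["A"] > 0].to_numpy()
    if populated.size == 0:
        raise ValueError("reference area has no populated bins")
    target_bin = np.asarray(target_bin, dtype=int)
    lookup = target_bin.copy()
    absent = ~np.isin(target_bin, populated)
    if absent.any():
        warnings.warn(
            f"{int(absent.sum())} target cells fall in bins unpopulated in "
            "the reference area; using nearest populated bin"
        )
        for b in np.unique(target_bin[absent]):
            nearest = populated[np.argmin(np.abs(populated - b))]
            lookup[target_bin == b] = nearest
    out = per_bin.loc[lookup, ["D", "D_lo", "D_hi"]].reset_index(drop=True)
    out.insert(0, "bin", target_bin)
    return out


def region_density(
    cell_density: pd.DataFrame, cell_area, regions
) -> pd.DataFrame:
    """Area-weighted mean density and summed abundance by region label."""
    regions = np.asarray(regions)
    areas = np.broadcast_to(
        np.asarray(cell_area, dtype=float), regions.shape
    )
    rows = []
    for region in pd.unique(regions):
        sel = regions == region
        a = areas[sel].sum()
        row = {"region": region, "area_km2": float(a)}
        for col in ("D", "D_lo", "D_hi"):
            d = float((cell_density[col].to_numpy()[sel] * areas[sel]).sum())
            row["nhat" + col[1:].replace("D", "")] = d
            row[col] = d / a
        rows.append(row)
    out = pd.DataFrame(rows)
    out = out.rename(columns={"nhat": "nhat", "nhat_lo": "nhat_lo",
                              "nhat_hi": "nhat_hi"})
    return out


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    coefficients: np.ndarray
    folds: int
    repeats: int
    seed: int

    @property
    def mean_rs(self) -> float:
        return float(np.nanmean(self.coefficients))


def kfold_cv(
    model: RSFModel,
    used: pd.DataFrame,
    cells: pd.DataFrame,
    cell_area,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    refit: bool = True,
    available: pd.DataFrame | None = None,
    area_adjust: bool = True,
    scores: np.ndarray | None = None,
    n_bins: int = 10,
) -> CVResult:
    """Repeated k-fold Spearman cross-validation of an RSF.

    Per repeat, used points are partitioned into ``folds`` folds; for
    each fold the model is refitted on the training folds (against
    ``available``; required when ``refit``), the domain ``cells`` are
    binned on the refitted scores, and withheld used points are
    tallied per bin. Bin rank is then correlated (Spearman) with the
    withheld-point frequency per bin, divided by bin area when
    ``area_adjust``. A repeat's coefficient is the mean over folds.

    With ``refit=False`` the supplied ``scores`` (or the model's own
    scores over ``cells``) are used unchanged, which evaluates a fixed
    score surface.
    """
    if len(used) < folds:
        raise ValueError("need at least `folds` used points")
    if refit and available is None:
        raise ValueError("refit=True requires available points")
    rng = np.random.default_rng(seed)
    coefs = np.empty(repeats)
    fixed_scores = None
    if not refit:
        fixed_scores = (
            np.asarray(scores, float) if scores is not None
            else model.score(cells)
        )
    for r in range(repeats):
        assign = rng.permutation(len(used)) % folds
        fold_rs = []
        for f in range(folds):
            test = used.iloc[assign == f]
            if test.empty:
                warnings.warn(f"fold {f} has no test points; skipped")
                continue
            if refit:
                train = used.iloc[assign != f]
                fold_model = fit_rsf(train, available, model.terms)
                cell_scores = fold_model.score(cells)
                test_scores = fold_model.score(test)
            else:
                fold_model = model
                cell_scores = fixed_scores
                test_scores = (
                    model.score(test) if scores is None
                    else np.asarray(scores, float)[
                        _nearest_cell(test, cells)
                    ]
                )
            bt = bin_scores(cell_scores, cell_area, n_bins)
            smax = cell_scores.max()
            tb = np.minimum(
                (test_scores / smax * n_bins).astype(int), n_bins - 1
            ) + 1
            tab = bt.table
            freq = np.bincount(tb, minlength=n_bins + 1)[1:].astype(float)
            nonempty = tab["A"].to_numpy() > 0
            if nonempty.sum() < 2:
                warnings.warn("fewer than two populated bins; fold skipped")
                continue
            f_adj = freq[nonempty]
            if area_adjust:
                f_adj = f_adj / tab["A"].to_numpy()[nonempty]
            rs = spearmanr(tab["bin"].to_numpy()[nonempty], f_adj).statistic
            fold_rs.append(rs)
        coefs[r] = np.nanmean(fold_rs) if fold_rs else np.nan
    return CVResult(coefs, folds, repeats, seed)


def _nearest_cell(points: pd.DataFrame, cells: pd.DataFrame) -> np.ndarray:
    from scipy.spatial import cKDTree

    tree = cKDTree(np.column_stack([cells["x"], cells["y"]]))
    _, idx = tree.query(np.column_stack([points["x"], points["y"]]))
    return idx
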
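"""Synthetic landscapes, detector arrays, bear populations, and captures.

The generator reproduces the statistical structure the estimators
assume: a tenure mosaic with continuous habitat covariates, activity
centers from a log-linear inhomogeneous Poisson process, and binary
per-occasion detections whose cumulative hazard follows the hazard
half-normal model with trap-type, behavioral (bk), time-trend (T), and
grizzly-bear (GB) effects.

Everything is deterministic given the config/seed.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimConfig, TrueParams
from .containers import (
    ActivityCenters,
    CaptureHistory,
    DetectorArray,
    MaskGrid,
    TENURE_LEVELS,
)

_LP_OVERFLOW = 50.0  # guard on the log-density linear predictor


# ---------------------------------------------------------------------------
# landscape


def _smooth_field(x, y, extent, rng, low, high):
    """Seeded sum of two harmonics rescaled to [low, high]."""
    w, h = extent
    a1, a2, b1, b2 = rng.uniform(0.5, 2.0, size=4)
    p1, p2 = rng.uniform(0.0, 2.0 * np.pi, size=2)
    raw = np.sin(2 * np.pi * (a1 * x / w + b1 * y / h) + p1) + np.sin(
        2 * np.pi * (a2 * x / w - b2 * y / h) + p2
    )
    lo, hi = raw.min(), raw.max()
    if hi - lo < 1e-12:
        return np.full_like(raw, 0.5 * (low + high))
    return low + (high - low) * (raw - lo) / (hi - lo)


def _random_segment(extent, rng):
    """A line segment crossing the extent between two random edge points."""
    w, h = extent
    sides = rng.choice(4, size=2, replace=False)
    pts = []
    for side in sides:
        t = rng.uniform()
        pts.append(
            [(t * w, 0.0), (t * w, h), (0.0, t * h), (w, t * h)][side]
        )
    return np.asarray(pts[0]), np.asarray(pts[1])


def _dist_to_segments(x, y, segments):
    d = np.full(x.shape, np.inf)
    p = np.column_stack([x, y])
    for a, b in segments:
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab)
        d = np.minimum(d, np.hypot(*(p - proj).T))
    return d


def generate_landscape(config: SimConfig) -> MaskGrid:
    """Build the gridded synthetic landscape with per-cell covariates.

    Tenure forms three contiguous blocks of columns (private | crown |
    protected, west to east) whose cell shares match the configured
    proportions up to column rounding. Continuous covariates follow the
    specs in ``config.covariates``.
    """
    w, h = config.extent
    s = config.cell_spacing
    if s <= 0:
        raise ValueError("cell spacing must be positive")
    nx, ny = int(round(w / s)), int(round(h / s))
    if nx < 1 or ny < 1:
        raise ValueError("extent too small for the requested spacing")
    cx = (np.arange(nx) + 0.5) * s
    cy = (np.arange(ny) + 0.5) * s
    gx, gy = np.meshgrid(cx, cy, indexing="ij")
    x, y = gx.ravel(), gy.ravel()

    rng = np.random.default_rng(config.seed)

    # tenure: contiguous column blocks matching the proportions
    p1, p2, _ = config.tenure_proportions
    c1 = int(round(p1 * nx))
    c2 = int(round((p1 + p2) * nx))
    col = (x / s - 0.5).round().astype(int)
    tenure = np.where(col < c1, TENURE_LEVELS[0],
                      np.where(col < c2, TENURE_LEVELS[1], TENURE_LEVELS[2]))

    cov = pd.DataFrame({"tenure": tenure})
    segments = []
    for name, spec in config.covariates.items():
        kind = spec["kind"]
        if kind == "smooth":
            cov[name] = _smooth_field(
                x, y, config.extent, rng, spec["low"], spec["high"]
            )
        elif kind == "patch":
            frac = spec["fraction"]
            if frac <= 0:
                cov[name] = np.zeros_like(x)
            else:
                cx0 = rng.uniform(0, w)
                cy0 = rng.uniform(0, h)
                radius = np.sqrt(frac * w * h / np.pi)
                inside = (x - cx0) ** 2 + (y - cy0) ** 2 <= radius**2
                cov[name] = inside.astype(float)
        elif kind == "tenure_levels":
            levels = spec["levels"]
            if min(levels.values()) < 0:
                raise ValueError(f"{name}: tenure levels must be >= 0")
            cov[name] = pd.Series(tenure).map(levels).to_numpy(float)
        elif kind == "lndist":
            segs = [_random_segment(config.extent, rng)
                    for _ in range(spec["n_lines"])]
            segments.extend(segs)
            cov[name] = np.log(_dist_to_segments(x, y, segs) + 0.1)
        else:
            raise ValueError(f"unknown covariate kind {kind!r} for {name!r}")

    meta = {"extent": config.extent, "lines": segments, "seed": config.seed}
    return MaskGrid(x, y, s, cov, meta)


# ---------------------------------------------------------------------------
# detectors


def place_detectors(
    landscape: MaskGrid, config: SimConfig, bias_linear: bool = True
) -> DetectorArray:
    """Place rub, fence, and opportunistic detectors on the landscape.

    Rub and fence detectors are jittered points along the landscape's
    synthetic linear features when ``bias_linear`` (surveys follow
    roads, trails and fence lines); otherwise uniform over the extent.
    Opportunistic detectors sit at the centroids of ``opp_cell_size``
    squares tiling the extent and are active only on the final
    occasion; rub/fence detectors are active on all earlier occasions.
    """
    w, h = landscape.meta.get("extent", (landscape.x.max(), landscape.y.max()))
    S = config.n_occasions
    if config.n_rub + config.n_fence > landscape.n_cells:
        raise ValueError("more detectors requested than landscape cells")
    rng = np.random.default_rng(landscape.meta.get("seed", config.seed) + 1)
    segments = landscape.meta.get("lines", [])

    def _linear_points(n):
        if n == 0:
            return np.empty((0, 2))
        if not (bias_linear and segments):
            return rng.uniform((0, 0), (w, h), size=(n, 2))
        lengths = np.array([np.hypot(*(b - a)) for a, b in segments])
        pick = rng.choice(len(segments), size=n, p=lengths / lengths.sum())
        t = rng.uniform(size=n)
        pts = np.array(
            [segments[i][0] + ti * (segments[i][1] - segments[i][0])
             for i, ti in zip(pick, t)]
        )
        pts += rng.normal(scale=0.3, size=pts.shape)
        return np.clip(pts, [0, 0], [w, h])

    xs, ys, types = [], [], []
    for n, ttype in ((config.n_rub, "rub"), (config.n_fence, "fence")):
        pts = _linear_points(n)
        xs.append(pts[:, 0])
        ys.append(pts[:, 1])
        types.extend([ttype] * n)

    # opportunistic grid centroids tiling the extent
    c = config.opp_cell_size
    nxo, nyo = int(np.ceil(w / c)), int(np.ceil(h / c))
    ox = (np.arange(nxo) + 0.5) * c
    oy = (np.arange(nyo) + 0.5) * c
    ogx, ogy = np.meshgrid(ox, oy, indexing="ij")
    xs.append(ogx.ravel())
    ys.append(ogy.ravel())
    n_opp = ogx.size
    types.extend(["opp"] * n_opp)

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    det_type = np.asarray(types)
    K = x.size
    ids = np.array([f"{t}{i:04d}" for i, t in enumerate(det_type)])

    usage = np.zeros((K, S), dtype=np.int8)
    systematic = det_type != "opp"
    usage[systematic, : S - 1] = 1
    usage[~systematic, S - 1] = 1
    if S == 1:  # degenerate single-occasion design: everything active
        usage[:, 0] = 1

    cover_levels = np.array(
        ["deciduous", "coniferous", "shrub", "grassland",
         "agriculture", "mixed", "barren"]
    )
    cover = rng.choice(cover_levels, size=K)
    gb = (rng.uniform(size=(K, S)) < 0.15).astype(np.int8)
    gb[det_type == "opp"] = 0

    return DetectorArray(
        ids, x, y, det_type, usage,
        covariates=pd.DataFrame({"cover": cover}),
        time_varying={"GB": gb},
    )


# ---------------------------------------------------------------------------
# population


def density_surface(landscape: MaskGrid, truth: TrueParams) -> np.ndarray:
    """Per-cell density D(x) = exp(z(x)' beta_D), bears/km^2."""
    lp = np.full(landscape.n_cells, truth.density_intercept, dtype=float)
    cov = landscape.covariates
    for key, beta in truth.density_beta.items():
        if key.startswith("tenure:"):
            level = key.split(":", 1)[1]
            z = (cov["tenure"].to_numpy() == level).astype(float)
        else:
            if key not in cov.columns:
                raise ValueError(f"density covariate {key!r} not on landscape")
            z = cov[key].to_numpy(float)
        lp = lp + beta * z
    if np.any(lp > _LP_OVERFLOW):
        raise OverflowError("density linear predictor exceeds overflow guard")
    return np.exp(lp)


def simulate_population(
    landscape: MaskGrid, truth: TrueParams, seed: int | None = None
) -> ActivityCenters:
    """Draw activity centers from the inhomogeneous Poisson process.

    Cell counts are Poisson with mean D(x) * a; centers are uniform
    within their cell.
    """
    if seed is None:
        seed = landscape.meta.get("seed", 0) + 2
    rng = np.random.default_rng(seed)
    dens = density_surface(landscape, truth)
    a = landscape.cell_area
    counts = rng.poisson(dens * a)
    total = int(counts.sum())
    half = landscape.spacing / 2.0
    reps = np.repeat(np.arange(landscape.n_cells), counts)
    x = landscape.x[reps] + rng.uniform(-half, half, size=total)
    y = landscape.y[reps] + rng.uniform(-half, half, size=total)
    return ActivityCenters(x, y, np.full(total, truth.sex))


# ---------------------------------------------------------------------------
# captures


def simulate_captures(
    centers: ActivityCenters,
    detectors: DetectorArray,
    truth: TrueParams,
    seed: int = 3,
) -> CaptureHistory:
    """Simulate binary detections under the hazard half-normal model.

    Per animal i, detector k, occasion s with usage:
    p = 1 - exp(-lambda0_iks * exp(-d_ik^2 / (2 sigma_ks^2))) where
    lambda0 carries trap-type, T, GB, and (once the animal has been
    detected at k on an earlier occasion) bk effects. Animals never
    detected are dropped from the returned history; the realized and
    detected totals are kept in ``meta``.
    """
    if detectors.usage is None or detectors.usage.size == 0:
        raise ValueError("detector array has no usage matrix")
    K, S = detectors.usage.shape
    N = centers.n_true
    rng = np.random.default_rng(seed)

    tt_l0 = np.array(
        [truth.beta_traptype.get(t, 0.0) if t != "rub" else 0.0
         for t in detectors.det_type]
    )
    tt_sig = np.array(
        [truth.sigma_beta_traptype.get(t, 0.0) if t != "rub" else 0.0
         for t in detectors.det_type]
    )
    gb = detectors.time_varying.get("GB", np.zeros((K, S)))

    d2 = (
        (centers.x[:, None] - detectors.x[None, :]) ** 2
        + (centers.y[:, None] - detectors.y[None, :]) ** 2
    )  # (N, K)

    omega = np.zeros((N, K, S), dtype=np.uint8)
    bk = np.zeros((N, K), dtype=bool)
    for s in range(S):
        active = detectors.usage[:, s] == 1
        if not active.any():
            continue
        log_l0 = (
            np.log(truth.lambda0)
            + tt_l0[None, :]
            + truth.beta_T * s
            + truth.beta_GB * gb[:, s][None, :]
            + truth.beta_bk * bk
        )  # (N, K)
        sig = truth.sigma * np.exp(tt_sig + truth.sigma_beta_T * s)  # (K,)
        lam = np.exp(log_l0 - d2 / (2.0 * sig[None, :] ** 2))
        p = -np.expm1(-lam)
        p[:, ~active] = 0.0
        hits = rng.uniform(size=(N, K)) < p
        omega[:, :, s] = hits
        bk |= hits  # behavioral response kicks in from the next occasion

    detected = omega.any(axis=(1, 2))
    ids = np.array([f"{truth.sex}{i:05d}" for i in range(N)])
    history = CaptureHistory(
        ids[detected],
        np.full(int(detected.sum()), truth.sex),
        omega[detected],
        meta={"n_simulated": N, "n_detected": int(detected.sum())},
    )
    return history
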
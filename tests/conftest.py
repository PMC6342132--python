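import warnings

import numpy as np
import pandas as pd
import pytest

import beardensity as bd
from beardensity.pipeline import RunConfig


# ---------------------------------------------------------------------------
# shared builders


def trap_grid(n_side=10, spacing=2.0, origin=20.0, n_occasions=7):
    """Rectangular grid of rub detectors active on every occasion."""
    nx, ny = (n_side, n_side) if np.isscalar(n_side) else n_side
    gx, gy = np.meshgrid(
        np.arange(nx) * spacing + origin,
        np.arange(ny) * spacing + origin,
        indexing="ij",
    )
    k = nx * ny
    return bd.DetectorArray(
        np.array([f"d{i}" for i in range(k)]),
        gx.ravel(),
        gy.ravel(),
        np.full(k, "rub"),
        np.ones((k, n_occasions), dtype=np.int8),
    )


def flat_truth(d=0.05, lam0=0.1, sigma=2.0, sex="F", **kw):
    return bd.TrueParams(
        density_intercept=np.log(d),
        density_beta={},
        lambda0=lam0,
        beta_traptype={},
        beta_bk=kw.pop("beta_bk", 0.0),
        sigma=sigma,
        sigma_beta_traptype={},
        sex=sex,
        **kw,
    )


def uniform_population(mask, density, rng, sex="F"):
    """Poisson population at constant density over a mask's cells."""
    n = rng.poisson(density * mask.total_area)
    half = mask.spacing / 2
    cells = rng.integers(0, mask.n_cells, size=n)
    x = mask.x[cells] + rng.uniform(-half, half, n)
    y = mask.y[cells] + rng.uniform(-half, half, n)
    return bd.ActivityCenters(x, y, np.full(n, sex))


def recovery_replicate(seed, n_side=10, spacing=2.0, n_occasions=7,
                       d=0.05, lam0=0.1, sigma=2.0, buffer=6.0,
                       mask_spacing=2.0):
    """Simulate one flat-density dataset on a trap grid and fit D~1."""
    rng = np.random.default_rng(seed)
    det = trap_grid(n_side, spacing, n_occasions=n_occasions)
    mask = bd.build_mask(det, buffer, mask_spacing)
    pop = uniform_population(mask, d, rng)
    truth = flat_truth(d, lam0, sigma)
    hist = bd.simulate_captures(pop, det, truth, seed=seed + 100_000)
    if hist.n_individuals < 5:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = bd.fit_secr(
            bd.ObservationModel((), ()), bd.DensityModel(()),
            hist, det, mask, seed=seed, n_starts=1,
        )
    return fit


def tiny_instance(rng, max_cells=3, max_traps=3, n_occasions=2):
    """Random small SECR instance for oracle comparisons."""
    M = int(rng.integers(1, max_cells + 1))
    K = int(rng.integers(1, max_traps + 1))
    S = n_occasions
    mask_xy = rng.uniform(0, 5, size=(M, 2))
    det_xy = rng.uniform(0, 5, size=(K, 2))
    det_type = rng.choice(["rub", "fence", "opp"], size=K)
    usage = rng.integers(0, 2, size=(K, S))
    usage[0, :] = 1
    gb = rng.integers(0, 2, size=(K, S))
    n = int(rng.integers(1, 4))
    omega = (rng.uniform(size=(n, K, S)) < 0.4).astype(np.uint8) * usage[None]
    omega[:, 0, 0] = 1  # every animal detected at least once
    tenure = rng.choice(["private", "crown", "protected"], size=M)
    mask = bd.MaskGrid(
        mask_xy[:, 0], mask_xy[:, 1], 1.3, pd.DataFrame({"tenure": tenure})
    )
    det = bd.DetectorArray(
        np.array([f"d{k}" for k in range(K)]),
        det_xy[:, 0], det_xy[:, 1], det_type, usage,
        time_varying={"GB": gb},
    )
    hist = bd.CaptureHistory(
        np.array([f"a{i}" for i in range(n)]), np.full(n, "F"), omega
    )
    return mask, det, hist, gb, tenure


# ---------------------------------------------------------------------------
# bundled pipeline fixture (small, end-to-end)


def fixture_config(seed=11) -> RunConfig:
    sim = bd.SimConfig(
        extent=(36.0, 36.0), cell_spacing=2.0, n_rub=40, n_fence=8,
        opp_cell_size=12.0, n_occasions=6, seed=seed,
    )
    truth = {
        "F": bd.TrueParams(
            density_intercept=np.log(0.10),
            density_beta={"tenure:private": -0.3, "tenure:crown": -0.8},
            lambda0=0.12, beta_bk=0.5, sigma=2.2, sex="F",
        ),
        "M": bd.TrueParams(
            density_intercept=np.log(0.08),
            density_beta={"tenure:private": -0.3, "tenure:crown": -0.8},
            lambda0=0.15, beta_bk=0.5, sigma=3.0, sex="M",
        ),
    }
    return RunConfig(
        sim=sim,
        truth=truth,
        sexes=("F", "M"),
        mask_spacing=2.5,
        step1_candidates=[
            bd.ObservationModel((), ()), bd.ObservationModel(("bk",), ()),
        ],
        step2_candidates=[bd.DensityModel(()), bd.DensityModel(("tenure",))],
        rsf_candidates={
            "tenure+ndvi": ("tenure", "ndvi"), "ndvi": ("ndvi",),
        },
    )


@pytest.fixture(scope="session")
def pipeline_runs(tmp_path_factory):
    """The bundled fixture pipeline, run twice with identical config."""
    cfg = fixture_config()
    out_a = tmp_path_factory.mktemp("run_a")
    out_b = tmp_path_factory.mktemp("run_b")
    report = bd.run_pipeline(cfg, out_a)
    bd.run_pipeline(fixture_config(), out_b)
    return cfg, out_a, out_b, report
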
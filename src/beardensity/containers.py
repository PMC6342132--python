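"""In-memory containers shared across the simulation and estimation modules.

Coordinates are planar kilometres throughout; all distances are Euclidean.
No CRS is attached: the study geometry is small enough that a local
projected plane is adequate, and re-projection is the caller's job.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Detector categories: barbed-wire rub objects (trees, power poles,
#: fenceposts), fence lines, and gridded opportunistic cells.
TRAP_TYPES = ("rub", "fence", "opp")

#: Land-tenure levels; "protected" is the reference level in density models.
TENURE_LEVELS = ("private", "crown", "protected")


@dataclass
class MaskGrid:
    """A square-lattice habitat grid: mask cells with per-cell covariates.

    Serves both as the synthetic landscape and as the SECR habitat mask
    (the discretized region of integration for activity centers).

    Parameters
    ----------
    x, y : arrays of cell centroid coordinates (km).
    spacing : lattice spacing (km); cell area is ``spacing ** 2``.
    covariates : DataFrame aligned with the cells (one row per cell).
        Categorical columns (e.g. ``tenure``) keep their labels.
    meta : free-form metadata (extent, generating config, linear features).
    """

    x: np.ndarray
    y: np.ndarray
    spacing: float
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.spacing <= 0:
            raise ValueError("mask spacing must be positive")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.covariates) not in (0, self.n_cells):
            raise ValueError(
                f"covariate table has {len(self.covariates)} rows "
                f"for {self.n_cells} cells"
            )
        if len(self.covariates) and self.covariates.isna().any().any():
            bad = self.covariates.columns[self.covariates.isna().any()].tolist()
            raise ValueError(f"covariate columns contain missing values: {bad}")

    @property
    def n_cells(self) -> int:
        return self.x.size

    @property
    def cell_area(self) -> float:
        """Cell area *a* in km^2."""
        return self.spacing**2

    @property
    def total_area(self) -> float:
        return self.n_cells * self.cell_area

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def with_covariates(self, extra: pd.DataFrame) -> "MaskGrid":
        """Return a new grid with additional covariate columns attached."""
        cov = self.covariates.reset_index(drop=True)
        merged = pd.concat([cov, extra.reset_index(drop=True)], axis=1)
        return MaskGrid(self.x, self.y, self.spacing, merged, dict(self.meta))


@dataclass
class DetectorArray:
    """Detector locations with usage and detector-level covariates.

    ``usage`` is a 0/1 matrix (detector x occasion): rub and fence
    detectors are typically active on the systematic occasions only,
    opportunistic grid cells only on the final occasion.

    ``time_varying`` holds per-occasion detector covariates, e.g. ``GB``
    (grizzly bear detected at the site during the previous occasion).
    """

    ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    det_type: np.ndarray
    usage: np.ndarray
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)
    time_varying: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.det_type = np.asarray(self.det_type)
        self.usage = np.asarray(self.usage, dtype=np.int8)
        if len(set(self.ids.tolist())) != self.n_detectors:
            raise ValueError("detector ids must be unique")
        if self.usage.ndim != 2 or self.usage.shape[0] != self.n_detectors:
            raise ValueError("usage must be a (n_detectors, n_occasions) matrix")
        bad = set(self.det_type.tolist()) - set(TRAP_TYPES)
        if bad:
            raise ValueError(f"unknown detector types: {sorted(bad)}")
        for name, arr in self.time_varying.items():
            arr = np.asarray(arr)
            if arr.shape != self.usage.shape:
                raise ValueError(
                    f"time-varying covariate {name!r} must match usage shape"
                )
            self.time_varying[name] = arr

    @property
    def n_detectors(self) -> int:
        return self.ids.size

    @property
    def n_occasions(self) -> int:
        return self.usage.shape[1]

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class CaptureHistory:
    """Binary detections omega[i, k, s]: individual x detector x occasion."""

    ids: np.ndarray
    sex: np.ndarray
    detections: np.ndarray
    session: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.sex = np.asarray(self.sex)
        self.detections = np.asarray(self.detections, dtype=np.uint8)
        if self.detections.ndim != 3:
            raise ValueError("detections must be (n, n_detectors, n_occasions)")
        if self.detections.shape[0] != self.ids.size:
            raise ValueError("one id per individual required")
        if self.sex.size != self.ids.size:
            raise ValueError("one sex label per individual required")

    @property
    def n_individuals(self) -> int:
        return self.ids.size

    @property
    def n_detections(self) -> int:
        return int(self.detections.sum())

    def check_usage(self, detectors: DetectorArray) -> None:
        """Raise if any detection falls on a detector-occasion with no effort."""
        if self.detections.shape[1:] != detectors.usage.shape:
            raise ValueError("history and detector array shapes disagree")
        if (self.detections.sum(axis=0) * (1 - detectors.usage)).any():
            raise ValueError("detections present where usage is zero")

    def subset(self, keep: np.ndarray) -> "CaptureHistory":
        return CaptureHistory(
            self.ids[keep], self.sex[keep], self.detections[keep],
            self.session, dict(self.meta),
        )


@dataclass
class ActivityCenters:
    """Realized activity (home-range) centers of a simulated population."""

    x: np.ndarray
    y: np.ndarray
    sex: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.sex = np.asarray(self.sex)

    @property
    def n_true(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])
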
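"""Null simulation and probability maps for the SMART-observation plot.

Fitting thousands of subset models invites false positives.  To
calibrate, the entire scan is recomputed many times with the metabolite
data replaced by independent standard-normal draws while the (ttd, tbs)
coordinates — and therefore the subset geometry — stay fixed.  Each
replicate yields a significant-subset density raster; comparing the
observed raster against the per-cell empirical null distribution gives
the probability of reaching the observed density by chance, reported at
six discrete levels (">0.20" down to "<0.001").
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from smartscan.errors import SmartError
from smartscan.opls import cross_validate
from smartscan.scan import (
    DensityMap,
    ScanSettings,
    _raster_axes,
    build_grid,
    hotelling_ellipse,
    select_subset,
)

LEVELS = ((0.001, "<0.001"), (0.01, "<0.01"), (0.05, "<0.05"), (0.10, "<0.10"), (0.20, "<0.20"))
LEVEL_ABOVE = ">0.20"


@dataclass
class SubsetGeometry:
    """Scan geometry reusable across replicates: members + coverage masks."""

    member_idx: list[np.ndarray]
    covers: np.ndarray  # (n_subsets, n_cells) boolean
    ttd_centers: np.ndarray
    tbs_centers: np.ndarray
    settings: ScanSettings

    @property
    def n_subsets(self) -> int:
        return len(self.member_idx)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.tbs_centers), len(self.ttd_centers))


@dataclass
class NullDistribution:
    """Per-cell empirical null densities from repeated random-data scans."""

    densities: np.ndarray  # (n_reps, n_tbs, n_ttd), uint16
    ttd_centers: np.ndarray
    tbs_centers: np.ndarray
    seed: int
    settings: ScanSettings

    @property
    def n_reps(self) -> int:
        return len(self.densities)

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path, densities=self.densities, ttd_centers=self.ttd_centers,
            tbs_centers=self.tbs_centers, seed=self.seed,
        )

    @classmethod
    def load(cls, path: str | Path, settings: ScanSettings | None = None) -> "NullDistribution":
        with np.load(path) as z:
            return cls(
                densities=z["densities"], ttd_centers=z["ttd_centers"],
                tbs_centers=z["tbs_centers"], seed=int(z["seed"]),
                settings=settings or ScanSettings(),
            )


@dataclass
class ProbabilityMap:
    """Observed density converted to per-cell null probabilities."""

    ttd_centers: np.ndarray
    tbs_centers: np.ndarray
    p_hat: np.ndarray
    levels: np.ndarray  # string labels, same shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p_hat, index=self.tbs_centers, columns=self.ttd_centers)

    def level_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.levels, index=self.tbs_centers, columns=self.ttd_centers)


def subset_geometry(
    coords: np.ndarray,
    settings: ScanSettings | None = None,
    raster_step: float = 0.25,
) -> SubsetGeometry:
    """Precompute unique subsets and their ellipse coverage masks.

    Only coordinates matter: the same geometry serves the observed scan
    and every null replicate.
    """
    if settings is None:
        settings = ScanSettings()
    coords = np.asarray(coords, dtype=float)
    grid = build_grid(coords, settings.step)
    k = min(settings.k, len(coords))
    seen: dict[tuple[int, ...], np.ndarray] = {}
    for anchor in grid:
        for weight in settings.weights:
            idx = select_subset(anchor, weight, coords, k=k)
            seen.setdefault(tuple(idx), idx)
    ttd_c, tbs_c = _raster_axes(coords, raster_step)
    cells = np.column_stack([g.ravel() for g in np.meshgrid(ttd_c, tbs_c)])
    members = list(seen.values())
    covers = np.zeros((len(members), len(cells)), dtype=bool)
    for i, idx in enumerate(members):
        covers[i] = hotelling_ellipse(coords[idx]).covers(cells)
    return SubsetGeometry(member_idx=members, covers=covers,
                          ttd_centers=ttd_c, tbs_centers=tbs_c, settings=settings)


def _replicate_density(geom: SubsetGeometry, n_vars: int, n_obs: int, seed_pair) -> np.ndarray:
    """One null replicate: random data, all subset models, density raster."""
    rng = np.random.default_rng(seed_pair)
    D = rng.standard_normal((n_obs, n_vars))
    s = geom.settings
    sig = np.zeros(geom.n_subsets, dtype=bool)
    for i, idx in enumerate(geom.member_idx):
        cv = cross_validate(
            D[idx], model_kind="EP", n_ortho=s.n_ortho,
            k_folds=min(s.k_folds, len(idx)), select_vars=s.select_vars,
            alpha=s.alpha, fold_seed=s.fold_seed,
        )
        sig[i] = cv.computable and not np.isnan(cv.p_cvanova) and cv.p_cvanova < s.alpha
    density = geom.covers[sig].sum(axis=0).astype(np.uint16)
    return density.reshape(geom.shape)


def simulate_null(
    coords: np.ndarray,
    n_vars: int,
    settings: ScanSettings | None = None,
    n_reps: int = 10000,
    seed: int = 0,
    raster_step: float = 0.25,
    n_jobs: int = 1,
    checkpoint: str | Path | None = None,
    checkpoint_every: int = 200,
) -> NullDistribution:
    """Recompute the significant-subset density under the global null.

    Each replicate replaces the difference matrix by i.i.d. standard
    normal draws of the same shape (the coordinates, and hence subset
    membership and ellipses, are fixed) and records the resulting
    density raster.  Replicate streams are seeded as (seed, replicate
    index), so the result is independent of execution order and of
    ``n_jobs``; an optional checkpoint file allows resuming long runs.
    """
    geom = subset_geometry(coords, settings, raster_step)
    n_obs = len(np.asarray(coords))
    done = 0
    densities = np.zeros((n_reps, *geom.shape), dtype=np.uint16)
    if checkpoint is not None and Path(checkpoint).exists():
        with np.load(checkpoint) as z:
            prev = z["densities"]
            if int(z["seed"]) == seed and prev.shape[1:] == geom.shape:
                done = min(len(prev), n_reps)
                densities[:done] = prev[:done]

    while done < n_reps:
        stop = min(n_reps, done + checkpoint_every) if checkpoint is not None else n_reps
        batch = Parallel(n_jobs=n_jobs)(
            delayed(_replicate_density)(geom, n_vars, n_obs, (seed, rep))
            for rep in range(done, stop)
        )
        densities[done:stop] = np.stack(batch)
        done = stop
        if checkpoint is not None:
            np.savez_compressed(checkpoint, densities=densities[:done], seed=seed)

    return NullDistribution(densities=densities, ttd_centers=geom.ttd_centers,
                            tbs_centers=geom.tbs_centers, seed=seed, settings=geom.settings)


def discretize(p_hat: np.ndarray) -> np.ndarray:
    """Map probabilities to the six printed levels."""
    levels = np.full(p_hat.shape, LEVEL_ABOVE, dtype=object)
    for bound, label in sorted(LEVELS, reverse=True):
        levels[p_hat < bound] = label
    return levels.astype(str)


def probability_map(observed: DensityMap, null: NullDistribution) -> ProbabilityMap:
    """Per-cell probability of the observed density arising by chance.

    Uses the add-one estimator p̂ = (1 + #{null ≥ observed}) / (1 + R),
    which never reports exactly zero; "<0.001" is reachable once R ≥
    999 replicates all fall below the observation.
    """
    if (
        observed.counts.shape != null.densities.shape[1:]
        or not np.allclose(observed.ttd_centers, null.ttd_centers)
        or not np.allclose(observed.tbs_centers, null.tbs_centers)
    ):
        raise SmartError("observed density raster does not match the null raster")
    exceed = (null.densities >= observed.counts[None, :, :]).sum(axis=0)
    p_hat = (1.0 + exceed) / (1.0 + null.n_reps)
    return ProbabilityMap(
        ttd_centers=observed.ttd_centers, tbs_centers=observed.tbs_centers,
        p_hat=p_hat, levels=discretize(p_hat),
    )
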
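"""The SMART scan engine.

The scan explores the plane spanned by the two per-pair coordinates —
time to diagnosis (ttd) and time between repeated samples (tbs), both
in years — on a regular lattice.  At every lattice point, and for seven
ttd-axis weights spanning 1/8 to 8, the k nearest case-control
observations are collected into a subset, an OPLS-EP model with
cross-validation is fitted to the subset's difference data, and the
model's CV-ANOVA significance, position (mean member coordinates) and a
95% Hotelling T² ellipse around the members are recorded.  Subsets with
identical membership are deduplicated, so each unique combination of
pairs is modeled once.

Two visual summaries derive from the scan: the SMART-model plot (model
positions colored by significance) and the SMART-observation plot (a
raster counting how many significant-subset ellipses overlay each
cell).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from smartscan.data_model import PairedCohort
from smartscan.errors import SampleSizeError, SmartError
from smartscan.opls import CVResult, OPLSModel, cross_validate, fit_opls_ep
from smartscan.significance import VariableStats, variable_stats

DEFAULT_WEIGHTS = (0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)

_TINY = 1e-12


@dataclass
class ScanSettings:
    """All knobs of one scan run; serialized alongside every result.

    ``step`` is the lattice increment in years, ``k`` the subset size,
    and ``weights`` the multipliers applied to the ttd axis when
    computing distances (the tbs weight is fixed at 1).  Model settings
    (fold count, orthogonal components, per-fold variable selection,
    significance level, fold seed) are passed through to the OPLS-EP
    cross-validation.
    """

    step: float = 0.25
    k: int = 20
    weights: tuple[float, ...] = DEFAULT_WEIGHTS
    k_folds: int = 7
    n_ortho: int = 0
    select_vars: bool = True
    alpha: float = 0.05
    fold_seed: int = 0
    keep_variable_stats: bool = True

    def to_dict(self) -> dict:
        return {
            "step": self.step,
            "k": self.k,
            "weights": list(self.weights),
            "k_folds": self.k_folds,
            "n_ortho": self.n_ortho,
            "select_vars": self.select_vars,
            "alpha": self.alpha,
            "fold_seed": self.fold_seed,
            "keep_variable_stats": self.keep_variable_stats,
        }


@dataclass
class Ellipse:
    """A Hotelling T² coverage ellipse in the (ttd, tbs) plane."""

    center: np.ndarray
    semi_axes: np.ndarray  # (major, minor)
    angle: float  # radians, major axis vs ttd axis
    cov: np.ndarray
    crit: float
    n: int
    degenerate: bool = False

    def covers(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the ellipse (degenerate covers none)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        if self.degenerate:
            return np.zeros(len(points), dtype=bool)
        diff = points - self.center
        sol = np.linalg.solve(self.cov, diff.T).T
        mahal = np.einsum("ij,ij->i", diff, sol)
        return mahal <= self.crit


def hotelling_ellipse(points: np.ndarray, level: float = 0.95) -> Ellipse:
    """95% Hotelling T² ellipse around a 2-D point cloud.

    The critical Mahalanobis bound is ``2 (n-1)/(n-2) F_{level}(2, n-2)``,
    the classic T² limit for individual observations; as n grows it
    approaches the chi-square bound χ²₂(level) ≈ 5.99 (radius ≈ 2.448
    for unit isotropic covariance).  Collinear clouds yield a degenerate
    sentinel with zero minor axis.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 3:
        raise SampleSizeError(f"need at least 3 points for an ellipse, got {n}")
    center = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    crit = 2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    degenerate = eigvals[1] <= _TINY * max(eigvals[0], 1.0)
    semi = np.sqrt(np.clip(eigvals, 0.0, None) * crit)
    if degenerate:
        semi[1] = 0.0
    angle = float(np.arctan2(eigvecs[1, 0], eigvecs[0, 0]))
    return Ellipse(center=center, semi_axes=semi, angle=angle, cov=cov,
                   crit=crit, n=n, degenerate=degenerate)


@dataclass
class SubsetRecord:
    """One unique scan subset and its fitted model."""

    pair_ids: tuple[str, ...]
    member_idx: np.ndarray
    anchor: tuple[float, float]
    weight: float
    model: OPLSModel | None
    cv: CVResult | None
    significant: bool
    position: tuple[float, float]
    ellipse: Ellipse
    var_stats: VariableStats | None = None

    @property
    def q2(self) -> float:
        return np.nan if self.cv is None else self.cv.Q2

    @property
    def p_cvanova(self) -> float:
        return np.nan if self.cv is None else self.cv.p_cvanova


@dataclass
class ScanResult:
    """Full output of one scan: every unique subset with its model."""

    subsets: list[SubsetRecord]
    grid: np.ndarray
    settings: ScanSettings
    coords: np.ndarray  # (n, 2) observation (ttd, tbs)
    pair_ids: list[str]
    variable_ids: list[str]

    @property
    def n_subsets(self) -> int:
        return len(self.subsets)

    @property
    def n_significant(self) -> int:
        return sum(s.significant for s in self.subsets)

    def significant_subsets(self) -> list[SubsetRecord]:
        return [s for s in self.subsets if s.significant]

    def loadings_w(self, significant_only: bool = True) -> np.ndarray:
        """Stacked predictive weight vectors (models × variables)."""
        subs = self.significant_subsets() if significant_only else self.subsets
        rows = []
        for s in subs:
            if s.model is None:
                continue
            w = np.zeros(len(self.variable_ids))
            # models may have been fitted on a column subset (constant
            # columns dropped); re-expand to the full variable order
            if s.model.variable_ids is not None and len(s.model.variable_ids) != len(self.variable_ids):
                pos = {v: i for i, v in enumerate(self.variable_ids)}
                for val, vid in zip(s.model.w, s.model.variable_ids):
                    w[pos[vid]] = val
            else:
                w[:] = s.model.w
            rows.append(w)
        return np.vstack(rows) if rows else np.zeros((0, len(self.variable_ids)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.subsets:
            rows.append(
                {
                    "anchor_ttd": s.anchor[0],
                    "anchor_tbs": s.anchor[1],
                    "weight": s.weight,
                    "position_ttd": s.position[0],
                    "position_tbs": s.position[1],
                    "n_members": len(s.pair_ids),
                    "Q2": s.q2,
                    "p_cvanova": s.p_cvanova,
                    "significant": s.significant,
                    "members": ";".join(s.pair_ids),
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out_dir / "subsets.tsv", sep="\t", index=False)
        with open(out_dir / "scan_settings.json", "w") as fh:
            json.dump(self.settings.to_dict(), fh, indent=2)


@dataclass
class DensityMap:
    """Raster of overlaid significant-subset ellipses over (ttd, tbs).

    ``counts[i, j]`` belongs to tbs center i and ttd center j; for
    variable maps the counts are signed by the direction of change.
    """

    ttd_centers: np.ndarray
    tbs_centers: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.tbs_centers, columns=self.ttd_centers)

    @property
    def cell_centers(self) -> np.ndarray:
        tt, bb = np.meshgrid(self.ttd_centers, self.tbs_centers)
        return np.column_stack([tt.ravel(), bb.ravel()])


def build_grid(cohort: PairedCohort | np.ndarray, step: float = 0.25) -> np.ndarray:
    """Lattice over the observed (ttd, tbs) bounding box, step-aligned.

    Lattice coordinates are integer multiples of ``step`` covering the
    data range inclusively.  Returns an (m, 2) array, ttd varying
    fastest.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    coords = cohort.coords if isinstance(cohort, PairedCohort) else np.asarray(cohort, dtype=float)
    if coords.size == 0:
        raise SmartError("cannot build a scan grid from an empty cohort")

    def axis(lo: float, hi: float) -> np.ndarray:
        start = np.floor(lo / step + 1e-9) * step
        stop = np.ceil(hi / step - 1e-9) * step
        n_pts = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n_pts)

    ttd_ax = axis(coords[:, 0].min(), coords[:, 0].max())
    tbs_ax = axis(coords[:, 1].min(), coords[:, 1].max())
    tt, bb = np.meshgrid(ttd_ax, tbs_ax)
    return np.column_stack([tt.ravel(), bb.ravel()])


def select_subset(
    anchor: Sequence[float],
    weight: float,
    cohort: PairedCohort | np.ndarray,
    k: int = 20,
    pair_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Indices of the k observations nearest the anchor in weighted distance.

    Distance = sqrt((weight·Δttd)² + (Δtbs)²); ties are broken by pair id
    so subsets are reproducible.
    """
    if isinstance(cohort, PairedCohort):
        coords = cohort.coords
        if pair_ids is None:
            pair_ids = cohort.pair_ids
    else:
        coords = np.asarray(cohort, dtype=float)
    n = len(coords)
    if k > n:
        raise SampleSizeError(f"k={k} exceeds cohort size n={n}")
    if pair_ids is None:
        pair_ids = [str(i) for i in range(n)]
    d2 = (weight * (coords[:, 0] - anchor[0])) ** 2 + (coords[:, 1] - anchor[1]) ** 2
    order = np.lexsort((np.asarray(pair_ids, dtype=object), d2))
    return np.sort(order[:k])


def _fit_subset(D_sub: np.ndarray, settings: ScanSettings, variable_ids: list[str]):
    """Fit the full EP model + CV for one subset; returns (model, cv, stats)."""
    sds = np.std(D_sub, axis=0, ddof=1)
    usable = np.flatnonzero(sds > _TINY)
    if usable.size == 0:
        return None, None, None
    cv = cross_validate(
        D_sub, model_kind="EP", n_ortho=settings.n_ortho, k_folds=min(settings.k_folds, len(D_sub)),
        select_vars=settings.select_vars, alpha=settings.alpha, fold_seed=settings.fold_seed,
    )
    model = fit_opls_ep(D_sub[:, usable], n_ortho=settings.n_ortho,
                        variable_ids=[variable_ids[j] for j in usable])
    vs = None
    if settings.keep_variable_stats:
        vs = variable_stats(D_sub, model.y_hat, cv.p_cvanova, variable_ids, alpha=settings.alpha)
    return model, cv, vs


def run_scan(cohort: PairedCohort, settings: ScanSettings | None = None) -> ScanResult:
    """Run the full subset scan over a repeated-time-point cohort.

    Every lattice point × weight combination proposes a subset; subsets
    with identical membership are modeled once (first-proposing anchor
    recorded).  Non-computable models are retained as non-significant
    sentinels, never dropped.
    """
    if settings is None:
        settings = ScanSettings()
    coords = cohort.coords
    if np.isnan(coords).any():
        raise SmartError("scan requires both ttd and tbs for every observation")
    D = cohort.d_matrix
    pair_ids = cohort.pair_ids
    grid = build_grid(cohort, settings.step)
    k = min(settings.k, len(cohort))

    proposals: dict[tuple[int, ...], tuple[tuple[float, float], float, np.ndarray]] = {}
    for anchor in grid:
        for weight in settings.weights:
            idx = select_subset(anchor, weight, coords, k=k, pair_ids=pair_ids)
            key = tuple(idx)
            if key not in proposals:
                proposals[key] = ((float(anchor[0]), float(anchor[1])), float(weight), idx)

    subsets: list[SubsetRecord] = []
    for key, (anchor, weight, idx) in proposals.items():
        D_sub = D[idx]
        coords_sub = coords[idx]
        model, cv, vs = _fit_subset(D_sub, settings, cohort.variable_ids)
        significant = bool(
            cv is not None and cv.computable and not np.isnan(cv.p_cvanova)
            and cv.p_cvanova < settings.alpha
        )
        position = (float(coords_sub[:, 0].mean()), float(coords_sub[:, 1].mean()))
        ellipse = hotelling_ellipse(coords_sub)
        subsets.append(
            SubsetRecord(
                pair_ids=tuple(pair_ids[i] for i in idx), member_idx=idx,
                anchor=anchor, weight=weight, model=model, cv=cv,
                significant=significant, position=position, ellipse=ellipse,
                var_stats=vs,
            )
        )
    return ScanResult(subsets=subsets, grid=grid, settings=settings, coords=coords,
                      pair_ids=list(pair_ids), variable_ids=list(cohort.variable_ids))


def _raster_axes(coords: np.ndarray, raster_step: float) -> tuple[np.ndarray, np.ndarray]:
    lo = np.floor(coords.min(axis=0) / raster_step) * raster_step
    hi = np.ceil(coords.max(axis=0) / raster_step) * raster_step
    ttd = lo[0] + raster_step * (0.5 + np.arange(int(round((hi[0] - lo[0]) / raster_step))))
    tbs = lo[1] + raster_step * (0.5 + np.arange(int(round((hi[1] - lo[1]) / raster_step))))
    return ttd, tbs


def observation_density(scan: ScanResult, raster_step: float = 0.25) -> DensityMap:
    """SMART-observation raster: per cell, the number of significant-subset
    ellipses covering the cell center."""
    ttd_c, tbs_c = _raster_axes(scan.coords, raster_step)
    dmap = DensityMap(ttd_centers=ttd_c, tbs_centers=tbs_c,
                      counts=np.zeros((len(tbs_c), len(ttd_c))))
    cells = dmap.cell_centers
    for s in scan.significant_subsets():
        dmap.counts += s.ellipse.covers(cells).reshape(dmap.counts.shape)
    return dmap


def variable_density(
    scan: ScanResult,
    variable_id: str,
    criterion: str = "multivariate",
    raster_step: float = 0.25,
) -> DensityMap:
    """Signed ellipse-density raster for one variable.

    ``criterion`` is one of ``ttest`` (univariate p < alpha), ``fdr``
    (univariate after BH-FDR at 0.2) or ``multivariate`` (significant
    model and both w/p criteria).  Cells accumulate +1 per covering
    subset where the variable increases in cases and -1 where it
    decreases.
    """
    if variable_id not in scan.variable_ids:
        raise SmartError(f"unknown variable {variable_id!r}")
    if criterion not in {"ttest", "fdr", "multivariate"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    j = scan.variable_ids.index(variable_id)
    ttd_c, tbs_c = _raster_axes(scan.coords, raster_step)
    dmap = DensityMap(ttd_centers=ttd_c, tbs_centers=tbs_c,
                      counts=np.zeros((len(tbs_c), len(ttd_c))))
    cells = dmap.cell_centers
    attr = {"ttest": "univariate", "fdr": "fdr", "multivariate": "multivariate"}[criterion]
    for s in scan.subsets:
        if s.var_stats is None:
            raise SmartError("scan was run without keep_variable_stats; variable maps unavailable")
        if not getattr(s.var_stats, attr)[j]:
            continue
        sign = 1.0 if s.var_stats.mean_d[j] >= 0 else -1.0
        dmap.counts += sign * s.ellipse.covers(cells).reshape(dmap.counts.shape)
    return dmap


def roi_model(
    cohort: PairedCohort,
    roi: tuple[float, float],
    variables: Sequence[str] | None = None,
    k_folds: int = 7,
    select_vars: bool = True,
    fold_seed: int = 0,
) -> CVResult:
    """One-component OPLS-EP on a declared region of interest.

    ``roi = (ttd_max, tbs_max)``: only pairs with ttd < ttd_max and
    tbs < tbs_max enter the model, optionally restricted to a variable
    panel.  The component count is fixed at one to limit overfitting.
    """
    mask = (cohort.ttd < roi[0]) & (cohort.tbs < roi[1])
    if not mask.any():
        raise SmartError(f"no observations inside roi {roi}")
    ids = [pid for pid, m in zip(cohort.pair_ids, mask) if m]
    sub = cohort.subset(ids)
    if len(sub) < 3:
        raise SampleSizeError(f"only {len(sub)} observation(s) inside roi {roi}")
    D = sub.d_matrix
    if variables is not None:
        missing = [v for v in variables if v not in cohort.variable_ids]
        if missing:
            raise SmartError(f"panel variable(s) not in cohort: {missing}")
        cols = [cohort.variable_ids.index(v) for v in variables]
        D = D[:, cols]
    return cross_validate(
        D, model_kind="EP", n_ortho=0, k_folds=min(k_folds, len(sub)),
        select_vars=select_vars, fold_seed=fold_seed,
    )
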
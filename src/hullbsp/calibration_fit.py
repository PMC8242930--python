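"""Fitting calibration tables from paired hull/soft-tissue observations.

For every (segment, parameter) cell with enough species, the paired values
are transformed (log10 for mass and the moments of inertia, identity
otherwise) and regressed: ordinary least squares always, and — when a
phylogeny is supplied — generalized least squares under Brownian motion
(Pagel's lambda fixed at 1, residual covariance proportional to shared
root-to-tip path length). The better model is selected by AIC computed
from maximum-likelihood Gaussian log-likelihoods with k = 3 parameters
(intercept, slope, residual variance) for both, so the AIC difference
reflects only the covariance structure. OLS fits also report R^2 and
leave-one-out cross-validation RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .segments_calibration import (
    LOG10_PARAMETERS,
    MIRRORED_PARAMETERS,
    SEGMENT_NAMES,
    CalibrationModel,
    CalibrationTable,
    transform_name,
)
from .mass_properties import PARAMETER_NAMES

__all__ = [
    "PairedDataset",
    "Phylogeny",
    "RegressionFit",
    "FitReport",
    "transform_values",
    "fit_ols",
    "bm_covariance",
    "fit_pgls_bm",
    "select_model",
    "loocv_rmse",
    "build_calibration",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

DATASET_COLUMNS = ["species", "segment", "side", "parameter", "hull_value", "soft_value"]


@dataclass
class PairedDataset:
    """Species x segment x parameter observations of (hull value, soft value).

    One row per (species, segment, side, parameter). Values are SI and
    untransformed; log10 transforms are applied at fit time.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"paired dataset missing columns {missing}")
        dup = self.frame.duplicated(subset=["species", "segment", "side", "parameter"])
        if dup.any():
            raise ValueError(
                f"duplicate (species, segment, side, parameter) rows: "
                f"{self.frame[dup].head().to_dict('records')}"
            )
        bad = ~self.frame["segment"].isin(SEGMENT_NAMES)
        if bad.any():
            raise ValueError(f"unknown segments {sorted(self.frame.loc[bad, 'segment'].unique())}")

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_csv(cls, path) -> "PairedDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def folded_left(self) -> pd.DataFrame:
        """Fold right-side appendicular rows onto the left by flipping the
        sign of the mirrored parameters (cm_y, ixy, iyz) in both columns."""
        frame = self.frame.copy()
        right = frame["side"] == "right"
        flip = right & frame["parameter"].isin(MIRRORED_PARAMETERS)
        frame.loc[flip, ["hull_value", "soft_value"]] *= -1.0
        frame.loc[right, "side"] = "left"
        return frame


class Phylogeny:
    """Rooted tree with branch lengths, keyed by unique tip labels.

    Ultrametricity is not required; Brownian covariances use raw shared
    root-to-tip path lengths.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip labels must be unique")
        self.tip_labels = labels

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=text, schema="newick")
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        tree = dendropy.Tree.get(path=str(path), schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    def root_to_tip_paths(self) -> dict[str, list[tuple[int, float]]]:
        """Per tip: the list of (ancestor node id, cumulative depth at that
        node's child end) along the root-to-tip path."""
        paths: dict[str, list[tuple[int, float]]] = {}
        for leaf in self.tree.leaf_node_iter():
            path = []
            depth = 0.0
            chain = []
            node = leaf
            while node is not None:
                chain.append(node)
                node = node.parent_node
            chain.reverse()  # root ... leaf
            for nd in chain[1:]:  # skip the root's (absent) subtending edge
                depth += nd.edge.length if nd.edge.length is not None else 0.0
                path.append((id(nd), depth))
            paths[leaf.taxon.label] = path
        return paths


def bm_covariance(tree: Phylogeny, species_order: list[str]) -> np.ndarray:
    """Brownian-motion covariance matrix: V[i, j] = shared root-to-tip path
    length of tips i and j (tip depth on the diagonal)."""
    paths = tree.root_to_tip_paths()
    missing = [s for s in species_order if s not in paths]
    if missing:
        raise KeyError(f"species missing from tree: {missing}")
    n = len(species_order)
    V = np.zeros((n, n))
    node_depths = [dict(paths[s]) for s in species_order]
    for i in range(n):
        depth_i = paths[species_order[i]][-1][1] if paths[species_order[i]] else 0.0
        V[i, i] = depth_i
        for j in range(i + 1, n):
            shared = 0.0
            dj = node_depths[j]
            for node_id, depth in paths[species_order[i]]:
                if node_id in dj:
                    shared = max(shared, depth)
            V[i, j] = V[j, i] = shared
    return V


# ---------------------------------------------------------------------------
# Regression fits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegressionFit:
    method: str  # "OLS" | "PGLS-BM"
    intercept: float
    slope: float
    sigma2: float  # ML residual variance
    loglik: float
    aic: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    n: int
    r2: float | None = None
    loocv_rmse: float | None = None


def transform_values(values, parameter: str) -> np.ndarray:
    """Apply the published transform: log10 for mass/ixx/iyy/izz, identity
    for everything else. Non-positive values under log10 are an error."""
    values = np.asarray(values, dtype=float)
    if parameter in LOG10_PARAMETERS:
        bad = np.nonzero(values <= 0)[0]
        if bad.size:
            raise ValueError(
                f"parameter {parameter!r} is log10-transformed but rows {bad.tolist()} "
                f"have non-positive values"
            )
        return np.log10(values)
    return values


def _gls_fit(x: np.ndarray, y: np.ndarray, V: np.ndarray | None, method: str) -> RegressionFit:
    """Shared ML machinery for OLS (V = None) and PGLS-BM."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError(f"x and y lengths differ: {n} vs {len(y)}")
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; the slope is unidentifiable")
    X = np.column_stack([np.ones(n), x])

    if V is None:
        Xw, yw = X, y
        logdetV = 0.0
    else:
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise ValueError(f"covariance matrix is not positive definite: {exc}") from exc
        Xw = solve_triangular(L, X, lower=True)
        yw = solve_triangular(L, y, lower=True)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))

    XtX = Xw.T @ Xw
    try:
        beta = np.linalg.solve(XtX, Xw.T @ yw)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular design: {exc}") from exc
    resid = yw - Xw @ beta
    rss = float(resid @ resid)

    sigma2_ml = rss / n
    if sigma2_ml <= 0:
        # Exact fit: the Gaussian ML likelihood is unbounded; report +inf
        # loglik so model selection prefers it deterministically.
        loglik = math.inf
    else:
        loglik = -0.5 * (n * math.log(2.0 * math.pi * sigma2_ml) + logdetV + n)
    k = 3  # intercept, slope, sigma2 (lambda is fixed, not estimated)
    aic = 2 * k - 2 * loglik

    dof = n - 2
    s2 = rss / dof if dof > 0 else float("nan")
    cov_beta = s2 * np.linalg.inv(XtX)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    tcrit = stats.t.ppf(0.975, dof)
    ci = [(beta[i] - tcrit * se[i], beta[i] + tcrit * se[i]) for i in range(2)]

    r2 = None
    if method == "OLS":
        tss = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 0.0

    return RegressionFit(
        method=method,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        sigma2=sigma2_ml,
        loglik=loglik,
        aic=aic,
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        n=n,
        r2=r2,
    )


def fit_ols(x, y) -> RegressionFit:
    """Ordinary least squares y = a + b x with ML Gaussian log-likelihood,
    AIC (k = 3), t-based 95% CIs and R^2."""
    return _gls_fit(np.asarray(x, float), np.asarray(y, float), None, "OLS")


def fit_pgls_bm(x, y, tree: Phylogeny, species: list[str]) -> RegressionFit:
    """Phylogenetic GLS under Brownian motion (lambda = 1).

    Residual covariance is sigma^2 * V with V from bm_covariance over the
    given species order. Reduces exactly to OLS when V is proportional to
    the identity (e.g. a star tree with equal tip depths).
    """
    x = np.asarray(x, dtype=float)
    if len(species) != len(x):
        raise ValueError("species list must match the observations")
    V = bm_covariance(tree, list(species))
    return _gls_fit(x, np.asarray(y, float), V, "PGLS-BM")


def select_model(ols: RegressionFit, pgls: RegressionFit) -> RegressionFit:
    """Pick the lower-AIC fit; ties (|dAIC| < 1e-9) go to OLS."""
    if ols.n != pgls.n:
        raise ValueError(f"fits are not on the same data: n={ols.n} vs n={pgls.n}")
    if pgls.aic < ols.aic - 1e-9:
        return pgls
    return ols


def loocv_rmse(x, y, method: str = "refit") -> float:
    """Leave-one-out RMSE of prediction for the OLS fit.

    ``method="refit"`` refits n times explicitly; ``method="hat"`` uses the
    closed form e_i / (1 - h_ii). The two agree to floating-point accuracy.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError(f"LOOCV needs at least 4 observations, got {n}")
    X = np.column_stack([np.ones(n), x])
    if method == "hat":
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
        press = resid / (1.0 - h)
        return float(np.sqrt(np.mean(press**2)))
    if method != "refit":
        raise ValueError(f"method must be 'refit' or 'hat', got {method!r}")
    errors = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        Xi, yi = X[mask], y[mask]
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ yi)
        errors[i] = y[i] - X[i] @ beta
    return float(np.sqrt(np.mean(errors**2)))


# ---------------------------------------------------------------------------
# Table building
# ---------------------------------------------------------------------------


@dataclass
class FitReport:
    """Per-cell fit diagnostics accompanying a fitted CalibrationTable."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _prune_tree(tree: Phylogeny, species: list[str]) -> Phylogeny:
    keep = set(species)
    clone = dendropy.Tree(tree.tree)
    taxa = [t for t in clone.taxon_namespace if t.label in keep]
    clone.retain_taxa(taxa)
    return Phylogeny(clone)


def build_calibration(
    dataset: PairedDataset,
    tree: Phylogeny | None = None,
    min_n: int = 3,
) -> tuple[CalibrationTable, FitReport]:
    """Fit a calibration table from a paired dataset.

    Right-side appendicular rows are folded onto the left before fitting.
    Each (segment, parameter) cell with at least ``min_n`` species is
    transformed and fitted; when a tree is given the tree is pruned to the
    cell's species and OLS vs PGLS-BM is selected by AIC. Cells with
    insufficient data are left absent.
    """
    frame = dataset.folded_left()
    if frame.empty:
        raise ValueError("paired dataset is empty")
    table = CalibrationTable(provenance="fitted by hullbsp.calibration_fit.build_calibration")
    report = FitReport()

    for (segment, parameter), cell in frame.groupby(["segment", "parameter"], sort=True):
        cell = cell.sort_values("species")
        n = len(cell)
        if n < min_n:
            continue
        species = cell["species"].tolist()
        x = transform_values(cell["hull_value"].to_numpy(), parameter)
        y = transform_values(cell["soft_value"].to_numpy(), parameter)

        ols = fit_ols(x, y)
        rmse = loocv_rmse(x, y) if n >= 4 else None
        pgls = None
        if tree is not None:
            pgls = fit_pgls_bm(x, y, _prune_tree(tree, species), species)
            chosen = select_model(ols, pgls)
        else:
            chosen = ols

        side = "left" if segment in ("arm", "forearm", "hand", "thigh", "shank", "foot") else "none"
        table.add(CalibrationModel(
            segment=segment,
            side=side,
            parameter=parameter,
            intercept=chosen.intercept,
            slope=chosen.slope,
            transform=transform_name(parameter),
            intercept_ci=chosen.intercept_ci,
            slope_ci=chosen.slope_ci,
            method=chosen.method,
            n=n,
            r2=ols.r2,
            rmse=rmse,
        ))
        report.rows.append({
            "segment": segment,
            "side": side,
            "parameter": parameter,
            "transform": transform_name(parameter),
            "n": n,
            "intercept": chosen.intercept,
            "slope": chosen.slope,
            "intercept_lo": chosen.intercept_ci[0],
            "intercept_hi": chosen.intercept_ci[1],
            "slope_lo": chosen.slope_ci[0],
            "slope_hi": chosen.slope_ci[1],
            "aic_ols": ols.aic,
            "aic_pgls": pgls.aic if pgls is not None else None,
            "chosen": chosen.method,
            "r2_ols": ols.r2,
            "loocv_rmse_ols": rmse,
        })

    if not table.models:
        raise ValueError("no (segment, parameter) cell had enough observations to fit")
    return table, report
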
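"""Ising network estimation from binary cross-sectional data.

Implements the nodewise ("eLasso") estimator: each symptom is regressed
on all others with L1-penalised logistic regression, the penalty weight
is chosen by the extended Bayesian Information Criterion

    EBIC(lambda) = -2 loglik + k log N + 2 gamma k log(J - 1)

with ``k`` the number of nonzero coefficients, and the two directed
coefficient sets are symmetrised into an undirected weight matrix (AND
rule by default: an edge survives only if both directions select it,
with the mean of the two coefficients as its weight). Intercepts of the
selected fits become the thresholds ``tau_i``.

The inner convex solve per (node, lambda) is scikit-learn's liblinear
L1 logistic regression; grid construction, EBIC scoring, selection and
symmetrisation are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from symptomnet.core_model import DimensionMismatchError, SymptomNetwork

_COEF_EPS = 1e-10  # liblinear returns exact zeros; guard against fp dust


class DatasetValidationError(ValueError):
    """The binary data matrix violates a dataset invariant."""


class EstimationError(RuntimeError):
    """A nodewise fit could not be carried out."""


@dataclass(frozen=True)
class BinaryDataset:
    """Respondents x symptoms 0/1 matrix.

    A zero-variance (constant) column makes its nodewise regression
    ill-posed, so such columns are rejected unless ``allow_constant``
    is set.
    """

    data: np.ndarray
    labels: list[str]
    allow_constant: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 2:
            raise DatasetValidationError(f"data must be 2-D, got shape {data.shape}")
        if not np.isin(data, (0, 1)).all():
            bad = np.argwhere(~np.isin(data, (0, 1)))[0]
            raise DatasetValidationError(
                f"non-binary value {data[tuple(bad)]!r} at row {bad[0]}, column {bad[1]}"
            )
        if len(self.labels) != data.shape[1]:
            raise DimensionMismatchError(
                f"{len(self.labels)} labels for {data.shape[1]} columns"
            )
        if not self.allow_constant:
            col_min = data.min(axis=0)
            col_max = data.max(axis=0)
            const = np.flatnonzero(col_min == col_max)
            if const.size:
                names = [self.labels[i] for i in const]
                raise DatasetValidationError(
                    f"constant column(s) {names}; pass allow_constant=True to override"
                )
        object.__setattr__(self, "data", data.astype(np.int8))
        object.__setattr__(self, "labels", list(map(str, self.labels)))

    @property
    def N(self) -> int:
        return self.data.shape[0]

    @property
    def J(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class EstimationConfig:
    """Hyperparameters of the nodewise estimator.

    ``ebic_gamma`` defaults to 0.25 and ``symmetrization`` to the AND
    rule, the defaults of the published eLasso implementation. The
    lambda grid, when not given, is 100 log-spaced values from the
    data-driven lambda_max down to ``lambda_min_ratio * lambda_max``.
    """

    ebic_gamma: float = 0.25
    lambda_grid: np.ndarray | None = None
    symmetrization: str = "and"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.001

    def __post_init__(self) -> None:
        if self.ebic_gamma < 0:
            raise ValueError(f"ebic_gamma must be >= 0, got {self.ebic_gamma}")
        if self.symmetrization not in ("and", "or"):
            raise ValueError(f"symmetrization must be 'and' or 'or', got {self.symmetrization!r}")
        if self.lambda_grid is not None:
            grid = np.asarray(self.lambda_grid, dtype=float)
            if np.any(grid <= 0):
                raise ValueError("lambda_grid must be strictly positive")
            grid = np.sort(grid)[::-1]
            object.__setattr__(self, "lambda_grid", grid)


@dataclass(frozen=True)
class NodeFit:
    """Selected fit for one node's conditional logistic model."""

    intercept: float
    coefficients: np.ndarray  # length J-1, order = other columns in original order
    ebic: float
    lambda_selected: float
    separation_warning: bool = False


def _lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the lasso-logistic solution is all-zero.

    With an unpenalised intercept the null fit predicts ybar for every
    respondent, so the KKT entry condition gives
    lambda_max = max_j |x_j . (y - ybar)| / N.
    """
    N = len(y)
    resid = y - y.mean()
    lam = np.max(np.abs(X.T @ resid)) / N
    return max(lam, 1e-6)


def _loglik(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


def regularization_path(
    dataset: BinaryDataset, node_index: int, cfg: EstimationConfig | None = None
) -> pd.DataFrame:
    """Fit the full lambda path for one node.

    Returns a frame with one row per lambda: lam, k (nonzero
    coefficients), loglik, ebic, intercept, and the coefficient vector.
    """
    cfg = cfg or EstimationConfig()
    X, y = _design(dataset, node_index)
    N, p_minus_1 = X.shape
    grid = cfg.lambda_grid
    if grid is None:
        lam_max = _lambda_max(X, y)
        grid = np.geomspace(lam_max, cfg.lambda_min_ratio * lam_max, cfg.n_lambda)

    # intercept-only model, exact: guarantees the empty neighbourhood is
    # always a selection candidate even if every grid point admits a
    # coefficient at the solver's tolerance
    ybar = y.mean()
    ll_null = _loglik(y, np.full_like(y, ybar, dtype=float))
    rows = [
        {
            "lam": float(grid[0]) * (1.0 + 1e-9),
            "k": 0,
            "loglik": ll_null,
            "ebic": -2.0 * ll_null,
            "intercept": float(np.log(ybar / (1.0 - ybar))),
            "coef": np.zeros(p_minus_1),
        }
    ]
    for lam in grid:
        # liblinear minimises C * sum(logloss) + ||w||_1, so C = 1/(N*lam)
        # matches the (1/N) loss + lam*||w||_1 parameterisation.
        clf = LogisticRegression(
            penalty="l1",
            C=1.0 / (N * lam),
            solver="liblinear",
            intercept_scaling=100.0,
            tol=1e-6,
            max_iter=2000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        coef = clf.coef_.ravel().copy()
        coef[np.abs(coef) < _COEF_EPS] = 0.0
        intercept = float(clf.intercept_[0])
        k = int(np.count_nonzero(coef))
        ll = _loglik(y, clf.predict_proba(X)[:, 1])
        ebic = -2.0 * ll + k * np.log(N) + 2.0 * cfg.ebic_gamma * k * np.log(p_minus_1)
        rows.append(
            {"lam": float(lam), "k": k, "loglik": ll, "ebic": ebic,
             "intercept": intercept, "coef": coef}
        )
    return pd.DataFrame(rows)


def _design(dataset: BinaryDataset, node_index: int) -> tuple[np.ndarray, np.ndarray]:
    data = dataset.data.astype(float)
    N, J = data.shape
    if not 0 <= node_index < J:
        raise IndexError(f"node_index {node_index} out of range for J={J}")
    if N < 10 * J:
        raise EstimationError(
            f"N={N} respondents is below the minimum 10*J={10 * J} for reliable estimation"
        )
    y = data[:, node_index]
    if y.min() == y.max():
        raise EstimationError(
            f"response column {dataset.labels[node_index]!r} is constant; cannot regress"
        )
    X = np.delete(data, node_index, axis=1)
    return X, y


def fit_node(
    dataset: BinaryDataset, node_index: int, cfg: EstimationConfig | None = None
) -> NodeFit:
    """EBIC-selected L1 logistic regression of one symptom on the rest.

    Ties in EBIC are broken toward larger lambda (the sparser model).
    A separation warning is raised on the fit when coefficients are
    implausibly large, indicating (quasi-)complete separation.
    """
    path = regularization_path(dataset, node_index, cfg)
    # grid is descending in lambda; idxmin takes the first minimiser,
    # so exact EBIC ties resolve to the sparser (larger-lambda) fit
    best = path.loc[path["ebic"].idxmin()]
    coef = best["coef"]
    return NodeFit(
        intercept=float(best["intercept"]),
        coefficients=np.asarray(coef, dtype=float),
        ebic=float(best["ebic"]),
        lambda_selected=float(best["lam"]),
        separation_warning=bool(np.any(np.abs(coef) > 30.0)),
    )


def estimate_network(
    dataset: BinaryDataset, cfg: EstimationConfig | None = None
) -> SymptomNetwork:
    """Estimate the full symptom network from a binary dataset.

    Runs :func:`fit_node` for every column, then symmetrises the two
    directed coefficients per pair. AND rule: the edge exists only if
    both coefficients are nonzero, with their mean as weight. OR rule:
    the edge exists if either is nonzero, with the mean of the nonzero
    values. Thresholds are the selected intercepts.
    """
    cfg = cfg or EstimationConfig()
    J = dataset.J
    directed = np.zeros((J, J))  # directed[i, j] = coefficient of j in i's regression
    tau = np.zeros(J)
    for i in range(J):
        try:
            fit = fit_node(dataset, i, cfg)
        except EstimationError as err:
            raise EstimationError(f"node {dataset.labels[i]!r}: {err}") from err
        tau[i] = fit.intercept
        others = [j for j in range(J) if j != i]
        directed[i, others] = fit.coefficients

    W = np.zeros((J, J))
    iu, ju = np.triu_indices(J, k=1)
    a = directed[iu, ju]
    b = directed[ju, iu]
    if cfg.symmetrization == "and":
        present = (a != 0) & (b != 0)
        w = np.where(present, (a + b) / 2.0, 0.0)
    else:
        present = (a != 0) | (b != 0)
        both = (a != 0) & (b != 0)
        w = np.where(both, (a + b) / 2.0, a + b)  # mean of nonzero values
        w = np.where(present, w, 0.0)
    W[iu, ju] = w
    W[ju, iu] = w
    return SymptomNetwork(labels=tuple(dataset.labels), weights=W, thresholds=tau)


# ---------------------------------------------------------------------------
# Dataset I/O


def read_dataset(path: str | Path, sep: str | None = None) -> BinaryDataset:
    """Read a respondents x symptoms 0/1 table from delimited text.

    The header row supplies the symptom labels. Missing and non-binary
    cells are rejected with a row/column report.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep)
    if frame.isna().any().any():
        mask = frame.isna()
        r, c = np.argwhere(mask.to_numpy())[0]
        raise DatasetValidationError(
            f"missing value at row {r}, column {frame.columns[c]!r} in {path}"
        )
    values = frame.to_numpy()
    if not np.isin(values, (0, 1)).all():
        r, c = np.argwhere(~np.isin(values, (0, 1)))[0]
        raise DatasetValidationError(
            f"non-binary value {values[r, c]!r} at row {r}, column {frame.columns[c]!r} in {path}"
        )
    return BinaryDataset(data=values.astype(np.int8), labels=list(frame.columns))


def write_dataset(dataset: BinaryDataset, path: str | Path) -> None:
    """Write a dataset as CSV with a header row of labels."""
    pd.DataFrame(dataset.data, columns=dataset.labels).to_csv(path, index=False)
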
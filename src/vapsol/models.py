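"""Regression models for heat-of-vaporization prediction.

Two trainers are provided: ordinary multilinear regression (MLR) and
kernel ridge regression (KRR) with the polynomial kernel
``k(x, x') = (x . x' + c)^d``. The published MLR instance — thirteen
descriptor coefficients plus intercept, in kJ/mol against descriptors in
their original units — ships as a coefficient registry and is exposed by
:func:`published_model`.

Model files are JSON with a schema version and a descriptor-order
fingerprint; prediction refuses inputs whose column order does not match
the fingerprint recorded at training time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import linalg

MODEL_SCHEMA_VERSION = 1

#: KRR defaults: regularization strength and soft-margin constant
DEFAULT_ALPHA = 0.001
DEFAULT_C = 1.0


class ModelError(ValueError):
    pass


class FingerprintError(ModelError):
    """Input descriptor order does not match the model's training order."""


def descriptor_fingerprint(names) -> str:
    return hashlib.sha256(",".join(names).encode()).hexdigest()[:16]


def _check_matrix(X: np.ndarray, y: np.ndarray) -> None:
    if X.ndim != 2:
        raise ModelError("X must be a 2-D matrix")
    if y.shape != (X.shape[0],):
        raise ModelError(f"y length {y.shape} does not match {X.shape[0]} rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ModelError("X and y must be finite with no missing values")


# ---------------------------------------------------------------------------
# linear model


@dataclass(frozen=True)
class LinearModel:
    """Coefficient map plus intercept; prediction is exactly theta.x + theta0.

    ``coef_strings`` preserves the printed decimal text of registry models
    so coefficients round-trip through model files bit-exactly.
    """

    names: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    coef_strings: tuple[str, ...] | None = None
    intercept_string: str | None = None

    def __post_init__(self):
        if len(self.names) != len(self.coefficients):
            raise ModelError("coefficient count does not match descriptor order")

    @property
    def fingerprint(self) -> str:
        return descriptor_fingerprint(self.names)

    def coefficient(self, name: str) -> float:
        try:
            return float(self.coefficients[self.names.index(name)])
        except ValueError:
            raise ModelError(f"model has no coefficient for {name!r}") from None

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.names):
            raise ModelError(
                f"expected {len(self.names)} descriptor columns, got {X.shape[1]}"
            )
        return X @ self.coefficients + self.intercept

    def predict_frame(self, table: pd.DataFrame) -> np.ndarray:
        cols = [c for c in table.columns if c != "name"]
        if tuple(cols) != self.names:
            raise FingerprintError(
                f"descriptor order mismatch: model was trained on {list(self.names)}, "
                f"input provides {cols}"
            )
        return self.predict(table[list(self.names)].to_numpy(dtype=float))


def fit_mlr(X, y, names=None) -> LinearModel:
    """Ordinary least squares with intercept.

    Residuals are orthogonal to the columns of X to 1e-8 relative. A
    rank-deficient X raises with the collinear columns listed; the single
    exception is an all-zero X, which degenerates to the intercept-only
    model theta0 = mean(y).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_matrix(X, y)
    n, p = X.shape
    if names is None:
        names = tuple(f"x{i}" for i in range(p))
    names = tuple(names)
    if n <= p:
        raise ModelError(f"need more rows ({n}) than descriptor columns ({p})")
    if p == 0 or not X.any():
        return LinearModel(names=names, coefficients=np.zeros(p), intercept=float(np.mean(y)))
    A = np.column_stack([X, np.ones(n)])
    # column-pivoted QR exposes which descriptors are collinear
    _, R, piv = linalg.qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * max(A.shape) * np.finfo(float).eps
    rank = int(np.sum(diag > tol))
    if rank < p + 1:
        bad = sorted(piv[rank:])
        labels = [names[k] if k < p else "intercept" for k in bad]
        raise ModelError(f"rank-deficient design matrix; collinear columns: {labels}")
    beta, *_ = linalg.lstsq(A, y)
    return LinearModel(names=names, coefficients=beta[:p], intercept=float(beta[p]))


def published_model() -> LinearModel:
    """The published fitted MLR model for ΔHvap in kJ/mol.

    Thirteen descriptor coefficients plus intercept; valid only with AE and
    QM in the original units of the underlying dataset. eta and chi carry
    no coefficient in this model.
    """
    text = (resources.files("vapsol") / "data" / "published_coefficients.csv").read_text()
    names, coefs, strings = [], [], []
    intercept = intercept_str = None
    for line in text.strip().splitlines()[1:]:
        name, value = line.split(",")
        if name == "intercept":
            intercept, intercept_str = float(value), value
        else:
            names.append(name)
            coefs.append(float(value))
            strings.append(value)
    if intercept is None:
        raise ModelError("coefficient registry lacks an intercept row")
    return LinearModel(
        names=tuple(names),
        coefficients=np.array(coefs),
        intercept=intercept,
        coef_strings=tuple(strings),
        intercept_string=intercept_str,
    )


# ---------------------------------------------------------------------------
# kernel ridge regression


def polynomial_kernel(x, x_prime, c: float = DEFAULT_C, d: int = 1) -> float:
    """Polynomial kernel (x . x' + c)^d for two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ModelError(f"vector length mismatch: {x.shape} vs {x_prime.shape}")
    if d < 1 or int(d) != d:
        raise ModelError(f"polynomial degree must be an integer >= 1, got {d}")
    if c < 0:
        raise ModelError(f"soft-margin constant must be >= 0, got {c}")
    return float((np.dot(x, x_prime) + c) ** d)


def _gram(A: np.ndarray, B: np.ndarray, c: float, d: int) -> np.ndarray:
    return (A @ B.T + c) ** d


@dataclass(frozen=True)
class KernelModel:
    """Dual-form polynomial KRR: stored training data plus dual coefficients.

    The duals solve (K + alpha I) a = y - y_mean on the (optionally
    z-scored) training descriptors; prediction adds the target mean back.
    """

    names: tuple[str, ...]
    X_train: np.ndarray  # already standardized when standardize=True
    dual: np.ndarray
    c: float
    d: int
    alpha: float
    y_mean: float
    standardize: bool
    means: np.ndarray = field(default=None)
    scales: np.ndarray = field(default=None)

    @property
    def fingerprint(self) -> str:
        return descriptor_fingerprint(self.names)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.standardize:
            return (X - self.means) / self.scales
        return X

    def predict(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.X_train.shape[1]:
            raise ModelError(
                f"expected {self.X_train.shape[1]} descriptor columns, got {X.shape[1]}"
            )
        K = _gram(self._transform(X), self.X_train, self.c, self.d)
        return K @ self.dual + self.y_mean

    def predict_frame(self, table: pd.DataFrame) -> np.ndarray:
        cols = [c for c in table.columns if c != "name"]
        if tuple(cols) != self.names:
            raise FingerprintError(
                f"descriptor order mismatch: model was trained on {list(self.names)}, "
                f"input provides {cols}"
            )
        return self.predict(table[list(self.names)].to_numpy(dtype=float))


def fit_krr(
    X,
    y,
    alpha: float = DEFAULT_ALPHA,
    c: float = DEFAULT_C,
    d: int = 1,
    standardize: bool = True,
    names=None,
) -> KernelModel:
    """Closed-form kernel ridge regression with the polynomial kernel.

    Solves (K + alpha I) a = y_centered by Cholesky factorization; alpha > 0
    guarantees positive definiteness. Descriptors are z-scored by default so
    that large-magnitude inputs (e.g. atomization energies) do not dominate
    the inner product; the choice is recorded in the model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_matrix(X, y)
    if alpha <= 0:
        raise ModelError(f"regularization strength must be > 0, got {alpha}")
    if d < 1 or int(d) != d:
        raise ModelError(f"polynomial degree must be an integer >= 1, got {d}")
    if c < 0:
        raise ModelError(f"soft-margin constant must be >= 0, got {c}")
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    means = scales = None
    Xs = X
    if standardize:
        means = X.mean(axis=0)
        scales = X.std(axis=0)
        scales = np.where(scales == 0.0, 1.0, scales)  # constant column guard
        Xs = (X - means) / scales
    y_mean = float(np.mean(y))
    K = _gram(Xs, Xs, c, int(d))
    if not np.isfinite(K).all():
        raise ModelError("kernel matrix contains non-finite entries")
    n = K.shape[0]
    cho = linalg.cho_factor(K + alpha * np.eye(n), lower=True)
    dual = linalg.cho_solve(cho, y - y_mean)
    return KernelModel(
        names=tuple(names),
        X_train=Xs,
        dual=dual,
        c=float(c),
        d=int(d),
        alpha=float(alpha),
        y_mean=y_mean,
        standardize=standardize,
        means=means,
        scales=scales,
    )


# ---------------------------------------------------------------------------
# trainer factories (for the LOOCV driver and grid search)


def mlr_trainer():
    return lambda X, y: fit_mlr(X, y)


def krr_trainer(alpha=DEFAULT_ALPHA, c=DEFAULT_C, d=1, standardize=True):
    return lambda X, y: fit_krr(X, y, alpha=alpha, c=c, d=d, standardize=standardize)


# ---------------------------------------------------------------------------
# model files


def save_model(model, path) -> None:
    """Write a model to JSON (schema-versioned)."""
    if isinstance(model, LinearModel):
        coeffs = (
            list(model.coef_strings)
            if model.coef_strings is not None
            else [repr(float(v)) for v in model.coefficients]
        )
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "mlr",
            "descriptor_order": list(model.names),
            "fingerprint": model.fingerprint,
            "coefficients": coeffs,
            "intercept": model.intercept_string or repr(float(model.intercept)),
        }
    elif isinstance(model, KernelModel):
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "kind": "krr",
            "descriptor_order": list(model.names),
            "fingerprint": model.fingerprint,
            "X_train": model.X_train.tolist(),
            "dual": model.dual.tolist(),
            "c": model.c,
            "d": model.d,
            "alpha": model.alpha,
            "y_mean": model.y_mean,
            "standardize": model.standardize,
            "means": None if model.means is None else model.means.tolist(),
            "scales": None if model.scales is None else model.scales.tolist(),
        }
    else:
        raise ModelError(f"cannot serialize model of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ModelError(f"unsupported model schema: {payload.get('schema_version')}")
    names = tuple(payload["descriptor_order"])
    if payload["kind"] == "mlr":
        strings = tuple(payload["coefficients"])
        return LinearModel(
            names=names,
            coefficients=np.array([float(s) for s in strings]),
            intercept=float(payload["intercept"]),
            coef_strings=strings,
            intercept_string=payload["intercept"],
        )
    if payload["kind"] == "krr":
        return KernelModel(
            names=names,
            X_train=np.asarray(payload["X_train"], dtype=float),
            dual=np.asarray(payload["dual"], dtype=float),
            c=float(payload["c"]),
            d=int(payload["d"]),
            alpha=float(payload["alpha"]),
            y_mean=float(payload["y_mean"]),
            standardize=bool(payload["standardize"]),
            means=None if payload["means"] is None else np.asarray(payload["means"]),
            scales=None if payload["scales"] is None else np.asarray(payload["scales"]),
        )
    raise ModelError(f"unknown model kind {payload['kind']!r}")
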
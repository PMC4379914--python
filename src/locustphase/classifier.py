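"""The logistic solitariness model (P-sol).

An animal's phase state is scored with a binary logistic regression on
behavioral markers: the linear predictor

    eta = beta0 + sum_k beta_k * X_k

is mapped to ``P_sol = exp(eta) / (1 + exp(eta))``, the probability that
the animal belongs to the solitary phase (solitary coded 1, gregarious
0).  The published coefficients retain three markers — total distance
moved (TDM), frequency of movement (FOM) and attraction index (AI) —
with intercept 2.361 and slopes -0.016, -0.172 and -0.005; all three
slopes are negative, so more motile, stimulus-attracted animals score
lower.  Note the published right-hand side is the linear predictor eta,
not the probability itself: a probability could not take the printed
form, and only the logistic transform keeps P-sol in (0, 1).

The module also provides maximum-likelihood refitting (Newton
iteration), forward marker selection, and per-class classification
rates so the model can be rebuilt on any labelled cohort.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, log_expit

from .features import MARKERS, FeatureVector

__all__ = [
    "LogisticModel",
    "FitReport",
    "DegenerateDesignError",
    "published_model",
    "linear_predictor",
    "p_sol",
    "classify",
    "fit_logistic",
    "select_markers",
    "classification_rates",
    "score_features",
]

SOLITARY, GREGARIOUS = "solitary", "gregarious"

#: Slope magnitude beyond which a non-converged fit is flagged as
#: (quasi-)complete separation.
SEPARATION_BOUND = 50.0


class DegenerateDesignError(ValueError):
    """The design matrix is rank deficient (e.g. duplicated markers)."""


@dataclass(frozen=True)
class LogisticModel:
    """Intercept plus per-marker coefficients defining eta and P-sol."""

    intercept: float
    coefficients: dict[str, float]
    threshold: float = 0.5
    name: str = ""
    version: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.coefficients) - set(MARKERS)
        if unknown:
            raise ValueError(f"unknown markers in model: {sorted(unknown)}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_yaml(self, path) -> None:
        payload = {
            "name": self.name,
            "version": self.version,
            "intercept": float(self.intercept),
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "threshold": float(self.threshold),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path_or_file) -> "LogisticModel":
        if hasattr(path_or_file, "read"):
            payload = yaml.safe_load(path_or_file)
        else:
            with open(path_or_file) as fh:
                payload = yaml.safe_load(fh)
        return cls(
            intercept=float(payload["intercept"]),
            coefficients={k: float(v) for k, v in payload["coefficients"].items()},
            threshold=float(payload.get("threshold", 0.5)),
            name=str(payload.get("name", "")),
            version=str(payload.get("version", "")),
        )


def published_model() -> LogisticModel:
    """The published three-marker solitariness model (built-in asset)."""
    ref = importlib.resources.files("locustphase.data") / "published_model.yaml"
    with ref.open() as fh:
        return LogisticModel.from_yaml(fh)


def _marker_value(fv, name: str) -> float:
    if isinstance(fv, Mapping):
        if name not in fv:
            raise KeyError(f"marker {name!r} missing from feature mapping")
        return float(fv[name])
    try:
        return float(getattr(fv, name))
    except AttributeError:
        raise KeyError(f"marker {name!r} missing from feature vector") from None


def linear_predictor(model: LogisticModel, fv) -> float:
    """eta = beta0 + sum beta_k * X_k over the model's retained markers."""
    eta = model.intercept
    for name, beta in model.coefficients.items():
        eta += beta * _marker_value(fv, name)
    return eta


def p_sol(model: LogisticModel, fv) -> float:
    """Probability of the solitary phase; numerically stable logistic."""
    return float(expit(linear_predictor(model, fv)))


def classify(model: LogisticModel, fv) -> str:
    """``"solitary"`` iff P-sol >= threshold (ties go to solitary)."""
    return SOLITARY if p_sol(model, fv) >= model.threshold else GREGARIOUS


@dataclass(frozen=True)
class FitReport:
    """Outcome of a maximum-likelihood logistic fit."""

    model: LogisticModel
    converged: bool
    iterations: int
    log_likelihood: float
    separation_flag: bool
    per_class_rate: dict[str, float]


def _as_binary_labels(labels) -> np.ndarray:
    """Map labels to {0, 1} with solitary = 1, gregarious = 0."""
    arr = np.asarray(labels)
    if arr.dtype.kind in "OU":
        mapping = {SOLITARY: 1, GREGARIOUS: 0}
        try:
            return np.array([mapping[str(v)] for v in arr], dtype=float)
        except KeyError as exc:
            raise ValueError(f"unknown class label {exc.args[0]!r}") from None
    out = arr.astype(float)
    if not np.all(np.isin(out, (0.0, 1.0))):
        raise ValueError("numeric labels must be 0 (gregarious) or 1 (solitary)")
    return out


def _design(features, markers: Sequence[str] | None):
    if isinstance(features, pd.DataFrame):
        if markers is None:
            markers = [m for m in MARKERS if m in features.columns]
        X = features.loc[:, list(markers)].to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        if markers is None:
            markers = [f"X{i + 1}" for i in range(X.shape[1])]
    return X, tuple(markers)


def fit_logistic(
    features,
    labels,
    markers: Sequence[str] | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> FitReport:
    """Maximum-likelihood logistic regression by Newton iteration.

    ``features`` is a DataFrame with marker columns (or a plain matrix
    with ``markers`` naming its columns); ``labels`` are class names or
    0/1 with solitary coded 1.  Convergence is declared when the largest
    coefficient change falls below ``tol``.  Complete separation is not
    an error: the fit stops and reports ``separation_flag`` once any
    slope magnitude exceeds ``SEPARATION_BOUND`` without convergence.
    Rank-deficient designs raise :class:`DegenerateDesignError`.
    """
    X, marker_names = _design(features, markers)
    y = _as_binary_labels(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels must have equal length")
    for cls in (0.0, 1.0):
        if np.sum(y == cls) < 2:
            raise ValueError("need at least 2 animals per class")
    Xd = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise DegenerateDesignError("design matrix is rank deficient")

    beta = np.zeros(Xd.shape[1])
    converged = False
    separation = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        eta = Xd @ beta
        p = expit(eta)
        w = np.clip(p * (1.0 - p), 1e-12, None)
        grad = Xd.T @ (y - p)
        H = (Xd * w[:, None]).T @ Xd
        try:
            delta = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separation = True
            break
        beta += delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break
        if np.max(np.abs(beta[1:])) > SEPARATION_BOUND:
            separation = True
            break

    eta = Xd @ beta
    ll = float(np.sum(np.where(y == 1, log_expit(eta), log_expit(-eta))))
    model = LogisticModel(
        intercept=float(beta[0]),
        coefficients={m: float(b) for m, b in zip(marker_names, beta[1:])},
        name="refit",
    )
    pred = (expit(eta) >= model.threshold).astype(float)
    rates = {
        SOLITARY: float(np.mean(pred[y == 1] == 1)),
        GREGARIOUS: float(np.mean(pred[y == 0] == 0)),
    }
    return FitReport(
        model=model,
        converged=converged,
        iterations=iterations,
        log_likelihood=ll,
        separation_flag=separation and not converged,
        per_class_rate=rates,
    )


def select_markers(
    features: pd.DataFrame,
    labels,
    candidates: Sequence[str] = MARKERS,
    criterion: str = "bic",
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[tuple[str, ...], FitReport]:
    """Forward marker selection for the solitariness model.

    Starting from the intercept-only model, repeatedly add the candidate
    that most improves the criterion — ``"bic"`` (default), ``"aic"``,
    or ``"accuracy"`` (overall correct-classification rate) — stopping
    when no addition improves it strictly.  With eleven candidates a
    greedy search maximises over many near-chi-square improvements each
    round, so the stiffer BIC penalty is the default: it keeps the
    expected number of falsely selected markers near zero on pure-noise
    designs, where AIC would typically admit several.  Ties break by the
    canonical marker order.  Degenerate additions (e.g. a perfect
    duplicate of a selected marker) are skipped.
    """
    if criterion not in ("bic", "aic", "accuracy"):
        raise ValueError("criterion must be 'bic', 'aic' or 'accuracy'")
    y = _as_binary_labels(labels)
    candidates = [m for m in MARKERS if m in candidates]

    def fit(markers: list[str]) -> FitReport:
        if markers:
            return fit_logistic(features, y, markers=markers, max_iter=max_iter, tol=tol)
        # intercept-only fit has closed form
        p1 = float(np.mean(y))
        p1 = min(max(p1, 1e-12), 1 - 1e-12)
        beta0 = float(np.log(p1 / (1 - p1)))
        ll = float(np.sum(np.where(y == 1, np.log(p1), np.log(1 - p1))))
        pred = 1.0 if p1 >= 0.5 else 0.0
        model = LogisticModel(intercept=beta0, coefficients={}, name="refit")
        return FitReport(
            model=model,
            converged=True,
            iterations=0,
            log_likelihood=ll,
            separation_flag=False,
            per_class_rate={
                SOLITARY: float(np.mean((y == 1) == (pred == 1.0))),
                GREGARIOUS: float(np.mean((y == 0) == (pred == 0.0))),
            },
        )

    n_obs = len(y)

    def score(report: FitReport, k: int) -> float:
        if criterion == "bic":
            return float(np.log(n_obs)) * (k + 1) - 2.0 * report.log_likelihood
        if criterion == "aic":
            return 2.0 * (k + 1) - 2.0 * report.log_likelihood  # lower is better
        eta = report.model.intercept + sum(
            report.model.coefficients[m] * features[m].to_numpy(dtype=float)
            for m in report.model.coefficients
        )
        return -float(np.mean((expit(eta) >= 0.5) == (y == 1)))  # lower is better

    selected: list[str] = []
    best_report = fit(selected)
    best_score = score(best_report, 0)
    remaining = [m for m in candidates]
    improved = True
    while improved and remaining:
        improved = False
        round_best: tuple[float, str, FitReport] | None = None
        for m in remaining:
            try:
                rep = fit(selected + [m])
            except DegenerateDesignError:
                continue
            s = score(rep, len(selected) + 1)
            if round_best is None or s < round_best[0] - 1e-12:
                round_best = (s, m, rep)
        if round_best is not None and round_best[0] < best_score - 1e-12:
            best_score, chosen, best_report = round_best
            selected.append(chosen)
            remaining.remove(chosen)
            improved = True
    return tuple(selected), best_report


def classification_rates(model: LogisticModel, features, labels) -> dict[str, float]:
    """Fraction correctly classified within each true class."""
    y = _as_binary_labels(labels)
    if np.sum(y == 1) == 0 or np.sum(y == 0) == 0:
        raise ValueError("both classes must be represented")
    if isinstance(features, pd.DataFrame):
        rows = (row for _, row in features.iterrows())
    else:
        rows = iter(features)
    pred = np.array([1.0 if classify(model, fv) == SOLITARY else 0.0 for fv in rows])
    return {
        SOLITARY: float(np.mean(pred[y == 1] == 1)),
        GREGARIOUS: float(np.mean(pred[y == 0] == 0)),
    }


def score_features(table: pd.DataFrame, model: LogisticModel) -> pd.DataFrame:
    """Append ``eta``, ``P_sol`` and ``predicted_label`` columns."""
    out = table.copy()
    eta = np.full(len(out), model.intercept, dtype=float)
    for name, beta in model.coefficients.items():
        if name not in out.columns:
            raise KeyError(f"marker {name!r} missing from feature table")
        eta += beta * out[name].to_numpy(dtype=float)
    psol = expit(eta)
    out["eta"] = eta
    out["P_sol"] = psol
    out["predicted_label"] = np.where(psol >= model.threshold, SOLITARY, GREGARIOUS)
    return out
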
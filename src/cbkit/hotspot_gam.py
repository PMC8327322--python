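"""Mutational-hotspot estimation with a penalized-spline binomial GAM.

The hotspot model regresses case/control status on gene-level burden and
residue position:

    logit P(case) = beta0 + beta1 * carrier + f(position) * carrier

``carrier`` indicates carriage of a rare missense variant in the gene;
``f`` is a penalized cubic B-spline smooth of residue position.  Position
is meaningless for non-carriers, so the smooth enters only through its
interaction with carrier status — the basis rows of the two aggregated
non-carrier observations are identically zero.  Fitting all rare variants
in cases *and* controls (including any pathogenic variants carried by
controls) makes the model agnostic to prior classifications and lets it
absorb incomplete penetrance and benign background variation.

The per-position log odds ratio of interest is the carrier-at-position-x
versus non-carrier contrast ``beta1 + f(x)``; exponentiated with a
delta-method 95% CI it gives the regional burden ("hotspot") curve, and
its strata (OR >= 5 / 10 / 20 / 100) provide graded quantitative evidence
for hotspot-based variant interpretation.

Numerics: equally spaced (uniform) B-spline knots extended beyond [1, L]
with a second-order difference penalty on the coefficients — the standard
P-spline construction, whose penalty null space is exactly the constant
and linear functions of position; a sum-to-zero constraint over the
carrier observations makes the smooth identifiable next to ``beta1``.
The smoothing parameter is chosen by Laplace-approximate REML (or GCV)
via bounded scalar optimization on log lambda; coefficients come from
penalized iteratively reweighted least squares (PIRLS), the covariance is
the inverse penalized Fisher information, and the effective degrees of
freedom are trace((H + lambda*S)^-1 H).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats
from scipy.interpolate import BSpline
from scipy.special import expit

from .core_data import CASE, CONTROL, GeneDataset, carrier_summary

__all__ = [
    "GamFrame",
    "HotspotModel",
    "PositionPrediction",
    "SmallSampleError",
    "SeparationError",
    "ConvergenceError",
    "assemble_gam_frame",
    "fit_hotspot",
    "predict_log_or",
    "predict_position_or",
    "stratify_evidence",
    "probability_odds_map",
    "empirical_or_haldane",
    "save_model",
    "load_model",
]

#: Minimum carrier observations for a stable positional smooth.
MIN_CARRIERS = 20

#: Evidence strata on the odds-ratio point-estimate scale.
EVIDENCE_THRESHOLDS = (
    ("strong", 100.0),
    ("moderate", 20.0),
    ("supporting", 10.0),
    ("weak", 5.0),
)

_Z95 = 1.96


class SmallSampleError(ValueError):
    """Too few carrier observations to fit a positional smooth."""


class SeparationError(RuntimeError):
    """All carriers belong to one cohort; the model is not identifiable."""


class ConvergenceError(RuntimeError):
    """PIRLS failed to converge; carries the last coefficient state."""

    def __init__(self, message: str, beta: np.ndarray | None = None):
        super().__init__(message)
        self.beta = beta


@dataclass
class GamFrame:
    """Model frame for the hotspot GAM.

    Carrier rows come first — one per carrier, in dataset order with
    ``carrier_count`` expansion — followed by two aggregated non-carrier
    rows (case then control) whose weights are the non-carrier counts
    times the coverage weight.  ``weight`` multiplies each row's
    log-likelihood contribution (reciprocal mean 10x coverage around the
    variant for carriers, gene-wide for the aggregate rows).
    """

    is_case: np.ndarray
    carrier: np.ndarray
    position: np.ndarray
    weight: np.ndarray
    gene: str
    L: int

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=float)
        self.carrier = np.asarray(self.carrier, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        self.weight = np.asarray(self.weight, dtype=float)
        n = self.is_case.shape[0]
        for name in ("carrier", "position", "weight"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} must align with is_case")
        if np.any(self.weight < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n_carrier_rows(self) -> int:
        return int(self.carrier.sum())

    def carrier_mask(self) -> np.ndarray:
        return self.carrier > 0.5


@dataclass
class PositionPrediction:
    """Per-position (or per-variant) odds-ratio prediction."""

    position: int
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    evidence: str


def _window_mean_coverage(cov: np.ndarray, pos: int, window: int) -> float:
    lo = max(0, pos - 1 - window)
    hi = min(len(cov), pos + window)
    return float(cov[lo:hi].mean())


def assemble_gam_frame(
    ds: GeneDataset,
    coverage_window: int = 15,
    min_carriers: int = MIN_CARRIERS,
    allow_small: bool = False,
) -> GamFrame:
    """Build the GAM model frame from a gene dataset.

    Each carrier contributes one row (response = its cohort) weighted by
    the reciprocal of the mean 10x coverage within ``+-coverage_window``
    residues for its cohort; the two aggregated non-carrier rows are
    weighted by non-carrier count divided by the gene-wide mean coverage.
    With no coverage profiles all coverage weights are 1.

    Genes with fewer than ``min_carriers`` carrier observations are
    refused unless ``allow_small`` — sparse data give unstable smooths.
    """
    case_car, ctrl_car, case_non, ctrl_non = carrier_summary(ds)
    total_carriers = case_car + ctrl_car
    if total_carriers < min_carriers and not allow_small:
        raise SmallSampleError(
            f"{ds.gene}: {total_carriers} carrier observations < {min_carriers}; "
            "pass allow_small=True to override"
        )
    is_case: list[float] = []
    carrier: list[float] = []
    position: list[float] = []
    weight: list[float] = []
    for v in ds.variants:
        cov = ds.coverage(v.cohort)
        w = 1.0 if cov is None else 1.0 / _window_mean_coverage(
            cov, v.residue_position, coverage_window
        )
        for _ in range(v.carrier_count):
            is_case.append(1.0 if v.cohort == CASE else 0.0)
            carrier.append(1.0)
            position.append(float(v.residue_position))
            weight.append(w)
    # aggregated non-carrier rows (position 0: the smooth is zeroed anyway)
    for y, count, cov in (
        (1.0, case_non, ds.coverage_case),
        (0.0, ctrl_non, ds.coverage_control),
    ):
        w_cov = 1.0 if cov is None else 1.0 / float(np.mean(cov))
        is_case.append(y)
        carrier.append(0.0)
        position.append(0.0)
        weight.append(count * w_cov)
    return GamFrame(
        is_case=np.array(is_case), carrier=np.array(carrier),
        position=np.array(position), weight=np.array(weight),
        gene=ds.gene, L=ds.protein_length,
    )


# ---------------------------------------------------------------------------
# basis, penalty and fitting
# ---------------------------------------------------------------------------


def _uniform_knots(L: int, dim: int, degree: int = 3) -> np.ndarray:
    """Equally spaced knot vector covering [1, L], extended ``degree`` each side."""
    n_seg = dim - degree
    if n_seg < 1:
        raise ValueError(f"basis_dim must exceed the spline degree, got {dim}")
    h = (L - 1.0) / n_seg if L > 1 else 1.0
    return 1.0 + h * np.arange(-degree, n_seg + degree + 1)


def _basis_matrix(x: np.ndarray, knots: np.ndarray, degree: int = 3) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return np.zeros((0, len(knots) - degree - 1))
    return BSpline.design_matrix(x, knots, degree).toarray()


def _difference_penalty(dim: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(dim), n=order, axis=0)
    return D.T @ D


@dataclass
class HotspotModel:
    """Fitted hotspot (or hotspot+) model.

    Coefficient layout: ``[beta0, beta1, spline (dim-1 after the
    sum-to-zero constraint), feature coefficients...]``.  ``cov`` is the
    Bayesian posterior covariance (inverse penalized Fisher information).
    """

    gene: str
    L: int
    beta: np.ndarray
    cov: np.ndarray
    lam: float
    edf: float
    edf_smooth: float
    knots: np.ndarray
    degree: int
    constraint: np.ndarray          # (dim, dim-1) null-space map Z
    feature_names: tuple[str, ...] = ()
    smoothing: str = "REML"
    converged: bool = True

    @property
    def beta0(self) -> float:
        return float(self.beta[0])

    @property
    def beta1(self) -> float:
        return float(self.beta[1])

    @property
    def spline_coefs(self) -> np.ndarray:
        q = len(self.feature_names)
        return self.beta[2 : len(self.beta) - q]

    @property
    def n_spline(self) -> int:
        return self.constraint.shape[1]

    def smooth_basis(self, positions: np.ndarray) -> np.ndarray:
        """Constrained spline basis rows for carrier positions."""
        B = _basis_matrix(np.asarray(positions, dtype=float), self.knots, self.degree)
        return B @ self.constraint

    def contrast_rows(
        self, positions: np.ndarray, scores: np.ndarray | None = None
    ) -> np.ndarray:
        """Rows v with v @ beta = carrier-vs-non-carrier log OR at x."""
        positions = np.atleast_1d(np.asarray(positions, dtype=float))
        n = positions.shape[0]
        q = len(self.feature_names)
        V = np.zeros((n, len(self.beta)))
        V[:, 1] = 1.0
        V[:, 2 : 2 + self.n_spline] = self.smooth_basis(positions)
        if q:
            if scores is None:
                raise ValueError("model has feature terms; scores are required")
            scores = np.atleast_2d(np.asarray(scores, dtype=float))
            if scores.shape != (n, q):
                raise ValueError(f"scores must have shape ({n}, {q})")
            V[:, 2 + self.n_spline :] = scores
        return V

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "L": self.L,
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "lam": self.lam,
            "edf": self.edf,
            "edf_smooth": self.edf_smooth,
            "knots": self.knots.tolist(),
            "degree": self.degree,
            "constraint": self.constraint.tolist(),
            "feature_names": list(self.feature_names),
            "smoothing": self.smoothing,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HotspotModel":
        return cls(
            gene=d["gene"], L=int(d["L"]), beta=np.array(d["beta"]),
            cov=np.array(d["cov"]), lam=float(d["lam"]), edf=float(d["edf"]),
            edf_smooth=float(d["edf_smooth"]), knots=np.array(d["knots"]),
            degree=int(d["degree"]), constraint=np.array(d["constraint"]),
            feature_names=tuple(d["feature_names"]), smoothing=d["smoothing"],
            converged=bool(d["converged"]),
        )


def save_model(model: HotspotModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path) -> HotspotModel:
    with open(path) as fh:
        return HotspotModel.from_dict(json.load(fh))


def _design(
    frame: GamFrame,
    basis_dim: int,
    features: np.ndarray | None,
    degree: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Build (X, penalty, knots, Z, S_z) for the frame."""
    knots = _uniform_knots(frame.L, basis_dim, degree)
    carriers = frame.carrier_mask()
    B = np.zeros((len(frame.is_case), basis_dim))
    B[carriers] = _basis_matrix(frame.position[carriers], knots, degree)
    # sum-to-zero constraint over carrier rows: 1' B Z = 0
    c = B[carriers].sum(axis=0)
    Z = linalg.null_space(c.reshape(1, -1))          # (dim, dim-1)
    Bz = B @ Z
    S_z = Z.T @ _difference_penalty(basis_dim) @ Z
    cols = [np.ones(len(frame.is_case)), frame.carrier, Bz]
    if features is not None and features.shape[1]:
        F = np.zeros((len(frame.is_case), features.shape[1]))
        F[carriers] = features
        cols.append(F)
    X = np.column_stack(cols)
    n_params = X.shape[1]
    P = np.zeros((n_params, n_params))
    P[2 : 2 + S_z.shape[0], 2 : 2 + S_z.shape[1]] = S_z
    return X, P, knots, Z, S_z


def _ridge_solve(H: np.ndarray, b: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    """Solve H x = b, escalating a diagonal ridge if H is numerically
    semi-definite (e.g. quasi-separated data flattening the curvature)."""
    # perturb each coordinate relative to its own curvature so that
    # heterogeneous blocks (huge penalized spline vs small unpenalized
    # terms) are not cross-contaminated
    diag = np.maximum(np.abs(np.diag(H)), 1e-300)
    try:
        return linalg.cho_solve(linalg.cho_factor(H), b)
    except linalg.LinAlgError:
        pass
    ridge = 1e-14
    while ridge <= 1e-2:
        try:
            cho = linalg.cho_factor(H + ridge * np.diag(diag))
            return linalg.cho_solve(cho, b)
        except linalg.LinAlgError:
            ridge *= 1e4
    sol, *_ = np.linalg.lstsq(H, b, rcond=None)
    return sol if np.all(np.isfinite(sol)) else fallback


def _pirls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    P: np.ndarray,
    lam: float,
    beta0: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Penalized IRLS for a weighted binomial GLM.

    Returns (beta, penalized Hessian, log-likelihood).
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    if beta0 is None:
        mean_y = float(np.average(y, weights=np.maximum(w, 1e-12)))
        mean_y = min(max(mean_y, 1e-6), 1 - 1e-6)
        beta[0] = math.log(mean_y / (1 - mean_y))
    last_obj = np.inf
    H = None
    for it in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        Wd = w * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        XtW = X.T * Wd
        H = XtW @ X + lam * P
        beta_new = _ridge_solve(H, XtW @ z, beta)
        # step-halving on the penalized deviance
        def objective(b):
            e = X @ b
            m = np.clip(expit(e), 1e-12, 1 - 1e-12)
            ll = float(np.sum(w * (y * np.log(m) + (1 - y) * np.log(1 - m))))
            return -ll + 0.5 * lam * float(b @ P @ b)

        obj = objective(beta_new)
        step = 1.0
        while not np.isfinite(obj) or obj > last_obj + 1e-10:
            step *= 0.5
            if step < 1e-8:
                break
            beta_new = beta + step * (beta_new - beta)
            obj = objective(beta_new)
        delta = np.max(np.abs(beta_new - beta)) / (1.0 + np.max(np.abs(beta_new)))
        beta = beta_new
        if abs(last_obj - obj) < tol * (1.0 + abs(obj)) and delta < 1e-8:
            last_obj = obj
            break
        last_obj = obj
    else:
        raise ConvergenceError(f"PIRLS did not converge in {max_iter} iterations", beta)
    # polish: Newton converges quadratically, so two further steps push the
    # score to machine precision (the stopping rule above fires early on
    # near-flat objectives)
    for _ in range(2):
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
        Wd = w * mu * (1 - mu)
        z = eta + (y - mu) / (mu * (1 - mu))
        XtW = X.T * Wd
        beta = _ridge_solve(XtW @ X + lam * P, XtW @ z, beta)
    eta = X @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    ll = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
    Wd = w * mu * (1 - mu)
    H = (X.T * Wd) @ X + lam * P
    return beta, H, ll


def _log_det_penalty(S_z: np.ndarray) -> tuple[float, int]:
    """log of the product of positive eigenvalues of S_z, and its rank."""
    eig = np.linalg.eigvalsh(S_z)
    pos = eig[eig > 1e-10 * max(eig.max(), 1.0)]
    return float(np.sum(np.log(pos))), int(pos.size)


def _reml_criterion(
    loglam: float,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    P: np.ndarray,
    S_z: np.ndarray,
    logdet_s: float,
    rank_s: int,
    beta0: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    lam = math.exp(loglam)
    beta, H, ll = _pirls(X, y, w, P, lam, beta0=beta0)
    pen_ll = ll - 0.5 * lam * float(beta @ P @ beta)
    sign, logdet_h = np.linalg.slogdet(H)
    if sign <= 0:
        return np.inf, beta
    reml = -pen_ll + 0.5 * logdet_h - 0.5 * (rank_s * loglam + logdet_s)
    return reml, beta


def _gcv_criterion(
    loglam: float,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    P: np.ndarray,
    beta0: np.ndarray | None,
) -> tuple[float, np.ndarray]:
    lam = math.exp(loglam)
    beta, H, ll = _pirls(X, y, w, P, lam, beta0=beta0)
    cov = np.linalg.inv(H)
    edf = float(np.trace(cov @ (H - lam * P)))
    n = float(np.sum(w))
    deviance = -2.0 * ll
    denom = max(n - edf, 1e-8)
    return n * deviance / denom ** 2, beta


def fit_hotspot(
    frame: GamFrame,
    basis_dim: int = 10,
    smoothing: str = "REML",
    lam: float | None = None,
    features: np.ndarray | None = None,
    feature_names: Sequence[str] = (),
    loglam_bounds: tuple[float, float] = (-8.0, 16.0),
) -> HotspotModel:
    """Fit the hotspot GAM by PIRLS with automatic smoothing selection.

    ``smoothing`` is "REML" (Laplace-approximate restricted likelihood,
    the default) or "GCV"; ``lam`` fixes the smoothing parameter and
    skips selection.  ``features``, when given, are carrier-row-aligned
    columns added as unpenalized linear terms interacted with carrier
    status (the hotspot+ extension).
    """
    carriers = frame.carrier_mask()
    y_car = frame.is_case[carriers]
    if carriers.sum() < 3:
        raise SmallSampleError("need at least 3 carrier rows")
    if np.all(y_car == 1.0) or np.all(y_car == 0.0):
        raise SeparationError(
            f"{frame.gene}: all carriers in one cohort; "
            "carrier-status effect is not identifiable"
        )
    if features is not None:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[0] != int(carriers.sum()):
            raise ValueError("features must be (n_carrier_rows, q)")
        if features.shape[1] != len(feature_names):
            raise ValueError("feature_names must match feature columns")
        if features.shape[1]:
            rank = np.linalg.matrix_rank(
                np.column_stack([np.ones(features.shape[0]), features])
            )
            if rank < features.shape[1] + 1:
                raise ValueError(
                    f"collinear feature set: {tuple(feature_names)}"
                )
    X, P, knots, Z, S_z = _design(frame, basis_dim, features)
    y, w = frame.is_case, frame.weight
    keep = w > 0
    Xk, yk, wk = X[keep], y[keep], w[keep]

    logdet_s, rank_s = _log_det_penalty(S_z)
    if smoothing.upper() not in ("REML", "GCV"):
        raise ValueError("smoothing must be 'REML' or 'GCV'")

    if lam is None:
        def crit(ll_: float) -> float:
            try:
                if smoothing.upper() == "REML":
                    return _reml_criterion(
                        ll_, Xk, yk, wk, P, S_z, logdet_s, rank_s, None
                    )[0]
                return _gcv_criterion(ll_, Xk, yk, wk, P, None)[0]
            except ConvergenceError:
                return np.inf

        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            crit, bounds=loglam_bounds, method="bounded",
            options={"xatol": 1e-4},
        )
        lam = float(math.exp(res.x))

    beta, H, ll = _pirls(Xk, yk, wk, P, lam)
    cov = np.linalg.inv(H)
    Hfisher = H - lam * P
    A = cov @ Hfisher
    edf = float(np.trace(A))
    edf_smooth = float(np.trace(A[2 : 2 + S_z.shape[0], 2 : 2 + S_z.shape[1]]))
    return HotspotModel(
        gene=frame.gene, L=frame.L, beta=beta, cov=cov, lam=lam, edf=edf,
        edf_smooth=edf_smooth, knots=knots, degree=3, constraint=Z,
        feature_names=tuple(feature_names), smoothing=smoothing.upper(),
    )


# ---------------------------------------------------------------------------
# prediction and evidence
# ---------------------------------------------------------------------------


def predict_log_or(
    model: HotspotModel,
    positions: Sequence[int] | np.ndarray,
    scores: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Carrier-vs-non-carrier log OR and delta-method SE at each position."""
    positions = np.atleast_1d(np.asarray(positions))
    if np.any(positions < 1) or np.any(positions > model.L):
        raise ValueError(f"positions must lie in [1, {model.L}]")
    V = model.contrast_rows(positions.astype(float), scores)
    log_or = V @ model.beta
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", V, model.cov, V), 0.0))
    return log_or, se


def predict_position_or(
    model: HotspotModel,
    positions: Sequence[int] | np.ndarray,
    scores: np.ndarray | None = None,
) -> list[PositionPrediction]:
    """Per-position OR with 95% CI and evidence stratum."""
    positions = np.atleast_1d(np.asarray(positions))
    log_or, se = predict_log_or(model, positions, scores)
    out = []
    for pos, lo_, se_ in zip(positions, log_or, se):
        or_ = math.exp(lo_)
        out.append(
            PositionPrediction(
                position=int(pos), log_or=float(lo_), se=float(se_), or_=or_,
                ci_low=math.exp(lo_ - _Z95 * se_),
                ci_high=math.exp(lo_ + _Z95 * se_),
                evidence=stratify_evidence(or_),
            )
        )
    return out


def stratify_evidence(or_value: float) -> str:
    """Evidence stratum for an odds-ratio point estimate.

    OR >= 100 strong, >= 20 moderate, >= 10 supporting, >= 5 weak,
    else none.
    """
    if or_value <= 0:
        raise ValueError("odds ratio must be positive")
    for name, threshold in EVIDENCE_THRESHOLDS:
        if or_value >= threshold:
            return name
    return "none"


def probability_odds_map(p: float) -> float:
    """Odds p/(1-p) for a case probability p in (0, 1).

    Probability thresholds 0.9 / 0.95 / 0.99 correspond to odds 9 / 19 /
    99, i.e. ORs of roughly 10 / 20 / 100 against an even prior.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    return p / (1.0 - p)


def empirical_or_haldane(
    case_carriers: int,
    case_non: int,
    ctrl_carriers: int,
    ctrl_non: int,
) -> tuple[float, float, float]:
    """Empirical OR with a Haldane correction and Woolf 95% CI.

    If any cell of the 2x2 table is zero, 0.5 is added to all four cells
    before computing OR = (a*d)/(b*c); the CI is
    exp(log OR +- 1.96 * sqrt(sum 1/cell)).
    """
    cells = [case_carriers, case_non, ctrl_carriers, ctrl_non]
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    if case_carriers == 0 and ctrl_carriers == 0:
        raise ValueError("no carriers observed in either cohort")
    a, b, c, d = (float(x) for x in cells)
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, or_ * math.exp(-_Z95 * se), or_ * math.exp(_Z95 * se)
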
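"""Growth-response regression: the five model families Y1–Y5.

NDVI is regressed on a soil feature (instantaneous ST/SMC/SEC or
cumulative SST/SSMC/SSEC) or on all three at once ("multiparameter
fusion"). The candidate families are

* Y1–Y3 — polynomials of degree 1, 2, 3;
* Y4 — one-term power law  y = a·x^b;
* Y5 — two-term power law  y = a·x^b + c  (univariate only).

For ternary (three-feature) fits the polynomial basis contains every
monomial of total degree ≤ d including cross terms, and the power
family becomes an additive per-feature power law
y = a₁x₁^b₁ + a₂x₂^b₂ + a₃x₃^b₃.

The module follows the Model / Results idiom: ``GrowthModel(y, x,
family)`` holds data and family, ``fit()`` returns a
:class:`GrowthResults` carrying coefficients, construction metrics
(SSE, dof-corrected RMSE, R², adjusted R²), prediction and a summary
table. ``run_model_grid`` sweeps features × families with a
chronological train/validation split.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import metrics as _metrics

__all__ = [
    "ModelSpec",
    "FAMILY_ALIASES",
    "build_design",
    "GrowthModel",
    "GrowthResults",
    "train_val_split",
    "run_model_grid",
]

POLY_FAMILIES = {"poly1": 1, "poly2": 2, "poly3": 3}
POWER_FAMILIES = ("power1", "power2")
FAMILY_ALIASES = {
    "Y1": "poly1", "Y2": "poly2", "Y3": "poly3", "Y4": "power1", "Y5": "power2",
}
_REVERSE_ALIASES = {v: k for k, v in FAMILY_ALIASES.items()}

# nonlinear fit policy: fixed multi-start grid, tight tolerance, capped restarts
_B_GRID = np.linspace(-3.0, 3.0, 7)
_NLS_TOL = 1e-10
_MAX_RESTARTS = 20


class FitError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Family identifier plus arity (univariate or ternary)."""

    family: str
    arity: str = "univariate"

    def __post_init__(self):
        family = FAMILY_ALIASES.get(self.family, self.family)
        object.__setattr__(self, "family", family)
        if family not in POLY_FAMILIES and family not in POWER_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.arity not in ("univariate", "ternary"):
            raise ValueError(f"arity must be univariate or ternary, got {self.arity!r}")
        if family == "power2" and self.arity == "ternary":
            raise ValueError("the two-term power family is univariate only")

    @property
    def alias(self) -> str:
        return _REVERSE_ALIASES[self.family]

    @property
    def is_power(self) -> bool:
        return self.family in POWER_FAMILIES

    @property
    def degree(self) -> int:
        if self.is_power:
            raise ValueError("power families have no polynomial degree")
        return POLY_FAMILIES[self.family]

    @property
    def n_features(self) -> int:
        """Feature count p entering the adjusted-R² penalty.

        Univariate polynomial: the degree. Power laws: 1 for the
        one-term form, 2 for the two-term form. Ternary polynomial:
        the number of non-intercept basis terms. Ternary power law: 3.
        """
        if self.arity == "univariate":
            if self.family == "power1":
                return 1
            if self.family == "power2":
                return 2
            return self.degree
        if self.family == "power1":
            return 3
        d = self.degree
        return sum(_n_monomials(3, k) for k in range(1, d + 1))


def _n_monomials(nvars: int, degree: int) -> int:
    from math import comb

    return comb(nvars + degree - 1, degree)


def _ternary_exponents(degree: int):
    """Exponent triples of all monomials of total degree 1..degree."""
    out = []
    for d in range(1, degree + 1):
        for combo in combinations_with_replacement(range(3), d):
            e = [0, 0, 0]
            for v in combo:
                e[v] += 1
            out.append(tuple(e))
    return out


def build_design(x, spec: ModelSpec) -> np.ndarray:
    """Polynomial basis matrix (intercept first) for the given family.

    Univariate degree d: columns [1, x, x², …, x^d].
    Ternary degree d: intercept plus every monomial of total degree ≤ d
    in the three features (cross terms included). Power families have
    no linear design and raise.
    """
    if spec.is_power:
        raise ValueError("power families are nonlinear; no design matrix")
    x = np.asarray(x, dtype=float)
    if spec.arity == "univariate":
        x = x.ravel()
        return np.column_stack([x**k for k in range(spec.degree + 1)])
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"ternary arity needs an (n, 3) feature array, got {x.shape}")
    cols = [np.ones(len(x))]
    for e in _ternary_exponents(spec.degree):
        cols.append(x[:, 0] ** e[0] * x[:, 1] ** e[1] * x[:, 2] ** e[2])
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# Nonlinear (power-law) fitting


def _power_predict(params, x, spec: ModelSpec):
    x = np.asarray(x, dtype=float)
    if spec.arity == "ternary":
        a = params[0::2][:3]
        b = params[1::2][:3]
        return sum(a[j] * x[:, j] ** b[j] for j in range(3))
    if spec.family == "power1":
        a, b = params
        return a * x**b
    a, b, c = params
    return a * x**b + c


def _power_starts(x, y, spec: ModelSpec):
    """Fixed multi-start grid over the exponent(s), amplitude from lstsq."""
    starts = []
    if spec.arity == "ternary":
        for b in (0.5, 1.0, 2.0):
            bs = np.full(3, b)
            basis = np.column_stack([x[:, j] ** b for j in range(3)])
            a, *_ = np.linalg.lstsq(basis, y, rcond=None)
            starts.append(np.ravel(np.column_stack([a, bs])))
        return starts[:_MAX_RESTARTS]
    x1 = x.ravel()
    for b in _B_GRID:
        xb = x1**b
        denom = float(xb @ xb)
        if not np.isfinite(denom) or denom == 0:
            continue
        if spec.family == "power1":
            a = float(xb @ y) / denom
            starts.append(np.array([a if a != 0 else 1.0, b]))
        else:
            basis = np.column_stack([xb, np.ones_like(xb)])
            try:
                coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
            except np.linalg.LinAlgError:
                continue
            starts.append(np.array([coef[0] if coef[0] != 0 else 1.0, b, coef[1]]))
    return starts[:_MAX_RESTARTS]


def _fit_power(x, y, spec: ModelSpec) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise FitError(
            f"{spec.alias} ({spec.family}) requires strictly positive features; "
            "apply a positive shift first"
        )
    best, best_sse = None, np.inf
    for start in _power_starts(x, y, spec):
        try:
            sol = least_squares(
                lambda p: _power_predict(p, x, spec) - y,
                start,
                xtol=_NLS_TOL,
                ftol=_NLS_TOL,
                gtol=_NLS_TOL,
                max_nfev=2000,
            )
        except (ValueError, FloatingPointError):
            continue
        resid = _power_predict(sol.x, x, spec) - y
        sse = float(resid @ resid)
        if np.isfinite(sse) and sse < best_sse:
            best, best_sse = sol.x, sse
    if best is None:
        raise FitError(f"power fit failed to converge from all starts (family {spec.family})")
    return best


# ---------------------------------------------------------------------------
# Model / Results


class GrowthModel:
    """Growth-response model of NDVI against one or three soil features.

    Parameters
    ----------
    y : target values (NDVI), length n
    x : feature vector (n,) for univariate families or (n, 3) for
        ternary fusion
    family : one of poly1/poly2/poly3/power1/power2 or the aliases
        Y1–Y5
    name : optional label for reports (e.g. "SST")
    """

    def __init__(self, y, x, family="poly3", arity=None, name=None):
        self.y = np.asarray(y, dtype=float).ravel()
        x = np.asarray(x, dtype=float)
        if arity is None:
            arity = "ternary" if x.ndim == 2 and x.shape[1] == 3 else "univariate"
        self.spec = ModelSpec(family, arity)
        self.x = x if arity == "ternary" else x.ravel()
        self.name = name or ("IMP" if arity == "ternary" else "x")
        n = len(self.y)
        if (self.x.shape[0] if self.x.ndim else 0) != n:
            raise ValueError("x and y lengths differ")
        if n <= self.spec.n_features + 1:
            raise ValueError(
                f"need n > p + 1 observations (n={n}, p={self.spec.n_features})"
            )

    @classmethod
    def from_epoch_table(cls, table: pd.DataFrame, feature, family="poly3",
                         target="ndvi_filtered", name=None):
        """Build from an epoch table; ``feature`` is a column name or a
        list of exactly three column names (ternary fusion)."""
        if isinstance(feature, (list, tuple)):
            x = table[list(feature)].to_numpy(float)
            name = name or "+".join(feature)
        else:
            x = table[feature].to_numpy(float)
            name = name or str(feature)
        return cls(table[target].to_numpy(float), x, family=family, name=name)

    def fit(self) -> "GrowthResults":
        """Estimate coefficients: linear least squares for polynomial
        families, tolerance-tightened multi-start nonlinear least
        squares for power laws. Deterministic (the start grid is fixed)."""
        if self.spec.is_power:
            params = _fit_power(self.x, self.y, self.spec)
        else:
            design = build_design(self.x, self.spec)
            params, *_ = np.linalg.lstsq(design, self.y, rcond=None)
        return GrowthResults(self, np.asarray(params, dtype=float))


class GrowthResults:
    """Fitted growth model: coefficients, fit metrics, prediction, summary."""

    def __init__(self, model: GrowthModel, params: np.ndarray):
        self.model = model
        self.params = params
        self.fittedvalues = self.predict(model.x)
        self._train = _metrics.construction_metrics(
            model.y, self.fittedvalues, p=model.spec.n_features
        )

    # -- metric accessors (construction conventions) --
    @property
    def nobs(self) -> int:
        return int(self._train["n"])

    @property
    def n_features(self) -> int:
        return self.model.spec.n_features

    @property
    def sse(self) -> float:
        return self._train["sse"]

    @property
    def rmse(self) -> float:
        """Residual standard error sqrt(SSE/(n-p-1))."""
        return self._train["rmse"]

    @property
    def rmse_plain(self) -> float:
        """Uncorrected RMSE sqrt(SSE/n)."""
        return self._train["rmse_plain"]

    @property
    def rsquared(self) -> float:
        return self._train["r2"]

    @property
    def rsquared_adj(self) -> float:
        return self._train["ar"]

    def predict(self, x) -> np.ndarray:
        spec = self.model.spec
        if spec.is_power:
            return _power_predict(self.params, np.asarray(x, dtype=float), spec)
        return build_design(x, spec) @ self.params

    def validate(self, x, y) -> dict[str, float]:
        """Held-out metrics (MSE, RMSE = sqrt(MSE), R², AR) on new data.

        AR is reported as NaN when the held-out split is too small for
        the feature count (n ≤ p + 1), which happens for the ternary
        cubic on a 12-epoch validation window.
        """
        y = np.asarray(y, dtype=float).ravel()
        yhat = self.predict(x)
        n, p = y.size, self.n_features
        mse = float(np.mean((y - yhat) ** 2))
        r2 = _metrics.r_squared(y, yhat)
        ar = _metrics.adjusted_r2(r2, n, p) if n > p + 1 else float("nan")
        return {"mse": mse, "rmse": float(np.sqrt(mse)), "r2": r2, "ar": ar,
                "n": n, "p": p}

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Growth model {spec.alias} ({spec.family}, {spec.arity}) "
            f"on {self.model.name}",
            f"  n = {self.nobs}, p = {self.n_features}",
            "  coefficients: " + ", ".join(f"{c:.6g}" for c in self.params),
            f"  SSE  = {self.sse:.4f}",
            f"  RMSE = {self.rmse:.4f}  (residual std. error)",
            f"  R2   = {self.rsquared:.4f}",
            f"  AR   = {self.rsquared_adj:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Split and grid


def train_val_split(n_rows: int, n_train: int = 60):
    """Chronological split: first ``n_train`` rows fit, the rest validate."""
    if hasattr(n_rows, "__len__"):
        n_rows = len(n_rows)
    if n_train < 1 or n_train >= n_rows:
        raise ValueError(f"n_train must be in [1, {n_rows - 1}], got {n_train}")
    idx = np.arange(n_rows)
    return idx[:n_train], idx[n_train:]


DEFAULT_FEATURE_SETS = {
    "ST": "st", "SMC": "smc", "SEC": "sec",
    "SST": "sst", "SSMC": "ssmc", "SSEC": "ssec",
    "IMP": ("st", "smc", "sec"), "SIMP": ("sst", "ssmc", "ssec"),
}


def _families_for(feature) -> tuple[str, ...]:
    ternary = isinstance(feature, (list, tuple))
    return ("Y1", "Y2", "Y3", "Y4") if ternary else ("Y1", "Y2", "Y3", "Y4", "Y5")


def run_model_grid(
    table: pd.DataFrame,
    feature_sets: dict | None = None,
    families: tuple[str, ...] | None = None,
    n_train: int = 60,
    target: str = "ndvi_filtered",
) -> pd.DataFrame:
    """Fit every feature set × family, evaluate on both splits.

    Returns one row per combination with construction metrics
    (sse, rmse, r2, ar) on the training split and validation metrics
    (mse, rmse_val, r2_val, ar_val) on the held-out split. Power
    families are skipped (with a NaN row) for features that are not
    strictly positive on the training split.
    """
    feature_sets = feature_sets or DEFAULT_FEATURE_SETS
    train_idx, val_idx = train_val_split(len(table), n_train)
    rows = []
    for item, feature in feature_sets.items():
        fams = families or _families_for(feature)
        for fam in fams:
            cols = list(feature) if isinstance(feature, (list, tuple)) else [feature]
            x_all = table[cols].to_numpy(float)
            x_tr = x_all[train_idx]
            x_va = x_all[val_idx]
            if len(cols) == 1:
                x_tr, x_va = x_tr.ravel(), x_va.ravel()
            y_tr = table[target].to_numpy(float)[train_idx]
            y_va = table[target].to_numpy(float)[val_idx]
            row = {"item": item, "model": fam}
            try:
                res = GrowthModel(y_tr, x_tr, family=fam, name=item).fit()
                row.update(
                    sse=res.sse, rmse=res.rmse, r2=res.rsquared, ar=res.rsquared_adj
                )
                val = res.validate(x_va, y_va)
                row.update(
                    mse=val["mse"], rmse_val=val["rmse"],
                    r2_val=val["r2"], ar_val=val["ar"],
                )
            except FitError:
                row.update({k: np.nan for k in
                            ("sse", "rmse", "r2", "ar", "mse", "rmse_val",
                             "r2_val", "ar_val")})
            rows.append(row)
    return pd.DataFrame(rows)
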
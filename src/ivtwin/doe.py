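"""Response-surface screening: design generation, quadratic fits,
stepwise reduction and desirability optimization.

The screening stage varies three factors (temperature, chaotrope
concentration, reaction-enhancing additive) over a 15-run design with
three center replicates, fits a full second-order polynomial per
response on coded (−1..+1) units, prunes non-significant terms by
backward elimination under an effect-hierarchy constraint, and locates
the joint optimum of several responses by maximizing the Derringer–Suich
composite desirability on a grid over the coded cube.

The default 15-run template is a three-factor Box–Behnken layout (the
12 edge midpoints of the cube plus center replicates), which supports
all pure-quadratic terms; a two-level factorial alternative
(``template="factorial"``: the 8 cube corners plus centers, whose
quadratic columns are aliased) is kept behind a flag for comparison.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

MAIN_TERMS = ("x1", "x2", "x3")
INTERACTION_TERMS = ("x1:x2", "x1:x3", "x2:x3")
QUADRATIC_TERMS = ("x1^2", "x2^2", "x3^2")
FULL_TERMS = MAIN_TERMS + INTERACTION_TERMS + QUADRATIC_TERMS


@dataclass(frozen=True)
class FactorSpec:
    """A DoE factor with physical bounds."""

    name: str
    low: float
    high: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"factor {self.name}: low must be < high")

    def to_physical(self, coded) -> np.ndarray:
        """coded −1..+1 → physical units (affine)."""
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        return mid + half * np.asarray(coded, dtype=float)

    def to_coded(self, physical) -> np.ndarray:
        mid = 0.5 * (self.low + self.high)
        half = 0.5 * (self.high - self.low)
        return (np.asarray(physical, dtype=float) - mid) / half


def default_factors() -> list[FactorSpec]:
    """The continuous-IVT screening factors: temperature 37–40 °C,
    urea 0.4–1.2 M, reaction-enhancing additive 0.1–1 mg/mL."""
    return [
        FactorSpec("temperature", 37.0, 40.0, "degC"),
        FactorSpec("urea", 0.4, 1.2, "M"),
        FactorSpec("additive", 0.1, 1.0, "mg/mL"),
    ]


@dataclass
class Design:
    """Run table in coded and physical units.

    ``runs`` columns: run_id, x1..x3 (coded), one physical column per
    factor, is_center.
    """

    runs: pd.DataFrame
    factors: list[FactorSpec]
    n_center: int
    seed: int | None = None

    def __post_init__(self) -> None:
        for i, f in enumerate(self.factors, start=1):
            coded = self.runs[f"x{i}"].to_numpy()
            phys = self.runs[f.name].to_numpy()
            if not np.allclose(phys, f.to_physical(coded), atol=1e-9):
                raise ValueError(
                    f"coded/physical mismatch for factor {f.name}"
                )

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def coded(self) -> np.ndarray:
        return self.runs[[f"x{i}" for i in range(1, len(self.factors) + 1)]].to_numpy()


def generate_design(
    factors: list[FactorSpec] | None = None,
    n_center: int = 3,
    seed: int | None = None,
    template: str = "box_behnken",
) -> Design:
    """The three-factor screening design (default: Box–Behnken + centers).

    Box–Behnken: the 12 midpoints of the cube edges — all sign
    combinations of two factors at ±1 with the third at 0 — plus
    ``n_center`` center replicates: 15 runs for the default.  Run order
    is shuffled when a seed is given (runs are exchangeable; the order
    is cosmetic).
    """
    if factors is None:
        factors = default_factors()
    if len(factors) != 3:
        raise ValueError(
            "the screening template is defined for exactly 3 factors; "
            "got %d" % len(factors)
        )
    if template == "box_behnken":
        pts = []
        for i, j in itertools.combinations(range(3), 2):
            for si, sj in itertools.product((-1.0, 1.0), repeat=2):
                p = [0.0, 0.0, 0.0]
                p[i], p[j] = si, sj
                pts.append(p)
    elif template == "factorial":
        pts = [list(p) for p in itertools.product((-1.0, 1.0), repeat=3)]
    else:
        raise ValueError(f"unknown template {template!r}")
    pts += [[0.0, 0.0, 0.0]] * n_center
    coded = np.array(pts)

    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(coded))
        coded = coded[order]

    runs = pd.DataFrame(coded, columns=["x1", "x2", "x3"])
    for i, f in enumerate(factors, start=1):
        runs[f.name] = f.to_physical(runs[f"x{i}"])
    runs["is_center"] = np.all(coded == 0.0, axis=1)
    runs.insert(0, "run_id", np.arange(1, len(runs) + 1))
    return Design(runs=runs, factors=factors, n_center=n_center, seed=seed)


def _model_matrix(coded: np.ndarray, terms: tuple[str, ...]) -> pd.DataFrame:
    x1, x2, x3 = coded[:, 0], coded[:, 1], coded[:, 2]
    cols = {
        "x1": x1, "x2": x2, "x3": x3,
        "x1:x2": x1 * x2, "x1:x3": x1 * x3, "x2:x3": x2 * x3,
        "x1^2": x1**2, "x2^2": x2**2, "x3^2": x3**2,
    }
    X = pd.DataFrame({t: cols[t] for t in terms})
    X.insert(0, "Intercept", 1.0)
    return X


@dataclass
class RSModel:
    """A fitted (possibly reduced) second-order response-surface model."""

    response: str
    terms: tuple[str, ...]
    coef: pd.Series
    se: pd.Series
    pvalues: pd.Series
    adj_R2: float
    design: Design
    y: np.ndarray

    def predict_coded(self, coded: np.ndarray) -> np.ndarray:
        coded = np.atleast_2d(np.asarray(coded, dtype=float))
        X = _model_matrix(coded, self.terms)
        return X.to_numpy() @ self.coef.reindex(X.columns).to_numpy()

    def predict_physical(self, physical: np.ndarray) -> np.ndarray:
        physical = np.atleast_2d(np.asarray(physical, dtype=float))
        coded = np.column_stack(
            [f.to_coded(physical[:, i]) for i, f in enumerate(self.design.factors)]
        )
        return self.predict_coded(coded)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "p_value": self.pvalues}
        )


def _fit_terms(design: Design, y: np.ndarray, terms: tuple[str, ...], response: str) -> RSModel:
    X = _model_matrix(design.coded, terms)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name the aliased columns for the caller
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased terms: {bad}")
    res = sm.OLS(y, X).fit()
    y = np.asarray(y, dtype=float)
    pvalues = res.pvalues.copy()
    adj_r2 = float(res.rsquared_adj)
    # degenerate cases: a constant response (or an exact, noise-free
    # surface) has zero residual variance, making t-stats 0/0 for truly
    # absent terms.  A numerically-zero coefficient carries no evidence:
    # report p = 1 so elimination can discard it; a constant response
    # explains nothing: adj R^2 = 0.
    scale = max(1.0, float(np.max(np.abs(y))))
    for term in pvalues.index:
        numerically_zero = (
            abs(res.params[term]) < 1e-9 * scale and res.bse[term] < 1e-9 * scale
        )
        if numerically_zero or (not np.isfinite(pvalues[term])):
            if abs(res.params[term]) < 1e-9 * scale:
                pvalues[term] = 1.0
    if not np.isfinite(adj_r2):
        adj_r2 = 0.0
    return RSModel(
        response=response,
        terms=terms,
        coef=res.params,
        se=res.bse,
        pvalues=pvalues,
        adj_R2=adj_r2,
        design=design,
        y=y,
    )


def fit_quadratic(design: Design, y: np.ndarray, response: str = "response") -> RSModel:
    """OLS fit of the full second-order model on coded units."""
    y = np.asarray(y, dtype=float)
    if len(y) != design.n_runs:
        raise ValueError(
            f"response length {len(y)} != run count {design.n_runs}"
        )
    return _fit_terms(design, y, FULL_TERMS, response)


def _parents(term: str) -> set[str]:
    if ":" in term:
        return set(term.split(":"))
    if "^2" in term:
        return {term.split("^")[0]}
    return set()


def _children(term: str, terms: tuple[str, ...]) -> set[str]:
    return {t for t in terms if term in _parents(t)}


def stepwise_reduce(model: RSModel, alpha: float = 0.05) -> RSModel:
    """Backward elimination by p-value under effect hierarchy.

    Repeatedly removes the highest-p *removable* term with p > alpha
    and refits; a term is removable only when no retained higher-order
    term depends on it (a main effect stays while any of its
    interactions or its quadratic is retained).  The intercept is never
    removed.
    """
    terms = model.terms
    current = model
    while True:
        removable = [
            t for t in terms
            if not _children(t, terms) and current.pvalues.get(t, 0.0) > alpha
        ]
        if not removable:
            return current
        worst = max(removable, key=lambda t: current.pvalues[t])
        terms = tuple(t for t in terms if t != worst)
        current = _fit_terms(current.design, current.y, terms, current.response)


def desirability_optimize(
    models: dict[str, RSModel],
    goals: dict[str, str],
    n_grid: int = 21,
) -> dict:
    """Joint optimum by Derringer–Suich composite desirability.

    Each response's individual desirability is a linear ramp over the
    range of its model predictions on the search grid (0 at the worst
    end, 1 at the best end; ``goals[name]`` is "maximize" or
    "minimize").  The composite is the geometric mean across responses,
    maximized by exhaustive search on an ``n_grid``³ grid over the coded
    cube.

    Returns the best coded and physical settings, the composite
    desirability and the per-response predictions there.
    """
    if not models:
        raise ValueError("need at least one model")
    names = list(models)
    design = models[names[0]].design
    for m in models.values():
        if m.design.factors != design.factors:
            raise ValueError("all models must share the factor space")
    for name in names:
        if goals.get(name) not in ("maximize", "minimize"):
            raise ValueError(f"goal for {name!r} must be maximize or minimize")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")

    axis = np.linspace(-1.0, 1.0, n_grid)
    grid = np.array(list(itertools.product(axis, axis, axis)))
    D = np.ones(len(grid))
    preds = {}
    for name in names:
        p = models[name].predict_coded(grid)
        preds[name] = p
        lo, hi = float(p.min()), float(p.max())
        if hi - lo < 1e-300:
            d = np.ones_like(p)
        elif goals[name] == "maximize":
            d = (p - lo) / (hi - lo)
        else:
            d = (hi - p) / (hi - lo)
        D *= d
    D = D ** (1.0 / len(names))
    best = int(np.argmax(D))
    coded_best = grid[best]
    physical_best = {
        f.name: float(f.to_physical(coded_best[i]))
        for i, f in enumerate(design.factors)
    }
    return {
        "coded": coded_best,
        "physical": physical_best,
        "desirability": float(D[best]),
        "predictions": {name: float(preds[name][best]) for name in names},
    }


def contour_eval(
    model: RSModel,
    factor_pair: tuple[str, str],
    fixed: dict[str, float],
    n_grid: int = 50,
) -> dict:
    """Model predictions on a rectangular physical grid of two factors.

    ``fixed`` gives the physical value of the remaining factor.
    Returns dict with 1-D axes ``x``/``y`` (physical units) and the
    prediction matrix ``z`` (shape len(y) × len(x))."""
    fnames = [f.name for f in model.design.factors]
    for nm in factor_pair:
        if nm not in fnames:
            raise ValueError(f"unknown factor {nm!r}")
    fx = model.design.factors[fnames.index(factor_pair[0])]
    fy = model.design.factors[fnames.index(factor_pair[1])]
    (fz,) = [f for f in model.design.factors if f.name not in factor_pair]
    if fz.name not in fixed:
        raise ValueError(f"fixed value for factor {fz.name!r} required")

    x = np.linspace(fx.low, fx.high, n_grid)
    y = np.linspace(fy.low, fy.high, n_grid)
    z = np.empty((n_grid, n_grid))
    for i, yv in enumerate(y):
        phys = np.zeros((n_grid, 3))
        phys[:, fnames.index(fx.name)] = x
        phys[:, fnames.index(fy.name)] = yv
        phys[:, fnames.index(fz.name)] = fixed[fz.name]
        z[i] = model.predict_physical(phys)
    return {"x": x, "y": y, "z": z,
            "factors": (fx.name, fy.name), "fixed": {fz.name: fixed[fz.name]}}
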
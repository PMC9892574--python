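"""Penalized B-spline smooths and additive-predictor design matrices.

An additive predictor is an intercept plus parametric (dummy-coded) terms
plus smooth functions of continuous covariates.  Each smooth is a B-spline
basis expansion with a difference penalty on its coefficients (the P-spline
convention) and a sum-to-zero centering constraint for identifiability; the
constraint is applied by reparameterising onto the orthogonal complement of
the basis column-sum vector, which drops one coefficient per smooth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = [
    "SmoothSpec",
    "EquationSpec",
    "AdditivePredictorDesign",
    "bspline_basis",
    "make_knots",
    "difference_penalty",
    "center_smooth",
    "build_design",
]


@dataclass(frozen=True)
class SmoothSpec:
    """One penalized smooth term.

    Parameters
    ----------
    covariate : str
        Column to smooth over.
    num_basis : int
        Number of B-spline basis functions J (default 10).
    degree : int
        Spline degree D (cubic by default).
    penalty_order : int
        Order of the difference penalty (second order by default).
    knot_placement : {"quantile", "equidistant"}
        Interior-knot rule; quantile placement is robust to skewed
        covariates such as income.
    """

    covariate: str
    num_basis: int = 10
    degree: int = 3
    penalty_order: int = 2
    knot_placement: str = "quantile"

    def __post_init__(self):
        if self.num_basis < self.degree + 2:
            raise ValueError("num_basis must be at least degree + 2")
        if self.penalty_order not in (1, 2, 3):
            raise ValueError("penalty_order must be 1, 2 or 3")
        if self.penalty_order >= self.num_basis:
            raise ValueError("penalty_order must be smaller than num_basis")
        if self.knot_placement not in ("quantile", "equidistant"):
            raise ValueError("knot_placement must be 'quantile' or 'equidistant'")


@dataclass(frozen=True)
class EquationSpec:
    """Description of one equation's additive predictor.

    ``parametric`` lists binary/categorical/linear columns (categoricals are
    dummy-coded against their first level); ``smooths`` lists the penalized
    smooth terms.  An intercept is always included.
    """

    response: str
    parametric: tuple = ()
    smooths: tuple = ()

    def __post_init__(self):
        object.__setattr__(self, "parametric", tuple(self.parametric))
        smooths = tuple(
            s if isinstance(s, SmoothSpec) else SmoothSpec(**s) if isinstance(s, dict)
            else SmoothSpec(str(s))
            for s in self.smooths
        )
        object.__setattr__(self, "smooths", smooths)

    @property
    def columns(self):
        return tuple(self.parametric) + tuple(s.covariate for s in self.smooths)


def make_knots(x: np.ndarray, spec: SmoothSpec) -> np.ndarray:
    """Knot sequence of length J + D + 1 covering the data range.

    Boundary knots are replicated D+1 times at the data min/max; the J - D - 1
    interior knots sit at quantiles (default) or equidistantly.  Falls back to
    equidistant placement when quantiles collide (discrete covariates).
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if not hi > lo:
        raise ValueError(f"covariate {spec.covariate!r} is constant; cannot smooth")
    n_int = spec.num_basis - spec.degree - 1
    if spec.knot_placement == "quantile" and n_int > 0:
        qs = np.linspace(0.0, 1.0, n_int + 2)[1:-1]
        interior = np.quantile(x, qs)
        if np.any(np.diff(np.concatenate([[lo], interior, [hi]])) <= 0):
            interior = np.linspace(lo, hi, n_int + 2)[1:-1]
    else:
        interior = np.linspace(lo, hi, n_int + 2)[1:-1] if n_int > 0 else np.empty(0)
    knots = np.concatenate([
        np.repeat(lo, spec.degree + 1), interior, np.repeat(hi, spec.degree + 1)
    ])
    assert knots.size == spec.num_basis + spec.degree + 1
    return knots


def bspline_basis(x, spec: SmoothSpec, knots: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the (n x J) B-spline basis via the Cox-de Boor recursion.

    Rows sum to one on the evaluation interval and each basis function is
    non-zero over at most D+1 adjacent knot spans.
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = make_knots(x, spec)
    lo, hi = knots[spec.degree], knots[-spec.degree - 1]
    bad = (x < lo) | (x > hi) | ~np.isfinite(x)
    if np.any(bad):
        raise ValueError(
            f"values of {spec.covariate!r} outside the spline support "
            f"[{lo:g}, {hi:g}]: {np.asarray(x)[bad][:10]}"
        )
    # evaluate at hi via the left-limit convention so the last basis reaches 1
    xe = np.where(x == hi, hi - 1e-12 * max(1.0, abs(hi)), x)
    B = BSpline.design_matrix(xe, knots, spec.degree, extrapolate=False).toarray()
    # restore exactness at the right boundary
    at_hi = x == hi
    if np.any(at_hi):
        row = np.zeros(B.shape[1])
        row[-1] = 1.0
        B[at_hi] = row
    return B


def difference_penalty(num_basis: int, order: int) -> np.ndarray:
    """J x J penalty matrix D_d' D_d for the d-th order difference operator."""
    if order >= num_basis:
        raise ValueError("difference order must be smaller than the basis size")
    D = np.diff(np.eye(num_basis), n=order, axis=0)
    return D.T @ D


def center_smooth(basis: np.ndarray, penalty: np.ndarray):
    """Apply the sum-to-zero identifiability constraint to one smooth block.

    Returns ``(centered_basis, centered_penalty, back_transform)`` where the
    back-transform Z maps constrained coefficients (length J-1) to the
    original J-space, the centered basis has zero column sums, and
    ``Z' P Z`` is the penalty in the constrained parameterisation.
    """
    basis = np.asarray(basis, dtype=float)
    penalty = np.asarray(penalty, dtype=float)
    if basis.shape[1] != penalty.shape[0]:
        raise ValueError("basis column count must match penalty dimension")
    norms = np.linalg.norm(basis, axis=0)
    if np.any(norms == 0.0):
        raise np.linalg.LinAlgError("degenerate basis: zero column")
    c = basis.sum(axis=0)
    Q, _ = np.linalg.qr(c.reshape(-1, 1), mode="complete")
    Z = Q[:, 1:]
    return basis @ Z, Z.T @ penalty @ Z, Z


@dataclass(frozen=True)
class _Block:
    name: str
    kind: str                   # "intercept" | "linear" | "dummy" | "smooth"
    sl: slice
    levels: tuple = ()          # dummy: full level list (first = reference)
    smooth: SmoothSpec | None = None
    knots: np.ndarray | None = None
    Z: np.ndarray | None = None          # centering back-transform
    penalty: np.ndarray | None = None    # centered penalty matrix


@dataclass(frozen=True)
class AdditivePredictorDesign:
    """Design matrix, penalty blocks and coefficient layout for one equation."""

    spec: EquationSpec
    X: np.ndarray
    column_names: tuple
    blocks: tuple

    @property
    def n_coef(self) -> int:
        return self.X.shape[1]

    @property
    def smooth_blocks(self):
        return tuple(b for b in self.blocks if b.kind == "smooth")

    def penalty_matrices(self):
        """Full-size (n_coef x n_coef) penalty matrix per smooth term."""
        out = []
        for b in self.smooth_blocks:
            S = np.zeros((self.n_coef, self.n_coef))
            S[b.sl, b.sl] = b.penalty
            out.append(S)
        return out

    def matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Design matrix for (possibly new) data using the stored layout."""
        n = len(data)
        X = np.zeros((n, self.n_coef))
        for b in self.blocks:
            if b.kind == "intercept":
                X[:, b.sl] = 1.0
            elif b.kind == "linear":
                X[:, b.sl] = _numeric_column(data, b.name)[:, None]
            elif b.kind == "dummy":
                vals = data[b.name].astype(str).to_numpy()
                unseen = set(vals) - set(b.levels)
                if unseen:
                    raise ValueError(
                        f"column {b.name!r} has unseen categories {sorted(unseen)}"
                    )
                for j, lev in enumerate(b.levels[1:]):
                    X[:, b.sl.start + j] = (vals == lev).astype(float)
            else:  # smooth
                B = bspline_basis(_numeric_column(data, b.smooth.covariate),
                                  b.smooth, b.knots)
                X[:, b.sl] = B @ b.Z
        return X

    def eta(self, data: pd.DataFrame, coef: np.ndarray) -> np.ndarray:
        return self.matrix(data) @ np.asarray(coef, dtype=float)

    def smooth_matrix(self, block: _Block, x: np.ndarray) -> np.ndarray:
        """Centered basis of one smooth term on arbitrary covariate values."""
        return bspline_basis(np.asarray(x, dtype=float), block.smooth, block.knots) @ block.Z

    def coef_slices(self):
        return {b.name: b.sl for b in self.blocks}


def _numeric_column(data: pd.DataFrame, name: str) -> np.ndarray:
    if name not in data.columns:
        raise ValueError(f"column {name!r} missing from the data")
    vals = pd.to_numeric(data[name], errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(vals)):
        raise ValueError(f"column {name!r} contains missing/non-numeric values")
    return vals


def _is_categorical(s: pd.Series) -> bool:
    return isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == object \
        or pd.api.types.is_string_dtype(s)


def build_design(eq: EquationSpec, data: pd.DataFrame,
                 extra_parametric: tuple = ()) -> AdditivePredictorDesign:
    """Assemble the additive-predictor design for one equation.

    Column order is deterministic: intercept, then parametric terms in the
    declared order (categoricals expanded against their first level), then
    centered smooth blocks in the declared order.  ``extra_parametric``
    prepends additional numeric columns right after the intercept (used for
    the endogenous treatment indicator in the outcome equation).
    """
    for col in tuple(extra_parametric) + eq.columns:
        if col not in data.columns:
            raise ValueError(f"column {col!r} missing from the data")
    cols: list[np.ndarray] = []
    names: list[str] = []
    blocks: list[_Block] = []
    n = len(data)

    def add_block(mat, block_names, **kw):
        start = sum(c.shape[1] for c in cols)
        sl = slice(start, start + mat.shape[1])
        cols.append(mat)
        names.extend(block_names)
        blocks.append(_Block(sl=sl, **kw))
        return sl

    add_block(np.ones((n, 1)), ["intercept"], name="intercept", kind="intercept")
    for term in tuple(extra_parametric) + tuple(eq.parametric):
        s = data[term]
        if _is_categorical(s):
            if isinstance(s.dtype, pd.CategoricalDtype):
                levels = tuple(str(c) for c in s.cat.categories)
            else:
                levels = tuple(sorted(map(str, pd.unique(s.dropna()))))
            if len(levels) < 2:
                raise ValueError(f"categorical column {term!r} has a single level")
            vals = s.astype(str).to_numpy()
            mat = np.column_stack([(vals == lev).astype(float) for lev in levels[1:]])
            add_block(mat, [f"{term}{lev}" for lev in levels[1:]],
                      name=term, kind="dummy", levels=levels)
        else:
            add_block(_numeric_column(data, term)[:, None], [term],
                      name=term, kind="linear")
    for sm in eq.smooths:
        x = _numeric_column(data, sm.covariate)
        knots = make_knots(x, sm)
        B = bspline_basis(x, sm, knots)
        P = difference_penalty(sm.num_basis, sm.penalty_order)
        Bc, Pc, Z = center_smooth(B, P)
        add_block(Bc, [f"s({sm.covariate}).{j + 1}" for j in range(Bc.shape[1])],
                  name=f"s({sm.covariate})", kind="smooth",
                  smooth=sm, knots=knots, Z=Z, penalty=Pc)
    X = np.concatenate(cols, axis=1)
    return AdditivePredictorDesign(
        spec=eq, X=X, column_names=tuple(names), blocks=tuple(blocks)
    )
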
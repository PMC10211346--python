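"""Fast random-intercept linear mixed models.

The screening stage fits the same fixed-effect design to thousands of
response vectors (one per frame x sensor cell), so the engine profiles the
likelihood down to a single variance ratio ``lam = sigma_u^2 / sigma_e^2``
and caches everything that depends on the design only.  For a model
``y = X beta + Z u + e`` with one random intercept per group,
``V* = I + lam * J`` is block diagonal and Woodbury gives

    X' V*^-1 X = X'X - sum_i c_i s_i s_i',   c_i = lam / (1 + lam * n_i)

with ``s_i`` the per-group column sums of X.  Each REML evaluation is then
O(G * p^2) regardless of n.  Estimates are checked against statsmodels'
MixedLM in the test suite.

Fixed-effect factors are sum-to-zero coded, so jointly testing a term's
coefficients gives Type-III style Wald F tests.  Pairwise contrasts of
estimated marginal means are adjusted with the studentized range (Tukey
HSD).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._errors import FitError

DDF_METHODS = ("between-within", "residual")


# ---------------------------------------------------------------------------
# design construction (sum-to-zero coding)
# ---------------------------------------------------------------------------

class Design:
    """Fixed-effects design with categorical factors and continuous covariates.

    Parameters
    ----------
    factors:
        Mapping of factor name to ordered level list.
    terms:
        Model terms as tuples of variable names, e.g.
        ``[("choice",), ("feedback",), ("choice", "feedback")]``.  An
        intercept is always included.
    continuous:
        Names of continuous covariates (expected centered by the caller).
    """

    def __init__(
        self,
        factors: dict[str, list[str]],
        terms: list[tuple[str, ...]],
        continuous: tuple[str, ...] = (),
    ) -> None:
        self.factors = {k: list(v) for k, v in factors.items()}
        self.continuous = tuple(continuous)
        self.terms = [t if isinstance(t, tuple) else (t,) for t in terms]
        for t in self.terms:
            for name in t:
                if name not in self.factors and name not in self.continuous:
                    raise ValueError(f"term references unknown variable {name!r}")
        # column bookkeeping
        self.term_cols: dict[tuple[str, ...], list[int]] = {}
        self.n_cols = 1  # intercept
        for t in self.terms:
            width = 1
            for name in t:
                width *= len(self.factors[name]) - 1 if name in self.factors else 1
            self.term_cols[t] = list(range(self.n_cols, self.n_cols + width))
            self.n_cols += width

    def _main_block(self, name: str, values: pd.Series | np.ndarray) -> np.ndarray:
        if name in self.continuous:
            return np.asarray(values, dtype=float)[:, None]
        levels = self.factors[name]
        codes = pd.Categorical(values, categories=levels)
        if (codes.codes < 0).any():
            bad = sorted(set(np.asarray(values)[codes.codes < 0]))
            raise ValueError(f"factor {name!r}: unknown levels {bad}")
        k = len(levels)
        block = np.zeros((len(codes), k - 1))
        for j in range(k - 1):
            block[codes.codes == j, j] = 1.0
        block[codes.codes == k - 1, :] = -1.0
        return block

    def build(self, data: pd.DataFrame) -> np.ndarray:
        """Return the n x p design matrix (intercept first)."""
        n = len(data)
        cols = [np.ones((n, 1))]
        for t in self.terms:
            block = self._main_block(t[0], data[t[0]])
            for name in t[1:]:
                nxt = self._main_block(name, data[name])
                block = np.einsum("ni,nj->nij", block, nxt).reshape(n, -1)
            cols.append(block)
        return np.concatenate(cols, axis=1)

    def grid(self) -> pd.DataFrame:
        """Full factorial grid of factor levels with continuous covariates at 0."""
        names = list(self.factors)
        combos = list(itertools.product(*(self.factors[n] for n in names)))
        out = pd.DataFrame(combos, columns=names)
        for c in self.continuous:
            out[c] = 0.0
        return out

    def emm_matrix(self, by: tuple[str, ...]) -> tuple[list[tuple[str, ...]], np.ndarray]:
        """Rows mapping coefficients to estimated marginal means of ``by``.

        Cell predictions over the full factorial grid are averaged with
        equal weights across the levels of all other factors.
        """
        by = tuple(by)
        g = self.grid()
        rows = self.build(g)
        keys = list(map(tuple, g[list(by)].to_numpy()))
        order: list[tuple[str, ...]] = []
        for combo in itertools.product(*(self.factors[n] for n in by)):
            order.append(combo)
        M = np.zeros((len(order), rows.shape[1]))
        for i, combo in enumerate(order):
            sel = [j for j, k in enumerate(keys) if k == combo]
            M[i] = rows[sel].mean(axis=0)
        return order, M


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    """Fitted random-intercept model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_e: float
    sigma2_u: float
    nobs: int
    n_params: int
    n_groups: int
    loglik_criterion: float
    reml: bool
    var_fixed: float  # sample variance of X @ beta
    converged: bool = True

    def ddf(self, method: str = "between-within") -> float:
        if method == "residual":
            return max(1.0, self.nobs - self.n_params)
        if method == "between-within":
            return max(1.0, self.nobs - self.n_groups - self.n_params + 1)
        raise ValueError(f"unknown ddf method {method!r}")

    def r2(self) -> tuple[float, float]:
        """(marginal, conditional) variance-explained in the Nakagawa sense."""
        tot = self.var_fixed + self.sigma2_u + self.sigma2_e
        return self.var_fixed / tot, (self.var_fixed + self.sigma2_u) / tot


class RandomInterceptLM:
    """Pre-factored engine: build once per design, fit many responses."""

    def __init__(self, X: np.ndarray, groups: np.ndarray | None) -> None:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.n, self.p = X.shape
        if np.linalg.matrix_rank(X) < self.p:
            raise FitError("design matrix is rank deficient")
        if groups is None:
            self.G = 0
            self.order = np.arange(self.n)
        else:
            codes, _ = pd.factorize(np.asarray(groups))
            self.order = np.argsort(codes, kind="stable")
            codes = codes[self.order]
            self.G = int(codes.max()) + 1
            self.starts = np.searchsorted(codes, np.arange(self.G))
            self.n_i = np.diff(np.append(self.starts, self.n)).astype(float)
        self.X = X[self.order]
        self.XtX = self.X.T @ self.X
        if self.G:
            self.Sx = np.add.reduceat(self.X, self.starts, axis=0)  # (G, p)

    # -- internals ----------------------------------------------------------

    def _solve(self, lam: float, Xty: np.ndarray, Sy: np.ndarray, yty: float):
        if self.G and lam > 0:
            c = lam / (1.0 + lam * self.n_i)
            A = self.XtX - (self.Sx * c[:, None]).T @ self.Sx
            b = Xty - self.Sx.T @ (c * Sy)
            yVy = yty - float(c @ (Sy**2))
            logdetV = float(np.log1p(lam * self.n_i).sum())
        else:
            A, b, yVy, logdetV = self.XtX, Xty, yty, 0.0
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            raise FitError("singular generalized cross-product matrix")
        beta = np.linalg.solve(A, b)
        Q = yVy - float(beta @ b)
        return A, beta, Q, logdetV, logdetA

    def fit(self, y: np.ndarray, reml: bool = True) -> LMMFit:
        y = np.asarray(y, dtype=float)[self.order]
        if y.shape[0] != self.n:
            raise ValueError("response length mismatch")
        yty = float(y @ y)
        Xty = self.X.T @ y
        Sy = np.add.reduceat(y, self.starts) if self.G else np.zeros(0)
        dof = self.n - self.p if reml else self.n

        def criterion(loglam: float) -> float:
            lam = np.exp(loglam)
            try:
                _, _, Q, logdetV, logdetA = self._solve(lam, Xty, Sy, yty)
            except FitError:
                return np.inf
            if Q <= 0:
                return np.inf
            val = dof * np.log(Q) + logdetV
            if reml:
                val += logdetA
            return val

        if self.G:
            res = optimize.minimize_scalar(
                criterion, bounds=(-12.0, 12.0), method="bounded",
                options={"xatol": 1e-8},
            )
            lam = float(np.exp(res.x))
            # accept the boundary (no group variance) if it does at least as well
            if criterion(-30.0) <= res.fun + 1e-10:
                lam = 0.0
            crit_val = min(res.fun, criterion(np.log(lam) if lam > 0 else -30.0))
        else:
            lam = 0.0
            crit_val = criterion(-30.0)

        A, beta, Q, _, _ = self._solve(lam, Xty, Sy, yty)
        sigma2_e = Q / (self.n - self.p if reml else self.n)
        if sigma2_e <= 0:
            raise FitError("non-positive residual variance")
        cov_beta = sigma2_e * np.linalg.inv(A)
        fitted = self.X @ beta
        return LMMFit(
            beta=beta,
            cov_beta=cov_beta,
            sigma2_e=float(sigma2_e),
            sigma2_u=float(lam * sigma2_e),
            nobs=self.n,
            n_params=self.p,
            n_groups=self.G,
            loglik_criterion=float(-0.5 * crit_val),
            reml=reml,
            var_fixed=float(np.var(fitted)),
        )


def fit_lmm(
    data: pd.DataFrame,
    y: str | np.ndarray,
    design: Design,
    groups: str | None = "subject_id",
    reml: bool = True,
) -> LMMFit:
    """Convenience one-shot fit of ``y`` on a design built from ``data``."""
    X = design.build(data)
    g = data[groups].to_numpy() if isinstance(groups, str) else groups
    engine = RandomInterceptLM(X, g)
    yv = data[y].to_numpy() if isinstance(y, str) else np.asarray(y)
    return engine.fit(yv, reml=reml)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def wald_f(fit: LMMFit, cols: list[int], ddf_method: str = "between-within"):
    """Joint Wald F test that the listed coefficients are zero."""
    b = fit.beta[cols]
    C = fit.cov_beta[np.ix_(cols, cols)]
    q = len(cols)
    F = float(b @ np.linalg.solve(C, b)) / q
    df2 = fit.ddf(ddf_method)
    p = float(stats.f.sf(F, q, df2))
    return F, q, df2, p


def type3_table(fit: LMMFit, design: Design, ddf_method: str = "between-within") -> pd.DataFrame:
    """Type-III style Wald F tests for every term in the design."""
    rows = []
    for term, cols in design.term_cols.items():
        F, df1, df2, p = wald_f(fit, cols, ddf_method)
        rows.append({"term": ":".join(term), "F": F, "df1": df1, "df2": df2, "p": p})
    return pd.DataFrame(rows)


def tukey_table(
    fit: LMMFit,
    design: Design,
    by: tuple[str, ...] | str,
    ddf_method: str = "between-within",
) -> pd.DataFrame:
    """All pairwise contrasts of the estimated marginal means of ``by``.

    p-values are adjusted over the full family of pairs with the
    studentized-range distribution; unadjusted t-based p-values are kept
    alongside.
    """
    if isinstance(by, str):
        by = (by,)
    labels, M = design.emm_matrix(by)
    est = M @ fit.beta
    cov = M @ fit.cov_beta @ M.T
    k = len(labels)
    df = fit.ddf(ddf_method)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(est[i] - est[j])
            se = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
            t = diff / se
            p_un = float(2 * stats.t.sf(abs(t), df))
            q = abs(t) * np.sqrt(2.0)
            p_adj = float(np.clip(stats.studentized_range.sf(q, k, df), 0.0, 1.0))
            rows.append(
                {
                    "level_a": ":".join(labels[i]),
                    "level_b": ":".join(labels[j]),
                    "estimate": diff,
                    "se": se,
                    "t": t,
                    "df": df,
                    "p_unadjusted": p_un,
                    "p_tukey": max(p_adj, p_un),
                }
            )
    return pd.DataFrame(rows)


def emmeans(fit: LMMFit, design: Design, by: tuple[str, ...] | str) -> pd.DataFrame:
    """Estimated marginal means of ``by`` with standard errors."""
    if isinstance(by, str):
        by = (by,)
    labels, M = design.emm_matrix(by)
    est = M @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", M, fit.cov_beta, M))
    return pd.DataFrame(
        {"level": [":".join(l) for l in labels], "emmean": est, "se": se}
    )
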
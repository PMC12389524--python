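"""Linear QSAR path: descriptor pre-filtering, OLS, forward selection.

The pre-filter applies, in order, the four classic rules used before
heuristic linear model building: drop constant columns, drop descriptors
whose one-parameter regression F-statistic is below 1.0, break highly
correlated pairs (|r| > 0.8) by dropping the member with the lower
single-descriptor R^2, and drop descriptors whose one-parameter t-statistic
falls below a user-specified threshold.  Forward selection then grows the
model one descriptor at a time, reporting R^2 and leave-one-out R^2_cv per
size so the usual descriptors-vs-fit elbow analysis can be applied.

``apply_hm_model`` evaluates the published three-descriptor linear model
    lg(IC50) = -7.3731 - 40.041 RS + 0.48875 NR + 0.80855 ME
where RS is the relative number of sulfur atoms, NR the number of rings, and
ME the maximum exchange energy for a C-N bond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from mixqsar.datasets import DescriptorTable
from mixqsar.errors import ConfigurationError, DataError

HM_INTERCEPT = -7.3731
HM_COEFFICIENTS = {"RS": -40.041, "NR": 0.48875, "ME": 0.80855}


@dataclass
class LinearModel:
    """OLS fit with named coefficients and the usual fit statistics."""

    intercept: float
    coefficients: dict[str, float]
    r2: float
    rmse: float
    t_values: dict[str, float]
    f_statistic: float

    def predict(self, descriptors) -> np.ndarray:
        X = np.column_stack(
            [np.asarray(descriptors[name], dtype=float) for name in self.coefficients]
        )
        beta = np.array(list(self.coefficients.values()))
        return self.intercept + X @ beta


@dataclass
class RemovalRecord:
    descriptor: str
    rule: str  # constant | low_f | correlated | low_t
    statistic: float
    detail: str = ""


def _single_regression_stats(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(R^2, F, t of slope) for the one-descriptor regression y ~ 1 + x."""
    n = len(y)
    r = np.corrcoef(x, y)[0, 1]
    r2 = r * r
    if np.isclose(r2, 1.0):
        return 1.0, np.inf, np.inf
    f = r2 * (n - 2) / (1.0 - r2)
    return float(r2), float(f), float(np.sign(r) * np.sqrt(f))


def prefilter_descriptors(
    table: DescriptorTable,
    corr_threshold: float = 0.8,
    f_min: float = 1.0,
    t_min: float = 1.96,
) -> tuple[DescriptorTable, list[RemovalRecord]]:
    """Apply the four pre-filter rules in order; returns survivors + log."""
    y = table.response
    removed: list[RemovalRecord] = []
    survivors = list(table.descriptor_names)

    def drop(name: str, rule: str, stat: float, detail: str = "") -> None:
        survivors.remove(name)
        removed.append(RemovalRecord(name, rule, stat, detail))

    # 1. constant columns
    for name in list(survivors):
        col = table.descriptors[name].to_numpy(dtype=float)
        if np.ptp(col) == 0.0:
            drop(name, "constant", float(col[0]))

    # 2. one-parameter F-test below f_min
    stats = {
        name: _single_regression_stats(table.descriptors[name].to_numpy(dtype=float), y)
        for name in survivors
    }
    for name in list(survivors):
        if stats[name][1] < f_min:
            drop(name, "low_f", stats[name][1])

    # 3. correlated pairs: keep the member with the higher one-descriptor R^2
    changed = True
    while changed:
        changed = False
        for i, a in enumerate(list(survivors)):
            if a not in survivors:
                continue
            for b in list(survivors)[i + 1 :]:
                if a not in survivors or b not in survivors:
                    continue
                xa = table.descriptors[a].to_numpy(dtype=float)
                xb = table.descriptors[b].to_numpy(dtype=float)
                r = abs(np.corrcoef(xa, xb)[0, 1])
                if r > corr_threshold:
                    loser = b if stats[a][0] >= stats[b][0] else a
                    keeper = a if loser == b else b
                    drop(loser, "correlated", r, f"kept {keeper}")
                    changed = True

    # 4. one-parameter |t| below t_min
    for name in list(survivors):
        if abs(stats[name][2]) < t_min:
            drop(name, "low_t", stats[name][2])

    if not survivors:
        raise DataError(
            "all descriptors removed by pre-filtering; log: "
            + "; ".join(f"{r.descriptor}:{r.rule}" for r in removed)
        )
    return table.with_descriptors(survivors), removed


def fit_ols(table: DescriptorTable, descriptor_names: list[str]) -> LinearModel:
    """Least-squares fit with intercept on the named descriptors."""
    missing = [n for n in descriptor_names if n not in table.descriptor_names]
    if missing:
        raise ConfigurationError(f"unknown descriptors: {missing}")
    X = table.descriptors[list(descriptor_names)].to_numpy(dtype=float)
    y = table.response
    n, p = X.shape
    if n <= p:
        raise DataError(f"need more rows ({n}) than descriptors ({p}) for OLS")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        # name the dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(design, pivoting=True)
        rank = np.linalg.matrix_rank(design)
        dependent = [i - 1 for i in piv[rank:] if i > 0]
        names = [descriptor_names[i] for i in dependent]
        raise DataError(f"rank-deficient design; collinear descriptors: {names}")
    fit = sm.OLS(y, design).fit()
    residuals = y - fit.fittedvalues
    return LinearModel(
        intercept=float(fit.params[0]),
        coefficients=dict(zip(descriptor_names, map(float, fit.params[1:]))),
        r2=float(fit.rsquared),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        t_values=dict(zip(descriptor_names, map(float, fit.tvalues[1:]))),
        f_statistic=float(fit.fvalue),
    )


def _loo_r2(X: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out R^2_cv via the closed-form PRESS of linear regression."""
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    h = np.einsum(
        "ij,jk,ik->i", design, np.linalg.pinv(design.T @ design), design
    )
    press = np.sum((resid / (1.0 - h)) ** 2)
    sst = np.sum((y - y.mean()) ** 2)
    return float(1.0 - press / sst)


@dataclass
class ForwardSelectionStep:
    k: int
    names: list[str]
    r2: float
    r2_cv: float


def forward_select(table: DescriptorTable, max_k: int) -> list[ForwardSelectionStep]:
    """Greedy forward selection maximizing R^2 at each model size.

    Returns one record per k in 1..max_k with the chosen descriptors, the
    training R^2, and the leave-one-out cross-validated R^2.
    """
    pool = list(table.descriptor_names)
    if not 1 <= max_k <= len(pool):
        raise ConfigurationError(f"max_k must lie in [1, {len(pool)}], got {max_k}")
    y = table.response
    chosen: list[str] = []
    steps: list[ForwardSelectionStep] = []
    for k in range(1, max_k + 1):
        best_name, best_r2 = None, -np.inf
        for name in pool:
            if name in chosen:
                continue
            X = table.descriptors[chosen + [name]].to_numpy(dtype=float)
            design = np.column_stack([np.ones(len(y)), X])
            beta, *_ = np.linalg.lstsq(design, y, rcond=None)
            sse = np.sum((y - design @ beta) ** 2)
            r2 = 1.0 - sse / np.sum((y - y.mean()) ** 2)
            if r2 > best_r2 + 1e-15:
                best_name, best_r2 = name, r2
        chosen.append(best_name)
        X = table.descriptors[chosen].to_numpy(dtype=float)
        steps.append(ForwardSelectionStep(k, list(chosen), float(best_r2), _loo_r2(X, y)))
    return steps


def apply_hm_model(rs: float, nr: float, me: float) -> float:
    """Evaluate the published heuristic-method linear model (lg IC50, nM)."""
    return (
        HM_INTERCEPT
        + HM_COEFFICIENTS["RS"] * rs
        + HM_COEFFICIENTS["NR"] * nr
        + HM_COEFFICIENTS["ME"] * me
    )
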
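"""Permutation-based Spearman correlation of function against phenotype.

For a small cohort of variants (the study design has n = 8), null
distributions are computed by *exact enumeration* of all n! permutations of
one vector; above n = 8 a Monte-Carlo permutation test with the standard
(+1)/(n_perm+1) correction is used. Two-sided throughout.

Measures whose scores are not age-standardised (CVI total, DBC self-injury)
are handled with a rank-based partial correlation controlling for age:
ranks of x and y are residualized on age ranks and the residual correlation
is tested by permuting the y residuals (Freedman–Lane style).

The family of all computed (measure x metric) cells is corrected with the
Benjamini–Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations as _iter_permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic import FUNCTIONAL_METRICS, PHENOTYPE_MEASURES

__all__ = [
    "EXACT_ENUMERATION_MAX_N",
    "spearman_r",
    "permutation_p",
    "partial_spearman_age",
    "bh_fdr",
    "BHResult",
    "CorrelationConfig",
    "run_correlation_family",
]

#: largest n for which the permutation null is enumerated exactly (8! = 40320)
EXACT_ENUMERATION_MAX_N = 8

#: tolerance when counting permuted statistics as at least as extreme
_TIE_TOL = 1e-12


def _check_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need n >= {min_n} complete pairs, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite (drop missing pairs upstream)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    return x, y


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def spearman_r(x, y) -> float:
    """Spearman rho: Pearson correlation of average ranks (ties averaged)."""
    x, y = _check_pair(x, y)
    return _pearson(rankdata(x), rankdata(y))


@lru_cache(maxsize=4)
def _all_permutations(n: int) -> np.ndarray:
    """All n! index permutations as an (n!, n) array (cached; n <= 8)."""
    return np.array(list(_iter_permutations(range(n))), dtype=np.int8)


def _perm_null_p(xc: np.ndarray, y: np.ndarray, r_obs: float,
                 n_perm: int, rng: np.random.Generator | None) -> float:
    """Two-sided permutation p-value for the correlation of xc (centered)
    against permutations of y; exact for n <= EXACT_ENUMERATION_MAX_N."""
    n = y.size
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if n <= EXACT_ENUMERATION_MAX_N:
        perms = _all_permutations(n)
        r_all = (yc[perms] @ xc) / denom
        n_extreme = int(np.sum(np.abs(r_all) >= abs(r_obs) - _TIE_TOL))
        return n_extreme / factorial(n)
    if n_perm < 100:
        raise ValueError(f"n_perm={n_perm} < 100 in Monte-Carlo mode")
    if rng is None:
        rng = np.random.default_rng()
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    r_all = (yc[order] @ xc) / denom
    n_extreme = int(np.sum(np.abs(r_all) >= abs(r_obs) - _TIE_TOL))
    return (n_extreme + 1) / (n_perm + 1)


def permutation_p(x, y, n_perm: int = 10_000, seed: int | None = None) -> float:
    """Two-sided permutation p-value for Spearman's rho under exchangeability.

    Exact enumeration of all n! permutations for n <= 8 (the identity
    permutation makes the observed statistic count itself, so p >= 1/n!);
    otherwise Monte-Carlo with p = (extreme + 1)/(n_perm + 1).
    """
    x, y = _check_pair(x, y)
    rx, ry = rankdata(x), rankdata(y)
    r_obs = _pearson(rx, ry)
    return _perm_null_p(rx - rx.mean(), ry, r_obs, n_perm,
                        np.random.default_rng(seed))


def partial_spearman_age(
    x, y, age, n_perm: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Rank partial correlation of x and y controlling for age, with
    a Freedman–Lane permutation p-value.

    Ranks of x and y are residualized on age ranks by least squares; the
    partial rho is the Pearson correlation of the residuals, and its null is
    built by permuting the y residuals (exact/Monte-Carlo rules as in
    :func:`permutation_p`).
    """
    x, y = _check_pair(x, y, min_n=5)
    age = np.asarray(age, dtype=float)
    if age.shape != x.shape:
        raise ValueError("age must match x and y in length")
    if np.ptp(age) == 0:
        raise ValueError("age is constant; cannot control for it")
    rx, ry, ra = rankdata(x), rankdata(y), rankdata(age)
    design = np.column_stack([np.ones_like(ra), ra])
    rx_res = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
    ry_res = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    # a variable that is an exact rank-function of age has nothing left to
    # correlate after the control: partial association is zero by convention
    scale = np.sqrt(x.size)
    if (np.linalg.norm(rx_res) < 1e-9 * scale
            or np.linalg.norm(ry_res) < 1e-9 * scale):
        return 0.0, 1.0
    rho = _pearson(rx_res, ry_res)
    p = _perm_null_p(rx_res - rx_res.mean(), ry_res, rho, n_perm,
                     np.random.default_rng(seed))
    return rho, p


@dataclass(frozen=True)
class BHResult:
    flags: np.ndarray  # boolean, in input order
    cutoff: float  # largest significant p (NaN when nothing is flagged)
    q: float


def bh_fdr(pvals, q: float = 0.05) -> BHResult:
    """Benjamini–Hochberg step-up FDR over a family of p-values.

    Sorts p ascending, finds the largest i with p_(i) <= (i/m)·q, and flags
    tests 1..i. Returns flags in input order plus the data-dependent cutoff.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= (np.arange(1, m + 1) / m) * q
    flags = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below)))
        flags[order[: k + 1]] = True
        cutoff = float(sorted_p[k])
    else:
        cutoff = float("nan")
    return BHResult(flags=flags, cutoff=cutoff, q=q)


@dataclass(frozen=True)
class CorrelationConfig:
    q: float = 0.05
    n_perm: int = 10_000
    seed: int = 0
    age_controlled: tuple[str, ...] = ("CVI_total", "DBC_self_injury")
    metrics: tuple[str, ...] = FUNCTIONAL_METRICS
    measures: tuple[str, ...] = PHENOTYPE_MEASURES


def run_correlation_family(
    metrics_table: pd.DataFrame,
    phenotype_table: pd.DataFrame,
    config: CorrelationConfig = CorrelationConfig(),
) -> pd.DataFrame:
    """Full (phenotype measure x functional metric) correlation matrix.

    ``metrics_table`` holds one row per variant with functional-metric
    columns; ``phenotype_table`` one row per variant with phenotype-measure
    columns and ``age``. Pairs with missing values are dropped per cell; a
    cell with fewer than 4 complete pairs (5 when age-controlled) is reported
    as not computed rather than raising. BH flags are assigned across all
    computed cells.
    """
    common = metrics_table.index.intersection(phenotype_table.index)
    rows = []
    for i, measure in enumerate(config.measures):
        for j, metric in enumerate(config.metrics):
            cell_seed = np.random.SeedSequence(
                [config.seed, i, j]
            ).generate_state(1)[0] % (2**31)
            age_ctrl = measure in config.age_controlled
            row = {
                "measure": measure, "metric": metric, "age_controlled": age_ctrl,
                "n": 0, "r": np.nan, "p": np.nan, "computed": False,
            }
            if measure in phenotype_table.columns and metric in metrics_table.columns:
                x = metrics_table.loc[common, metric].astype(float)
                y = phenotype_table.loc[common, measure].astype(float)
                cols = {"x": x, "y": y}
                if age_ctrl:
                    cols["age"] = phenotype_table.loc[common, "age"].astype(float)
                cell = pd.DataFrame(cols).dropna()
                min_n = 5 if age_ctrl else 4
                if len(cell) >= min_n:
                    try:
                        if age_ctrl:
                            r, p = partial_spearman_age(
                                cell["x"], cell["y"], cell["age"],
                                n_perm=config.n_perm, seed=int(cell_seed),
                            )
                        else:
                            r = spearman_r(cell["x"], cell["y"])
                            p = permutation_p(
                                cell["x"], cell["y"],
                                n_perm=config.n_perm, seed=int(cell_seed),
                            )
                        row.update(n=len(cell), r=r, p=p, computed=True)
                    except ValueError:
                        row.update(n=len(cell))
                else:
                    row.update(n=len(cell))
            rows.append(row)
    out = pd.DataFrame(rows)
    out["bh_significant"] = False
    computed = out["computed"].to_numpy()
    if computed.any():
        bh = bh_fdr(out.loc[computed, "p"].to_numpy(), q=config.q)
        out.loc[computed, "bh_significant"] = bh.flags
        out.attrs["bh_cutoff"] = bh.cutoff
    return out
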
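"""Environmental-driver statistics for island genetic diversity.

Implements the screening and inference chain used to relate per-island
diversity to island characteristics:

* permutation-assisted VIF screening of collinear predictors
  (iterative removal at VIF >= 10);
* redundancy analysis (RDA) of the haplotype-by-island table on the
  retained predictors, with Chevan & Sutherland hierarchical partitioning
  of the explained variance into per-predictor independent contributions
  and a row-permutation test of the overall model and each contribution;
* Mantel tests between environmental and diversity distance matrices;
* ordinary least-squares lines of a diversity metric on a (possibly
  log10-transformed) predictor.

Predictors AREA and POP are log10-transformed by default; the RDA
response is Hellinger-transformed occurrence counts by default.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEFAULT_TRANSFORMS",
    "transform_env",
    "vif_screen",
    "VifScreenResult",
    "hellinger",
    "rda_hierpart",
    "HierPartResult",
    "mantel_test",
    "MantelResult",
    "mantel_suite",
    "euclidean_distance_matrix",
    "fit_glm",
    "GlmFit",
]

ENV_VARIABLES = ["AREA", "COA", "ISD", "ISW", "POP", "FRE"]
DEFAULT_TRANSFORMS: dict[str, str] = {"AREA": "log10", "POP": "log10"}


def transform_env(
    env: pd.DataFrame, transforms: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Apply per-predictor transforms (``identity`` or ``log10``)."""
    transforms = DEFAULT_TRANSFORMS if transforms is None else transforms
    out = env.copy().astype(float)
    for col, t in transforms.items():
        if col not in out.columns:
            continue
        if t == "log10":
            if (out[col] <= 0).any():
                raise ValueError(f"log10 transform of non-positive {col}")
            out[col] = np.log10(out[col])
        elif t != "identity":
            raise ValueError(f"unknown transform {t!r} for {col}")
    return out


def _vif_values(x: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) of column j regressed on the others."""
    n, k = x.shape
    out = np.empty(k)
    for j in range(k):
        y = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        tss = np.sum((y - y.mean()) ** 2)
        if tss == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / tss
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


@dataclass
class VifScreenResult:
    retained: list[str]
    excluded: list[str]
    vif: dict[str, float]
    permutation_q95: dict[str, float]
    threshold: float

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.vif:
            rows.append(
                {
                    "predictor": name,
                    "vif": self.vif[name],
                    "null_q95": self.permutation_q95.get(name, np.nan),
                    "excluded": name in self.excluded,
                }
            )
        return pd.DataFrame(rows)


def vif_screen(
    env: pd.DataFrame,
    threshold: float = 10.0,
    n_perm: int = 999,
    seed: int | None = 0,
) -> VifScreenResult:
    """Iteratively exclude predictors with VIF >= ``threshold``.

    At each step the predictor with the largest offending VIF is removed
    and VIFs are recomputed.  A permutation reference distribution (each
    column permuted independently, ``n_perm`` times) provides the 95%
    quantile of VIF expected under no collinearity, reported alongside.
    Perfectly collinear predictors yield infinite VIF and are excluded.
    """
    if env.shape[1] < 2:
        raise ValueError("VIF screening needs >= 2 predictors")
    if env.shape[0] < env.shape[1] + 2:
        raise ValueError("too few rows for VIF screening")
    rng = np.random.default_rng(seed)
    cols = list(env.columns)
    x_full = env.to_numpy(float)

    # null reference: independently permuted columns kill any real
    # correlation structure; the observed VIF is judged against it
    null = np.empty((n_perm, len(cols)))
    for b in range(n_perm):
        xp = np.column_stack(
            [x_full[rng.permutation(len(x_full)), j] for j in range(len(cols))]
        )
        null[b] = _vif_values(xp)
    q95 = dict(zip(cols, np.quantile(null, 0.95, axis=0)))

    retained = list(cols)
    excluded: list[str] = []
    while len(retained) >= 2:
        vifs = _vif_values(env[retained].to_numpy(float))
        worst = int(np.argmax(vifs))
        if vifs[worst] >= threshold:
            excluded.append(retained.pop(worst))
        else:
            break
    final = dict(
        zip(retained, _vif_values(env[retained].to_numpy(float)))
    ) if len(retained) >= 2 else {r: 1.0 for r in retained}
    # report last-known VIF for excluded predictors (from the full set)
    full_vifs = dict(zip(cols, _vif_values(x_full)))
    vif_report = {c: (final[c] if c in final else full_vifs[c]) for c in cols}
    return VifScreenResult(
        retained=retained,
        excluded=excluded,
        vif=vif_report,
        permutation_q95=q95,
        threshold=threshold,
    )


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: sqrt of row-relative abundances."""
    x = counts.to_numpy(float)
    rowsum = x.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise ValueError("Hellinger transform undefined for empty rows")
    return pd.DataFrame(
        np.sqrt(x / rowsum), index=counts.index, columns=counts.columns
    )


def _subset_r2_machinery(x: np.ndarray) -> dict[frozenset, np.ndarray]:
    """Hat matrices for every predictor subset (intercept-only for {})."""
    n, k = x.shape
    hats = {}
    ones = np.ones((n, 1))
    for r in range(k + 1):
        for subset in itertools.combinations(range(k), r):
            cols = np.column_stack([ones, x[:, list(subset)]])
            q, _ = np.linalg.qr(cols)
            hats[frozenset(subset)] = q @ q.T
    return hats


def _r2_from_hat(hat: np.ndarray, yc: np.ndarray, tss: float) -> float:
    fitted = hat @ yc
    return float(np.sum(fitted**2) / tss)


def _independent_contributions(
    r2: Mapping[frozenset, float], k: int
) -> np.ndarray:
    """Chevan-Sutherland averaging of incremental R^2 over all orderings."""
    contrib = np.zeros(k)
    for j in range(k):
        others = [i for i in range(k) if i != j]
        for r in range(k):
            w = (
                math.factorial(r)
                * math.factorial(k - r - 1)
                / math.factorial(k)
            )
            for subset in itertools.combinations(others, r):
                s = frozenset(subset)
                contrib[j] += w * (r2[s | {j}] - r2[s])
    return contrib


@dataclass
class HierPartResult:
    """RDA hierarchical-partitioning output.

    ``contributions`` are independent contributions on the unadjusted-R^2
    scale (they sum to ``r2_full``); ``contributions_adj`` rescales them
    proportionally so their sum equals the adjusted R^2.
    """

    predictors: list[str]
    contributions: np.ndarray
    p_values: np.ndarray
    r2_full: float
    r2_adj: float
    f_statistic: float
    df: tuple[int, int]
    p_model: float
    n_perm: int

    def as_frame(self) -> pd.DataFrame:
        total = self.contributions.sum()
        return pd.DataFrame(
            {
                "independent_contribution": self.contributions,
                "fraction_of_explained": self.contributions / total
                if total > 0
                else np.nan,
                "p_value": self.p_values,
            },
            index=self.predictors,
        )

    @property
    def contributions_adj(self) -> np.ndarray:
        total = self.contributions.sum()
        if total == 0:
            return self.contributions
        return self.contributions * (self.r2_adj / total)


def rda_hierpart(
    response: pd.DataFrame,
    env: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = 0,
    transform: Literal["hellinger", "raw", "pa"] = "hellinger",
) -> HierPartResult:
    """RDA of a community-style response with hierarchical partitioning.

    ``response`` is islands x haplotypes (counts unless already
    transformed); ``env`` is islands x retained predictors.  The full
    model's explained variance is the redundancy statistic: the fraction
    of the centred response's total sum of squares captured by its
    least-squares projection on the predictors.  Each predictor's
    independent contribution averages its incremental R^2 over all
    orderings (equivalently all 2^k subsets, Chevan & Sutherland).
    Significance of the model (pseudo-F) and of each contribution comes
    from ``n_perm`` permutations of the response rows.
    """
    if response.shape[0] != env.shape[0]:
        raise ValueError("response and env must have the same rows")
    k = env.shape[1]
    if k > 12:
        raise ValueError(
            "hierarchical partitioning over >12 predictors is intractable "
            "(2^k subsets); reduce the predictor set first"
        )
    if transform == "hellinger":
        y = hellinger(response).to_numpy(float)
    elif transform == "pa":
        y = (response.to_numpy(float) > 0).astype(float)
    elif transform == "raw":
        y = response.to_numpy(float)
    else:
        raise ValueError(f"unknown response transform {transform!r}")

    n = y.shape[0]
    x = env.to_numpy(float)
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    yc = y - y.mean(axis=0)
    tss = float(np.sum(yc**2))
    if tss == 0:
        raise ValueError("response has no variance")

    hats = _subset_r2_machinery(x)
    r2 = {s: _r2_from_hat(h, yc, tss) for s, h in hats.items()}
    full = frozenset(range(k))
    r2_full = r2[full]
    contrib = _independent_contributions(r2, k)

    df1, df2 = k, n - 1 - k
    if df2 <= 0:
        raise ValueError("not enough rows for the pseudo-F test")
    f_obs = (r2_full / df1) / ((1 - r2_full) / df2)
    r2_adj = 1.0 - (1.0 - r2_full) * (n - 1) / df2

    rng = np.random.default_rng(seed)
    exceed_f = 0
    exceed_c = np.zeros(k)
    hat_stack = np.stack([hats[s] for s in hats])
    keys = list(hats)
    for _ in range(n_perm):
        yp = yc[rng.permutation(n)]
        yp = yp - yp.mean(axis=0)
        fitted = np.einsum("sij,jm->sim", hat_stack, yp)
        r2p_vals = np.sum(fitted**2, axis=(1, 2)) / tss
        r2p = dict(zip(keys, r2p_vals))
        r2p_full = r2p[full]
        fp = (r2p_full / df1) / ((1 - r2p_full) / df2)
        if fp >= f_obs:
            exceed_f += 1
        cp = _independent_contributions(r2p, k)
        exceed_c += cp >= contrib
    p_model = (1 + exceed_f) / (n_perm + 1)
    p_contrib = (1 + exceed_c) / (n_perm + 1)

    return HierPartResult(
        predictors=list(env.columns),
        contributions=contrib,
        p_values=p_contrib,
        r2_full=r2_full,
        r2_adj=r2_adj,
        f_statistic=float(f_obs),
        df=(df1, df2),
        p_model=float(p_model),
        n_perm=n_perm,
    )


def euclidean_distance_matrix(values: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Euclidean distances between rows of standardized variables."""
    df = values.to_frame() if isinstance(values, pd.Series) else values
    x = df.to_numpy(float)
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt(np.sum(diff**2, axis=2))
    return pd.DataFrame(d, index=df.index, columns=df.index)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    alternative: str = "greater"


def _lower_triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(len(d), k=-1)
    return d[i, j]


def mantel_test(
    d1: pd.DataFrame | np.ndarray,
    d2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = 0,
    alternative: Literal["greater", "less", "two-sided"] = "greater",
) -> MantelResult:
    """Permutation Mantel test between two distance matrices.

    ``r`` is the Pearson correlation of the lower-triangle vectors; the
    permutation null applies the same random relabelling to the rows and
    columns of ``d2`` and the p-value is ``(1 + #extreme) / (n_perm + 1)``.
    """
    a = np.asarray(d1, dtype=float)
    b = np.asarray(d2, dtype=float)
    for m, name in ((a, "d1"), (b, "d2")):
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"{name} is not a square matrix")
        if not np.allclose(m, m.T):
            raise ValueError(f"{name} is not symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError(f"{name} has a nonzero diagonal")
    if a.shape != b.shape:
        raise ValueError("distance matrices differ in size")
    va, vb = _lower_triangle(a), _lower_triangle(b)
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("constant distance vector: Mantel r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])

    rng = np.random.default_rng(seed)
    n = len(a)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        vp = _lower_triangle(b[np.ix_(idx, idx)])
        rp = np.corrcoef(va, vp)[0, 1]
        if alternative == "greater":
            exceed += rp >= r_obs
        elif alternative == "less":
            exceed += rp <= r_obs
        else:
            exceed += abs(rp) >= abs(r_obs)
    return MantelResult(
        r=r_obs,
        p=float((1 + exceed) / (n_perm + 1)),
        n_perm=n_perm,
        alternative=alternative,
    )


def mantel_suite(
    env: pd.DataFrame,
    diversity: pd.DataFrame,
    metrics: Sequence[str] = ("H", "Hd", "Pi", "PD"),
    n_perm: int = 999,
    seed: int | None = 0,
    transforms: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Mantel r and p for every (environment variable, diversity metric) pair.

    Distances are Euclidean on standardized (transformed) variables.
    Islands with a missing value of the metric (e.g. undefined Hd) are
    dropped pairwise for that metric.
    """
    envt = transform_env(env, transforms)
    rows = []
    seed_seq = np.random.SeedSequence(seed)
    child_seeds = seed_seq.generate_state(len(envt.columns) * len(metrics))
    si = 0
    for metric in metrics:
        if metric not in diversity.columns:
            continue
        keep = diversity[metric].notna()
        if keep.sum() < 4:
            continue
        idx = diversity.index[keep]
        missing_env = [i for i in idx if i not in envt.index]
        if missing_env:
            raise ValueError(f"islands missing from env table: {missing_env[:5]}")
        d_metric = euclidean_distance_matrix(diversity.loc[idx, metric])
        for var in envt.columns:
            d_env = euclidean_distance_matrix(envt.loc[idx, var])
            res = mantel_test(
                d_metric, d_env, n_perm=n_perm, seed=int(child_seeds[si])
            )
            si += 1
            rows.append(
                {
                    "metric": metric,
                    "variable": var,
                    "r": res.r,
                    "p": res.p,
                    "n": int(keep.sum()),
                    "n_perm": n_perm,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GlmFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    transform: str = "identity"


def fit_glm(
    y: pd.Series | np.ndarray,
    x: pd.Series | np.ndarray,
    transform: Literal["identity", "log10"] = "identity",
) -> GlmFit:
    """OLS of a diversity metric on one (optionally log10) predictor.

    Rows with missing values (e.g. undefined Hd) are dropped with a
    warning; the p-value is the two-sided t-test on the slope.
    """
    import warnings

    ys = pd.Series(np.asarray(y, dtype=float))
    xs = pd.Series(np.asarray(x, dtype=float))
    keep = ys.notna() & xs.notna()
    if keep.sum() < len(ys):
        warnings.warn(f"dropping {int((~keep).sum())} rows with missing values")
    ys, xs = ys[keep], xs[keep]
    if len(ys) < 3:
        raise ValueError("need >= 3 complete pairs for a line fit")
    if transform == "log10":
        if (xs <= 0).any():
            raise ValueError("log10 transform of non-positive predictor")
        xs = np.log10(xs)
    elif transform != "identity":
        raise ValueError(f"unknown transform {transform!r}")
    if np.std(xs) == 0:
        raise ValueError("predictor has zero variance")
    model = sm.OLS(ys.to_numpy(), sm.add_constant(xs.to_numpy())).fit()
    return GlmFit(
        slope=float(model.params[1]),
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        p_value=float(model.pvalues[1]),
        n=int(len(ys)),
        transform=transform,
    )
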
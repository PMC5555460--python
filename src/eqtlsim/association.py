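"""Association machinery: univariate scans, sequential conditional discovery,
joint multisite fits, closed-form omitted-variable bias, and power tools.

The discovery pipeline mirrors standard cis-eQTL practice: a per-variant
simple linear regression scan; then "sequential conditional" (stepwise)
detection in which the residual of each discovered SNP is carried forward as
the dependent variable of the next scan; and finally a single multivariable
("multisite") regression of the trait on all discovered peaks.

Closed forms implemented here:

* omitted-variable bias of the univariate estimate of one of two linked
  causal variants,  E[b1_hat] - b1 = r * b2 * sqrt(p2 q2 / (p1 q1)),
  where r is the signed dosage correlation (the expectation of the simple
  regression slope when the correlated second site is unmodeled);
* power of the 1-df univariate test via the noncentral chi-square with
  noncentrality n * ve / (1 + ve) (ve relative to unit environmental noise).

The required-sample-size search for accurate joint two-SNP estimation is a
Monte-Carlo grid search built on the exact two-locus generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    GenotypeMatrix,
    _sample_pair_batch,
    max_abs_r,
)
from .phenotypes import beta_from_ve

__all__ = [
    "ScanResult",
    "StepwisePeaks",
    "JointFit",
    "univariate_scan",
    "stepwise_conditional",
    "joint_fit",
    "expected_univariate_bias",
    "univariate_power",
    "required_sample_size",
    "SampleSizeResult",
]

ALPHA_DEFAULT = 1e-5
_P_MIN = 5e-324  # smallest subnormal double; p-values are clipped here
_COLLINEAR_R2 = 1.0 - 1e-12


@dataclass
class ScanResult:
    """Per-variant simple-regression estimates for one scan."""

    beta_hat: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    excluded: np.ndarray  # constant variants flagged True (NaN estimates)

    @property
    def n_variants(self) -> int:
        return len(self.beta_hat)

    def argmin_p(self) -> int:
        """Index of the smallest p-value; ties broken by lowest index."""
        p = np.where(self.excluded, np.inf, self.p_value)
        return int(np.argmin(p))

    def to_frame(self, variant_ids=None, positions=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"beta": self.beta_hat, "se": self.se, "p": self.p_value,
             "excluded": self.excluded}
        )
        if variant_ids is not None:
            df.insert(0, "variant_id", variant_ids)
        if positions is not None:
            df.insert(1, "position", positions)
        return df


@dataclass
class StepwisePeaks:
    """Ordered sequential-conditional discoveries."""

    variant_idx: np.ndarray
    beta_hat: np.ndarray  # conditional estimate at the discovery step
    p_value: np.ndarray
    step: np.ndarray  # 1-based discovery step
    stop_reason: str
    step_ve: np.ndarray = field(default=None)  # variance of y explained per step

    def __post_init__(self) -> None:
        self.variant_idx = np.asarray(self.variant_idx, dtype=int)
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.p_value = np.asarray(self.p_value, dtype=float)
        self.step = np.asarray(self.step, dtype=int)
        if self.step_ve is None:
            self.step_ve = np.full(len(self.variant_idx), np.nan)
        self.step_ve = np.asarray(self.step_ve, dtype=float)
        if len(self.step) and np.any(np.diff(self.step) <= 0):
            raise ValueError("steps must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return len(self.variant_idx)

    def to_frame(self, variant_ids=None, positions=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"variant_idx": self.variant_idx, "beta": self.beta_hat,
             "p": self.p_value, "step": self.step, "step_ve": self.step_ve}
        )
        if variant_ids is not None:
            df.insert(0, "variant_id", np.asarray(variant_ids)[self.variant_idx])
        if positions is not None:
            df.insert(1, "position", np.asarray(positions)[self.variant_idx])
        return df


@dataclass
class JointFit:
    """Multivariable OLS of the trait on a set of variants."""

    variant_idx: np.ndarray
    beta_hat: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    r_squared: float
    cov: np.ndarray
    pruned_idx: np.ndarray  # perfectly collinear variants dropped pre-fit


def _scan_arrays(dosages: np.ndarray, y: np.ndarray) -> ScanResult:
    n, m = dosages.shape
    if len(y) != n:
        raise ValueError("trait length does not match sample count")
    if n < 3:
        raise ValueError("need at least 3 samples for a per-variant regression")
    yc = y - y.mean()
    gc = dosages - dosages.mean(axis=0)
    sxx = np.einsum("ij,ij->j", gc, gc)
    excluded = sxx == 0
    sxx_safe = np.where(excluded, np.nan, sxx)
    sxy = yc @ gc
    beta = sxy / sxx_safe
    syy = float(yc @ yc)
    rss = np.maximum(syy - beta * sxy, 0.0)
    dof = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / dof / sxx_safe)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p = np.clip(p, _P_MIN, 1.0)
    # exact fits: rss == 0 -> se 0, t inf, p at the clip floor
    p = np.where(np.isnan(t) & ~excluded, 1.0, p)
    p = np.where(excluded, np.nan, p)
    return ScanResult(beta, se, p, excluded)


def univariate_scan(G: GenotypeMatrix | np.ndarray, y: np.ndarray) -> ScanResult:
    """Simple linear regression of the trait on each variant's dosage.

    Vectorized over variants; constant variants are excluded (flagged, NaN
    estimates) rather than raising.
    """
    dosages = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    return _scan_arrays(dosages, np.asarray(y, dtype=float))


def stepwise_conditional(
    G: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    alpha: float = ALPHA_DEFAULT,
    max_steps: int = 10,
) -> StepwisePeaks:
    """Sequential conditional discovery by residual forwarding.

    Repeatedly scan the current dependent variable (the trait, then the
    residual of each discovered SNP); if the minimum p-value beats ``alpha``
    record that variant with its conditional estimate and carry the
    regression residual forward. Ties at identical p break to the lowest
    variant index. An empty peak list is a valid outcome.

    Already-selected variants are excluded from later scans: the residual is
    orthogonal only to the most recent pick, so without the exclusion a
    variant could re-enter and be double-counted.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    dosages = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    y = np.asarray(y, dtype=float)
    var_y = float(np.var(y))

    resid = y.copy()
    idx, betas, ps, steps, step_ve = [], [], [], [], []
    taken = np.zeros(dosages.shape[1], dtype=bool)
    stop = "max_steps"
    for step in range(1, max_steps + 1):
        scan = _scan_arrays(dosages, resid)
        scan.p_value[taken] = np.nan
        scan.excluded = scan.excluded | taken
        j = scan.argmin_p()
        if scan.excluded.all() or not (scan.p_value[j] < alpha):
            stop = "no_variant_below_alpha"
            break
        g = dosages[:, j]
        gc = g - g.mean()
        b = float((resid - resid.mean()) @ gc / (gc @ gc))
        new_resid = resid - resid.mean() - b * gc
        taken[j] = True
        idx.append(j)
        betas.append(scan.beta_hat[j])
        ps.append(scan.p_value[j])
        steps.append(step)
        contrib = (np.var(resid) - np.var(new_resid)) / var_y if var_y > 0 else 0.0
        step_ve.append(contrib)
        resid = new_resid
    return StepwisePeaks(idx, betas, ps, steps, stop, step_ve)


def joint_fit(
    G: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    idx: Sequence[int],
) -> JointFit:
    """Multivariable least squares of the trait on the selected variants.

    Variants perfectly collinear (pairwise dosage r^2 at 1 within 1e-12)
    with an earlier-listed variant are pruned before fitting and reported in
    ``pruned_idx``. Remaining rank deficiency, or n <= #parameters, raises.
    """
    dosages = G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    y = np.asarray(y, dtype=float)
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise ValueError("idx must be non-empty")
    if len(np.unique(idx)) != len(idx):
        raise ValueError("variant indices must be distinct")

    cols = dosages[:, idx]
    keep: list[int] = []
    pruned: list[int] = []
    for j in range(len(idx)):
        cj = cols[:, j]
        if cj.std() == 0:
            pruned.append(idx[j])
            continue
        collinear = False
        for kpt in keep:
            r = np.corrcoef(cj, cols[:, kpt])[0, 1]
            if r * r >= _COLLINEAR_R2:
                collinear = True
                break
        if collinear:
            pruned.append(idx[j])  # variant index in the panel
        else:
            keep.append(j)  # position within cols
    kept_idx = idx[keep]
    n = dosages.shape[0]
    p_params = len(keep) + 1
    if n <= p_params:
        raise ValueError(
            f"n = {n} samples cannot identify {p_params} parameters"
        )
    X = np.column_stack([np.ones(n), cols[:, keep]])
    xtx = X.T @ X
    cond = np.linalg.cond(xtx)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"design rank-deficient after pruning; offending variants {kept_idx}"
        )
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    dof = n - p_params
    sigma2 = float(resid @ resid) / dof
    cov_all = sigma2 * np.linalg.inv(xtx)
    beta = coef[1:]
    se = np.sqrt(np.diag(cov_all)[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = np.clip(2.0 * stats.t.sf(np.abs(t), dof), _P_MIN, 1.0)
    syy = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / syy if syy > 0 else 0.0
    return JointFit(kept_idx, beta, se, p, r2, cov_all[1:, 1:], np.asarray(pruned))


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def expected_univariate_bias(
    r: float, beta_other: float, p_focal: float, p_other: float
) -> float:
    """Expected bias of the focal SNP's univariate estimate.

    When two causal variants are in LD with signed dosage correlation ``r``
    and only the focal one is modeled, the simple-regression slope converges
    to b1 + b2 * Cov(g1, g2) / Var(g1), i.e.

        E[b1_hat] - b1 = r * b2 * sqrt(p2 (1-p2) / (p1 (1-p1))),

    with p1 the focal and p2 the omitted variant's maf. The frequency-ratio
    orientation is fixed by simulation (the ratio cancels at p1 = p2, where
    the bias is simply r * b2).
    """
    for name, p in (("p_focal", p_focal), ("p_other", p_other)):
        if not (0.0 < p <= 0.5):
            raise ValueError(f"{name} must lie in (0, 0.5], got {p}")
    bound = max_abs_r(p_focal, p_other)
    if abs(r) > bound + 1e-12:
        raise ValueError(
            f"|r| = {abs(r):.4f} exceeds the attainable bound {bound:.4f} "
            f"for maf ({p_focal}, {p_other})"
        )
    return float(
        r
        * beta_other
        * np.sqrt(p_other * (1 - p_other) / (p_focal * (1 - p_focal)))
    )


def univariate_power(ve: float, n: int, alpha: float = ALPHA_DEFAULT) -> float:
    """Power of the 1-df univariate association test.

    Closed form via the noncentral chi-square: the association statistic is
    asymptotically chi-square(1) with noncentrality n * ve / (1 + ve), where
    ve is the variance explained relative to unit environmental noise (so
    ve / (1 + ve) is the fraction of total trait variance). At ve = 0 the
    power equals alpha.
    """
    if not (0.0 <= ve < 1.0):
        raise ValueError("ve must lie in [0, 1)")
    if n < 1:
        raise ValueError("n must be positive")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    lam = n * ve / (1.0 + ve)
    crit = stats.chi2.isf(alpha, df=1)
    return float(stats.ncx2.sf(crit, df=1, nc=lam)) if lam > 0 else float(alpha)


# ---------------------------------------------------------------------------
# sample-size search for accurate joint pair estimation
# ---------------------------------------------------------------------------


def _maf_for_het(two_pq: float = 0.4) -> float:
    """maf p solving 2 p (1-p) = two_pq (lower root)."""
    disc = 1.0 - 2.0 * two_pq
    if disc < 0:
        raise ValueError("2p(1-p) cannot exceed 0.5")
    return 0.5 * (1.0 - np.sqrt(disc))


@dataclass
class SampleSizeResult:
    """Error-vs-n curve and the smallest n meeting the accuracy criterion."""

    required_n: int | None  # None when the criterion is never met on the grid
    criterion: str
    tol: float
    curve: pd.DataFrame  # columns n, mean_abs_error, rmse, sd (per-site mean)

    @property
    def reached(self) -> bool:
        return self.required_n is not None


def required_sample_size(
    r2: float,
    ve_each: float,
    tol: float = 0.1,
    n_grid: Sequence[int] = tuple(range(100, 3001, 100)),
    reps: int = 1000,
    seed: int | np.random.Generator | None = None,
    criterion: Literal["mean_abs_error", "rmse", "sd"] = "mean_abs_error",
    maf: float | None = None,
) -> SampleSizeResult:
    """Smallest n at which a joint two-SNP fit estimates both effects to ``tol``.

    For each n on the grid, ``reps`` replicate panels of two variants in LD
    r^2 = ``r2`` are generated by the exact haplotype construction (equal
    mafs; default maf solves 2p(1-p) = 0.4 so ve = 0.1 corresponds to
    beta = 0.5 sdu), both variants are assigned ve = ``ve_each`` with
    positive minor-allele effects, traits get unit normal noise, and the two
    variants are fitted jointly. The per-replicate error is the mean
    |beta_hat - beta| over both sites; the curve also reports RMSE and the
    estimator SD so the accuracy criterion can be compared across metrics.
    """
    if not (0.0 <= r2 < 1.0):
        raise ValueError("r2 must lie in [0, 1)")
    if reps < 100:
        raise ValueError("reps must be >= 100 for a stable curve")
    n_grid = [int(n) for n in n_grid]
    if any(b <= a for a, b in zip(n_grid, n_grid[1:])):
        raise ValueError("n_grid must be strictly ascending")
    rng = np.random.default_rng(seed)
    p = _maf_for_het(0.4) if maf is None else float(maf)
    beta = float(beta_from_ve(ve_each, p))
    r = float(np.sqrt(r2))

    rows = []
    required = None
    for n in n_grid:
        g1, g2 = _sample_pair_batch(reps, n, p, p, r, rng)
        eps = rng.standard_normal((reps, n))
        yy = beta * (g1 + g2) + eps
        b1, b2 = _joint_pair_batch(g1, g2, yy)
        # replicates whose pair is perfectly collinear in-sample carry no
        # two-site information; they are excluded from the error average
        ok = np.isfinite(b1) & np.isfinite(b2)
        dev = np.stack([b1[ok] - beta, b2[ok] - beta])  # (2, n_ok)
        mae = float(np.mean(np.abs(dev)))
        rmse = float(np.sqrt(np.mean(dev**2)))
        sd = float(np.mean(np.std(dev, axis=1)))
        rows.append(
            {"n": n, "mean_abs_error": mae, "rmse": rmse, "sd": sd,
             "n_collinear": int((~ok).sum())}
        )
        if required is None and {"mean_abs_error": mae, "rmse": rmse, "sd": sd}[
            criterion
        ] <= tol:
            required = n
    curve = pd.DataFrame(rows)
    return SampleSizeResult(required, criterion, tol, curve)


def _joint_pair_batch(
    g1: np.ndarray, g2: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form two-predictor OLS slopes, vectorized over replicate rows."""
    g1c = g1 - g1.mean(axis=1, keepdims=True)
    g2c = g2 - g2.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    s11 = np.einsum("ij,ij->i", g1c, g1c)
    s22 = np.einsum("ij,ij->i", g2c, g2c)
    s12 = np.einsum("ij,ij->i", g1c, g2c)
    s1y = np.einsum("ij,ij->i", g1c, yc)
    s2y = np.einsum("ij,ij->i", g2c, yc)
    det = s11 * s22 - s12**2
    det = np.where(det == 0, np.nan, det)
    b1 = (s22 * s1y - s12 * s2y) / det
    b2 = (s11 * s2y - s12 * s1y) / det
    return b1, b2
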
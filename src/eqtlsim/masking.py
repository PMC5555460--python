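"""The unimputed-causal-variant experiment.

A single causal variant is simulated, then deleted from the panel together
with all of its close LD proxies (the variant is "not imputed"), and the
stepwise pipeline is run on what remains. The residual imperfect proxies can
split the causal signal into a primary plus a spurious secondary
association; trials are aggregated over a rare-shifted maf spectrum into
per-maf-bin detection rates and a cumulative spectrum-weighted spurious
proportion.

The locus places the causal variant *between* two proxy branches: each
branch anchor is generated conditionally on the causal haplotype at a target
r^2 given by a declared parametric tagging-efficiency curve (expected
best-proxy r^2 rising steeply with maf — common variants are well tagged,
rare ones barely), and each branch extends from its anchor as a high-LD
chain; independent common background variants complete the panel. The
two-branch geometry is what makes signal splitting possible at all: once the
causal is deleted, the branches correlate with each other only through it,
so conditioning on the best proxy on one side leaves residual causal signal
on the other side. Within a branch, proxies are in strong mutual LD (shared
haplotype background), which keeps the number of spurious signals bounded.
The curve stands in for the empirical maf -> tagging relationship of a real
imputation panel and is recorded in every summary.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    GenotypeMatrix,
    HaplotypePanel,
    MafSpectrum,
    haplotype_frequencies,
    ld_matrix,
)
from .phenotypes import CausalConfig, beta_from_ve, simulate_trait
from .association import ALPHA_DEFAULT, stepwise_conditional

__all__ = [
    "TaggingCurve",
    "MaskTrial",
    "SpuriousSignalSummary",
    "mask_tagged",
    "simulate_tagged_locus",
    "spurious_signal_trial",
    "run_mask_experiment",
    "aggregate_by_maf_bin",
    "genomewide_false_secondary_count",
]

MASK_R2_DEFAULT = 0.8
MAF_BIN_EDGES = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5)


@dataclass
class TaggingCurve:
    """Expected best-proxy r^2 as a function of causal maf.

    Logistic in log10(maf): r2_max / (1 + exp(-(log10(p) - mid) / scale)).
    Defaults give ~0.08 at maf 0.01, ~0.70 at maf 0.05, and ~0.84 for common
    variants: tagging efficiency collapses with rarity (variants absent from
    an imputation panel are poorly proxied when rare — poorly enough that a
    rare causal usually yields no association signal at all) while common
    variants almost always have a strong proxy.
    """

    r2_max: float = 0.85
    log10_midpoint: float = -1.58
    log10_scale: float = 0.18

    def best_r2(self, maf) -> np.ndarray:
        maf = np.asarray(maf, dtype=float)
        x = np.log10(maf)
        return (
            self.r2_max / (1.0 + np.exp(-(x - self.log10_midpoint) / self.log10_scale))
        )[()]


@dataclass
class MaskTrial:
    causal_maf: float
    ve: float
    best_remaining_proxy_r2: float
    primary_detected: bool
    secondary_detected: bool
    n_peaks: int
    masked: bool
    n_removed: int
    seed: int

    def __post_init__(self) -> None:
        if self.secondary_detected and not self.primary_detected:
            raise ValueError("secondary signal without a primary is impossible")


@dataclass
class SpuriousSignalSummary:
    bin_edges: np.ndarray
    n_trials: np.ndarray
    primary_rate: np.ndarray
    secondary_rate: np.ndarray
    primary_ci: np.ndarray  # (bins, 2) Clopper-Pearson 95%
    secondary_ci: np.ndarray
    weights: np.ndarray  # spectrum mass per bin, sums to 1
    cumulative_spurious_proportion: float
    tagging_curve: dict
    spectrum: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "maf_lo": self.bin_edges[:-1],
                "maf_hi": self.bin_edges[1:],
                "n_trials": self.n_trials,
                "primary_rate": self.primary_rate,
                "secondary_rate": self.secondary_rate,
                "primary_ci_lo": self.primary_ci[:, 0],
                "primary_ci_hi": self.primary_ci[:, 1],
                "secondary_ci_lo": self.secondary_ci[:, 0],
                "secondary_ci_hi": self.secondary_ci[:, 1],
                "weight": self.weights,
            }
        )


def mask_tagged(
    G: GenotypeMatrix, causal_idx: int, r2_cut: float = MASK_R2_DEFAULT
) -> tuple[GenotypeMatrix, dict]:
    """Remove the causal column and every column with r^2 above the cutoff.

    Returns the reduced panel and a removal log carrying the removed variant
    ids and the best remaining proxy r^2 to the causal. A cutoff of 0 (or a
    panel of perfect proxies) can empty the panel, which raises.
    """
    if not (0 <= causal_idx < G.n_variants):
        raise ValueError("causal index outside the panel")
    causal = G.dosages[:, causal_idx]
    if causal.std() == 0:
        raise ValueError("causal column is constant")
    dc = G.dosages - G.dosages.mean(axis=0)
    cc = causal - causal.mean()
    denom = np.sqrt((dc**2).sum(axis=0) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, dc.T @ cc / np.where(denom > 0, denom, 1.0), 0.0)
    r2 = r**2
    remove = r2 > r2_cut
    remove[causal_idx] = True
    if remove.all():
        raise ValueError("masking would remove the entire panel")
    keep = np.flatnonzero(~remove)
    best_remaining = float(np.nanmax(r2[keep])) if keep.size else 0.0
    log = {
        "removed_ids": list(map(str, G.variant_ids[remove])),
        "n_removed": int(remove.sum()),
        "best_remaining_proxy_r2": best_remaining,
        "r2_cut": float(r2_cut),
    }
    return G.subset(keep), log


def _conditional_haplotype(
    parent: np.ndarray, p: float, r: float, rng: np.random.Generator
) -> np.ndarray:
    """Child haplotype at equal maf ``p`` with target correlation ``r``."""
    f = haplotype_frequencies(p, p, r)
    p_given1 = f[3] / (f[2] + f[3])
    p_given0 = f[1] / (f[0] + f[1])
    pr = np.where(parent == 1, p_given1, p_given0)
    return (rng.random(parent.shape[0]) < pr).astype(np.int8)


def simulate_tagged_locus(
    n_samples: int,
    causal_maf: float,
    curve: TaggingCurve,
    rng: np.random.Generator,
    n_tagging: int = 30,
    n_background: int = 70,
    chain_r2: float = 0.9,
) -> tuple[GenotypeMatrix, int]:
    """Locus with a causal variant flanked by two high-LD proxy branches.

    The causal haplotype is Bernoulli(causal_maf). Each of two branch
    anchors (same maf as the causal) is generated conditionally on the
    causal with an independent target r^2 = U(0.7, 1) * r2_best(maf); each
    branch extends from its anchor as a chain with neighbor r^2 =
    ``chain_r2``. Branches are conditionally independent given the causal,
    so deleting the causal leaves two imperfectly coupled signal paths.
    Background variants (maf U(0.05, 0.5)) are independent of the causal.
    Returns the panel plus the causal's column index.
    """
    p_c = float(causal_maf)
    n_hap = 2 * int(n_samples)
    causal_h = (rng.random(n_hap) < p_c).astype(np.int8)
    # guarantee a polymorphic causal column
    while causal_h.sum() in (0, n_hap):
        causal_h = (rng.random(n_hap) < p_c).astype(np.int8)

    r2_best = float(curve.best_r2(p_c))
    r_chain = float(np.sqrt(chain_r2))
    cols = [causal_h]
    per_branch = (n_tagging + 1) // 2
    for _branch in range(2):
        anchor_r2 = r2_best * rng.uniform(0.7, 1.0)
        parent = _conditional_haplotype(
            causal_h, p_c, float(np.sqrt(anchor_r2)), rng
        )
        cols.append(parent)
        for _ in range(per_branch - 1):
            parent = _conditional_haplotype(parent, p_c, r_chain, rng)
            cols.append(parent)
    bg_maf = rng.uniform(0.05, 0.5, size=n_background)
    bg = (rng.random((n_hap, n_background)) < bg_maf).astype(np.int8)
    alleles = np.column_stack(cols + [bg])
    m = alleles.shape[1]
    order = rng.permutation(m)
    causal_col = int(np.flatnonzero(order == 0)[0])
    alleles = alleles[:, order]
    positions = np.sort(rng.choice(400_000, size=m, replace=False))
    ids = np.array([f"v{j}" for j in range(m)])
    panel = HaplotypePanel(alleles, positions, ids)
    return panel.to_genotypes(), causal_col


def spurious_signal_trial(
    n_samples: int = 1839,
    maf_spec: MafSpectrum | None = None,
    ve_range: tuple[float, float] = (0.02, 0.10),
    alpha: float = ALPHA_DEFAULT,
    r2_cut: float = MASK_R2_DEFAULT,
    curve: TaggingCurve | None = None,
    mask: bool = True,
    seed: int | np.random.Generator | None = None,
    n_tagging: int = 30,
    n_background: int = 70,
    chain_r2: float = 0.9,
    max_steps: int = 10,
) -> MaskTrial:
    """One trial: simulate, (optionally) mask the causal + proxies, detect.

    With ``mask=False`` (control mode) the causal stays in the panel and the
    trial reduces to the standard single-causal pipeline, so the
    spurious-secondary rate collapses to the null stepwise rate.
    """
    if maf_spec is None:
        maf_spec = MafSpectrum("rare_shifted")
    if curve is None:
        curve = TaggingCurve()
    rng = np.random.default_rng(seed)
    seed_rec = int(rng.integers(2**31)) if isinstance(seed, np.random.Generator) else (
        seed if isinstance(seed, int) else -1
    )
    p_c = float(maf_spec.sample(1, rng)[0])
    G, causal_col = simulate_tagged_locus(
        n_samples, p_c, curve, rng, n_tagging, n_background, chain_r2
    )
    ve = float(rng.uniform(*ve_range))
    maf_emp = float(G.maf[causal_col])
    config = CausalConfig(
        causal_idx=np.array([causal_col]),
        ve=np.array([ve]),
        sign=np.array([1]),
        beta=np.array([float(beta_from_ve(ve, maf_emp))]),
        maf=np.array([maf_emp]),
        scenario="1:0",
    )
    trait = simulate_trait(G, config, seed=rng)

    if mask:
        reduced, log = mask_tagged(G, causal_col, r2_cut)
        best_proxy = log["best_remaining_proxy_r2"]
        n_removed = log["n_removed"]
    else:
        reduced, best_proxy, n_removed = G, 1.0, 0
    peaks = stepwise_conditional(reduced, trait.y, alpha=alpha, max_steps=max_steps)
    return MaskTrial(
        causal_maf=p_c,
        ve=ve,
        best_remaining_proxy_r2=float(best_proxy),
        primary_detected=peaks.n_peaks >= 1,
        secondary_detected=peaks.n_peaks >= 2,
        n_peaks=peaks.n_peaks,
        masked=mask,
        n_removed=n_removed,
        seed=seed_rec,
    )


def run_mask_experiment(
    n_trials: int = 500,
    seed: int = 0,
    **trial_kwargs,
) -> pd.DataFrame:
    """Run independent mask trials; trial k's seed is SeedSequence([seed, k])."""
    rows = []
    for k in range(n_trials):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), k]))
        trial = spurious_signal_trial(seed=rng, **trial_kwargs)
        row = asdict(trial)
        row["trial"] = k
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_by_maf_bin(
    trials: pd.DataFrame,
    bin_edges: Sequence[float] = MAF_BIN_EDGES,
    maf_spec: MafSpectrum | None = None,
    tagging_curve: TaggingCurve | None = None,
) -> SpuriousSignalSummary:
    """Per-maf-bin detection rates and the cumulative weighted spurious rate.

    The cumulative proportion sums each bin's secondary-signal rate weighted
    by the maf spectrum's mass in that bin (empty bins contribute their
    weight times a NaN rate, reported as missing and excluded from the sum
    with a renormalization over observed bins).
    """
    if maf_spec is None:
        maf_spec = MafSpectrum("rare_shifted")
    if tagging_curve is None:
        tagging_curve = TaggingCurve()
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be ascending with >= 2 entries")
    nb = len(edges) - 1
    weights = maf_spec.bin_masses(edges)
    idx = np.clip(np.digitize(trials["causal_maf"], edges) - 1, 0, nb - 1)

    n = np.zeros(nb, dtype=int)
    prim = np.full(nb, np.nan)
    sec = np.full(nb, np.nan)
    prim_ci = np.full((nb, 2), np.nan)
    sec_ci = np.full((nb, 2), np.nan)
    for b in range(nb):
        sub = trials[idx == b]
        n[b] = len(sub)
        if n[b] == 0:
            continue
        kp = int(sub["primary_detected"].sum())
        ks = int(sub["secondary_detected"].sum())
        prim[b] = kp / n[b]
        sec[b] = ks / n[b]
        prim_ci[b] = _clopper_pearson(kp, n[b])
        sec_ci[b] = _clopper_pearson(ks, n[b])

    observed = ~np.isnan(sec)
    if observed.any():
        w = weights[observed] / weights[observed].sum()
        cumulative = float(np.sum(sec[observed] * w))
    else:
        cumulative = float("nan")
    return SpuriousSignalSummary(
        edges, n, prim, sec, prim_ci, sec_ci, weights, cumulative,
        tagging_curve=asdict(tagging_curve),
        spectrum={"kind": maf_spec.kind, "beta_a": maf_spec.beta_a,
                  "beta_b": maf_spec.beta_b, "floor": maf_spec.floor,
                  "ceiling": maf_spec.ceiling},
    )


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    a = (1 - conf) / 2
    lo = stats.beta.ppf(a, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def genomewide_false_secondary_count(
    cumulative_spurious_proportion: float,
    n_unobserved_variants: float,
    genic_fraction: float,
    functional_fraction: float,
) -> float:
    """Extrapolated genome-wide count of spurious secondary associations.

    Pure arithmetic: cumulative spurious proportion x number of variants
    absent from the panel x fraction near genes x fraction with a real
    effect. All constants are user-supplied (they are properties of a
    particular cohort and panel, not of this package).
    """
    for name, v in (
        ("cumulative_spurious_proportion", cumulative_spurious_proportion),
        ("genic_fraction", genic_fraction),
        ("functional_fraction", functional_fraction),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if n_unobserved_variants < 0:
        raise ValueError("variant count must be non-negative")
    return (
        cumulative_spurious_proportion
        * n_unobserved_variants
        * genic_fraction
        * functional_fraction
    )
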
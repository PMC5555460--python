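"""Scoring of simulation replicates.

Metrics mirror how multisite cis-eQTL simulations are typically summarized:

* tagging efficiency — the fraction of discovered peaks whose r^2 > 0.8
  "credible interval" contains a true causal variant (one causal per peak,
  claimed in step order; a peak in high LD with several causals is matched
  to the one with the largest true effect);
* causal capture — the reciprocal count of causal sites lying within
  r^2 > 0.8 of at least one peak (no dedup);
* RTC, the Regulatory Trait Concordance score
  (N_SNPs - rank_causal) / N_SNPs, a rank-based localization measure
  (1 = the causal site is the top association);
* a four-way variance decomposition (true sites jointly; discovered peaks
  jointly; summed sequential conditional contributions; top peak alone);
* bias surfaces — mean |estimate - true beta| binned by true |beta| and the
  causal site's mean LD with its co-causal sites, for conditional and joint
  estimates.

`run_experiment` ties the pipeline together over replicates and aggregates
detection-count x scenario contingency tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, LDBlockSpec, MafSpectrum, ld_matrix, simulate_locus, sample_causal_set
from .phenotypes import CausalConfig, assign_effects, simulate_trait
from .association import (
    ALPHA_DEFAULT,
    JointFit,
    StepwisePeaks,
    joint_fit,
    stepwise_conditional,
    univariate_scan,
)

__all__ = [
    "TaggingReport",
    "DetectionReport",
    "VarianceDecomposition",
    "BiasSurface",
    "match_peaks_to_causals",
    "count_captured_causals",
    "rtc_score",
    "variance_decomposition",
    "bias_surface",
    "run_experiment",
    "ExperimentResult",
]

R2_CREDIBLE = 0.8


@dataclass
class TaggingReport:
    """Peak -> causal matching at an r^2 cutoff (one causal per peak)."""

    n_peaks: int
    matched_causal: np.ndarray  # per-peak causal position in config, -1 = spurious
    best_r2: np.ndarray  # per-peak best r^2 to any causal (matched or not)
    proportion_matched: float
    r2_cut: float

    @property
    def n_spurious(self) -> int:
        return int((self.matched_causal < 0).sum())


@dataclass
class DetectionReport:
    """Causal capture: which simulated sites fall in a peak's credible set."""

    n_causal: int
    captured: np.ndarray  # per-causal bool
    best_tagging_r2: np.ndarray  # per-causal max r^2 over peaks
    r2_cut: float

    @property
    def n_causal_captured(self) -> int:
        return int(self.captured.sum())


@dataclass
class VarianceDecomposition:
    ve_simulated: float  # true sites fitted jointly
    ve_joint: float  # discovered peaks fitted jointly
    ve_conditional_sum: float  # summed sequential contributions
    ve_top_peak: float  # first peak alone


@dataclass
class BiasSurface:
    """Mean |deviation| per (true |beta|, mean co-causal r^2) cell."""

    beta_edges: np.ndarray
    r2_edges: np.ndarray
    conditional: np.ndarray  # NaN where empty
    joint: np.ndarray
    difference: np.ndarray  # joint - conditional mean deviation
    counts: np.ndarray


def match_peaks_to_causals(
    peaks: StepwisePeaks,
    config: CausalConfig,
    ld: np.ndarray,
    r2_cut: float = R2_CREDIBLE,
) -> TaggingReport:
    """Match each peak (in step order) to an unclaimed causal at r^2 > cutoff.

    ``ld`` is the full panel r^2 matrix (indexed by variant index). A peak in
    high LD with several causals claims the one with the largest true |beta|;
    a causal claimed by an earlier-step peak is unavailable to later peaks;
    peaks with no eligible causal are flagged spurious (-1).
    """
    k = config.k
    matched = np.full(peaks.n_peaks, -1, dtype=int)
    best_r2 = np.zeros(peaks.n_peaks)
    claimed = np.zeros(k, dtype=bool)
    for i, v in enumerate(peaks.variant_idx):
        r2_row = ld[v, config.causal_idx]
        r2_row = np.where(np.isnan(r2_row), 0.0, r2_row)
        best_r2[i] = r2_row.max() if k else 0.0
        eligible = (r2_row > r2_cut) & ~claimed
        if eligible.any():
            cand = np.flatnonzero(eligible)
            chosen = cand[np.argmax(config.beta[cand])]
            matched[i] = chosen
            claimed[chosen] = True
    prop = float((matched >= 0).mean()) if peaks.n_peaks else 0.0
    return TaggingReport(peaks.n_peaks, matched, best_r2, prop, r2_cut)


def count_captured_causals(
    peaks: StepwisePeaks,
    config: CausalConfig,
    ld: np.ndarray,
    r2_cut: float = R2_CREDIBLE,
) -> DetectionReport:
    """A causal is captured iff some peak has r^2 above the cutoff with it."""
    if peaks.n_peaks == 0:
        zeros = np.zeros(config.k)
        return DetectionReport(config.k, zeros.astype(bool), zeros, r2_cut)
    sub = ld[np.ix_(peaks.variant_idx, config.causal_idx)]
    sub = np.where(np.isnan(sub), 0.0, sub)
    best = sub.max(axis=0)
    return DetectionReport(config.k, best > r2_cut, best, r2_cut)


def rtc_score(p_values: np.ndarray, causal_idx: int) -> float:
    """Regulatory Trait Concordance of one causal site given a p-value ranking.

    rank is the 0-based position of the causal variant when variants are
    ordered by ascending p-value; tied p-values share the minimal rank.
    RTC = (N - rank) / N, so 1 means the causal site is the top association.
    """
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if not (0 <= causal_idx < n):
        raise ValueError("causal index outside the ranking universe")
    if np.isnan(p[causal_idx]):
        raise ValueError("causal variant has no p-value in this ranking")
    rank = int(np.sum(p[~np.isnan(p)] < p[causal_idx]))
    return (n - rank) / n


def variance_decomposition(
    G: GenotypeMatrix,
    y: np.ndarray,
    peaks: StepwisePeaks,
    config: CausalConfig,
) -> VarianceDecomposition:
    """Four R^2 values on the same replicate (Fig-2-style Simu/Multi/Uni/Single)."""
    y = np.asarray(y, dtype=float)
    ve_sim = joint_fit(G, y, config.causal_idx).r_squared
    if peaks.n_peaks == 0:
        return VarianceDecomposition(ve_sim, 0.0, 0.0, 0.0)
    ve_joint = joint_fit(G, y, peaks.variant_idx).r_squared
    ve_cond = float(np.nansum(peaks.step_ve))
    ve_top = joint_fit(G, y, peaks.variant_idx[:1]).r_squared
    return VarianceDecomposition(ve_sim, ve_joint, ve_cond, ve_top)


def bias_surface(
    scored_pairs: pd.DataFrame,
    beta_edges: Sequence[float] | None = None,
    r2_edges: Sequence[float] | None = None,
) -> BiasSurface:
    """Bin scored (peak, causal) pairs into the bias heatmap.

    ``scored_pairs`` needs columns true_abs_beta, mean_r2_others,
    conditional_dev, joint_dev (absolute deviations in sdu); only peaks
    matched to a causal at the credible cutoff should be scored. Empty cells
    are NaN, never zero.
    """
    required = {"true_abs_beta", "mean_r2_others", "conditional_dev", "joint_dev"}
    missing = required - set(scored_pairs.columns)
    if missing:
        raise ValueError(f"scored_pairs missing columns {sorted(missing)}")
    if len(scored_pairs) == 0:
        raise ValueError("need at least one scored (peak, causal) pair")
    if beta_edges is None:
        top = max(0.2, float(scored_pairs["true_abs_beta"].max()) + 0.1)
        beta_edges = np.arange(0.0, top + 0.1, 0.1)
    if r2_edges is None:
        r2_edges = np.arange(0.0, 1.0001, 0.05)
    beta_edges = np.asarray(beta_edges, float)
    r2_edges = np.asarray(r2_edges, float)

    bi = np.clip(
        np.digitize(scored_pairs["true_abs_beta"], beta_edges) - 1,
        0, len(beta_edges) - 2,
    )
    ri = np.clip(
        np.digitize(scored_pairs["mean_r2_others"], r2_edges) - 1,
        0, len(r2_edges) - 2,
    )
    shape = (len(beta_edges) - 1, len(r2_edges) - 1)
    counts = np.zeros(shape, dtype=int)
    cond_sum = np.zeros(shape)
    joint_sum = np.zeros(shape)
    np.add.at(counts, (bi, ri), 1)
    np.add.at(cond_sum, (bi, ri), scored_pairs["conditional_dev"].to_numpy())
    np.add.at(joint_sum, (bi, ri), scored_pairs["joint_dev"].to_numpy())
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(counts > 0, cond_sum / counts, np.nan)
        joint = np.where(counts > 0, joint_sum / counts, np.nan)
    return BiasSurface(beta_edges, r2_edges, cond, joint, joint - cond, counts)


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------


@dataclass
class ExperimentResult:
    replicates: pd.DataFrame
    scored_pairs: pd.DataFrame
    rtc: pd.DataFrame  # per-replicate primary-peak RTC
    table_detected: pd.DataFrame  # Table-1-style: n_peaks distribution + tagging
    table_captured: pd.DataFrame  # Table-2-style: captured-count distribution
    meta: dict


def _score_replicate(
    G: GenotypeMatrix,
    y: np.ndarray,
    config: CausalConfig,
    alpha: float,
    r2_cut: float,
    max_steps: int,
):
    peaks = stepwise_conditional(G, y, alpha=alpha, max_steps=max_steps)
    # LD restricted to the variants we index (peaks + causals) for speed
    involved = np.unique(np.concatenate([peaks.variant_idx, config.causal_idx]))
    pos = {v: i for i, v in enumerate(involved)}
    sub = ld_matrix(G, involved)
    full_ld = _SubsetLD(sub, pos)
    tag = match_peaks_to_causals(peaks, config, full_ld, r2_cut)
    cap = count_captured_causals(peaks, config, full_ld, r2_cut)
    scan = univariate_scan(G, y)
    top_causal = config.causal_idx[int(np.argmax(config.beta))]
    rtc = rtc_score(scan.p_value, top_causal)
    vdec = variance_decomposition(G, y, peaks, config)

    jf = joint_fit(G, y, peaks.variant_idx) if peaks.n_peaks else None
    pair_rows = []
    causal_ld = ld_matrix(G, config.causal_idx)
    for i in range(peaks.n_peaks):
        c = tag.matched_causal[i]
        if c < 0:
            continue
        others = np.delete(np.arange(config.k), c)
        mean_r2 = float(np.nanmean(causal_ld[c, others])) if others.size else 0.0
        true_b = config.signed_beta[c]
        v = peaks.variant_idx[i]
        orient = np.sign(
            np.corrcoef(G.dosages[:, v], G.dosages[:, config.causal_idx[c]])[0, 1]
        ) or 1.0
        target = orient * true_b
        cond_dev = abs(peaks.beta_hat[i] - target)
        if jf is not None and v in jf.variant_idx:
            jb = jf.beta_hat[list(jf.variant_idx).index(v)]
            joint_dev = abs(jb - target)
        else:
            joint_dev = np.nan
        pair_rows.append(
            {
                "step": int(peaks.step[i]),
                "true_abs_beta": abs(true_b),
                "mean_r2_others": mean_r2,
                "conditional_dev": cond_dev,
                "joint_dev": joint_dev,
            }
        )
    return peaks, tag, cap, rtc, vdec, pair_rows


class _SubsetLD:
    """Full-panel-indexable view over an LD matrix of a variant subset."""

    def __init__(self, sub: np.ndarray, pos: dict):
        self._sub = sub
        self._pos = pos

    def _map(self, arr):
        arr = np.asarray(arr)
        if arr.ndim == 0:
            return self._pos[int(arr)]
        return np.reshape([self._pos[int(v)] for v in arr.ravel()], arr.shape)

    def __getitem__(self, key):
        i, j = key
        return self._sub[self._map(i), self._map(j)]


def run_experiment(
    scenario: str = "4:0",
    k_causal: int = 4,
    reps: int = 200,
    n_samples: int = 1839,
    n_snps: int = 200,
    ve_range: tuple[float, float] = (0.02, 0.10),
    alpha: float = ALPHA_DEFAULT,
    r2_cut: float = R2_CREDIBLE,
    max_steps: int = 10,
    block_spec: LDBlockSpec | None = None,
    maf_spec: MafSpectrum | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Run the full simulate -> detect -> score pipeline over replicates.

    Each replicate draws a fresh block-LD cis-window panel, samples
    ``k_causal`` causal sites uniformly, assigns VE ~ Uniform(ve_range) under
    the sign ``scenario``, simulates the trait, runs sequential conditional
    detection at ``alpha``, refits peaks jointly, and scores tagging,
    capture, RTC, variance decomposition, and per-site deviations.

    Replicate seeds are spawned as SeedSequence([seed, rep]) so replicate k
    is invariant to the total replicate count.
    """
    rep_rows, pair_rows, rtc_rows = [], [], []
    for rep in range(reps):
        ss = np.random.SeedSequence([int(seed), rep])
        rng = np.random.default_rng(ss)
        G = simulate_locus(n_samples, n_snps, block_spec, maf_spec, rng)
        causal_idx = sample_causal_set(G, k_causal, seed=rng)
        config = assign_effects(G, causal_idx, ve_range, scenario, seed=rng)
        trait = simulate_trait(G, config, seed=rng)
        peaks, tag, cap, rtc, vdec, pairs = _score_replicate(
            G, trait.y, config, alpha, r2_cut, max_steps
        )
        rep_rows.append(
            {
                "rep": rep,
                "scenario": scenario,
                "n_peaks": peaks.n_peaks,
                "n_matched": int((tag.matched_causal >= 0).sum()),
                "n_spurious": tag.n_spurious,
                "proportion_matched": tag.proportion_matched,
                "n_captured": cap.n_causal_captured,
                "ve_simulated": vdec.ve_simulated,
                "ve_joint": vdec.ve_joint,
                "ve_conditional_sum": vdec.ve_conditional_sum,
                "ve_top_peak": vdec.ve_top_peak,
            }
        )
        rtc_rows.append({"rep": rep, "scenario": scenario, "rtc": rtc})
        for row in pairs:
            row["rep"] = rep
            pair_rows.append(row)

    replicates = pd.DataFrame(rep_rows)
    scored = pd.DataFrame(
        pair_rows,
        columns=["rep", "step", "true_abs_beta", "mean_r2_others",
                 "conditional_dev", "joint_dev"],
    )
    rtc_df = pd.DataFrame(rtc_rows)
    table1 = _detected_table(replicates, k_causal)
    table2 = _captured_table(replicates, k_causal)
    meta = {
        "scenario": scenario, "k_causal": k_causal, "reps": reps,
        "n_samples": n_samples, "n_snps": n_snps, "ve_range": list(ve_range),
        "alpha": alpha, "r2_cut": r2_cut, "seed": int(seed),
        "note": (
            "tagging proportions average over all peaks including those "
            "beyond the k-th in '>k' rows"
        ),
    }
    return ExperimentResult(replicates, scored, rtc_df, table1, table2, meta)


def _detected_table(replicates: pd.DataFrame, k: int) -> pd.DataFrame:
    """Detection-count distribution with mean tagging proportion per row."""
    rows = []
    total = len(replicates)
    labels = [str(i) for i in range(0, k + 1)] + [f">{k}"]
    for lab in labels:
        if lab.startswith(">"):
            mask = replicates["n_peaks"] > k
        else:
            mask = replicates["n_peaks"] == int(lab)
        sub = replicates[mask]
        with_peaks = sub[sub["n_peaks"] > 0]
        rows.append(
            {
                "detected": lab,
                "percent": 100.0 * len(sub) / total if total else np.nan,
                "tagging_proportion": (
                    float(with_peaks["proportion_matched"].mean())
                    if len(with_peaks)
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def _captured_table(replicates: pd.DataFrame, k: int) -> pd.DataFrame:
    rows = []
    total = len(replicates)
    for c in range(0, k + 1):
        sub = replicates[replicates["n_captured"] == c]
        rows.append(
            {"captured": c, "percent": 100.0 * len(sub) / total if total else np.nan}
        )
    return pd.DataFrame(rows)
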
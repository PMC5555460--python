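"""Synthetic genotype panels with controlled allele frequencies and LD.

Diploid dosage genotypes (minor-allele counts 0/1/2) are built from simulated
haplotypes. Two generators are provided:

* :func:`sample_pair` — an exact two-locus construction from the classical
  haplotype-frequency parameterization ``p11 = p1*p2 + D`` with
  ``D = r*sqrt(p1*q1*p2*q2)``, used wherever a precise pairwise LD target
  (r^2 = 0.1, 0.5, 0.9, ...) is required.
* :func:`simulate_locus` — a latent-Gaussian block model producing a whole
  ~400 kb cis-window of variants with serially correlated LD inside blocks
  and independence between blocks, standing in for a real imputed panel.

LD throughout the analysis layer is the squared Pearson correlation of
*dosages*; the haplotype-level correlation r appears only inside generation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InfeasibleLDError",
    "HaplotypePanel",
    "GenotypeMatrix",
    "LDBlockSpec",
    "MafSpectrum",
    "max_abs_r",
    "signed_r_bounds",
    "haplotype_frequencies",
    "sample_pair",
    "simulate_locus",
    "ld_matrix",
    "sample_causal_set",
    "read_genotypes",
    "write_dosage_tsv",
]

MAF_FLOOR = 0.01
WINDOW_BP = 400_000


class InfeasibleLDError(ValueError):
    """Requested LD target exceeds what the two allele frequencies permit."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class HaplotypePanel:
    """2n x m binary matrix of minor alleles plus variant metadata."""

    alleles: np.ndarray
    positions: np.ndarray
    variant_ids: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.positions = np.asarray(self.positions)
        self.variant_ids = np.asarray(self.variant_ids)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (2n x m) matrix")
        if self.alleles.shape[0] % 2:
            raise ValueError("haplotype count must be even (two per diplotype)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("haplotype entries must be 0/1")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_variants(self) -> int:
        return self.alleles.shape[1]

    def to_genotypes(self) -> "GenotypeMatrix":
        """Pair consecutive haplotypes (2i, 2i+1) into diploid dosages.

        Columns whose empirical allele frequency drifted above 0.5 are
        flipped so dosages always count the (empirical) minor allele.
        """
        dos = (self.alleles[0::2] + self.alleles[1::2]).astype(np.float64)
        flip = dos.mean(axis=0) > 1.0
        dos[:, flip] = 2.0 - dos[:, flip]
        return GenotypeMatrix(dos, self.positions, self.variant_ids)


@dataclass
class GenotypeMatrix:
    """n samples x m variants dosage matrix oriented to the minor allele."""

    dosages: np.ndarray
    positions: np.ndarray
    variant_ids: np.ndarray
    maf: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.positions = np.asarray(self.positions)
        self.variant_ids = np.asarray(self.variant_ids)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be n x m")
        if self.dosages.shape[1] != len(self.positions):
            raise ValueError("positions length does not match variant count")
        self.maf = self.dosages.mean(axis=0) / 2.0

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset(self, idx: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.dosages[:, idx], self.positions[idx], self.variant_ids[idx]
        )


@dataclass
class LDBlockSpec:
    """Block structure of a simulated locus.

    ``within_block_rho`` is the serial correlation of the latent Gaussian
    inside each block (one value per block, or a scalar recycled); blocks are
    mutually independent (between-block correlation fixed at zero).
    """

    block_lengths: Sequence[int]
    within_block_rho: float | Sequence[float]
    between_block_rho: float = 0.0

    def __post_init__(self) -> None:
        self.block_lengths = list(int(b) for b in self.block_lengths)
        if any(b < 1 for b in self.block_lengths):
            raise ValueError("block lengths must be positive")
        rho = self.within_block_rho
        if np.isscalar(rho):
            rho = [float(rho)] * len(self.block_lengths)
        self.within_block_rho = [float(r) for r in rho]
        if len(self.within_block_rho) != len(self.block_lengths):
            raise ValueError("one rho per block (or a scalar)")
        if any(not (0.0 <= r < 1.0) for r in self.within_block_rho):
            raise ValueError("rho must lie in [0, 1)")
        if self.between_block_rho != 0.0:
            raise ValueError("between-block correlation is fixed at 0")

    @property
    def n_variants(self) -> int:
        return sum(self.block_lengths)

    @classmethod
    def default_locus(cls, n_snps: int = 200) -> "LDBlockSpec":
        """Alternating high-LD / low-LD blocks covering ``n_snps`` variants.

        High blocks use rho = 0.99 (median adjacent dosage r^2 around 0.8),
        low blocks rho = 0.4, emulating a cis-window with a mix of strong
        haplotype blocks and poorly structured regions.
        """
        lengths: list[int] = []
        rhos: list[float] = []
        remaining, high = n_snps, True
        while remaining > 0:
            size = min(40 if high else 25, remaining)
            lengths.append(size)
            rhos.append(0.99 if high else 0.4)
            remaining -= size
            high = not high
        return cls(lengths, rhos)


@dataclass
class MafSpectrum:
    """Distribution minor allele frequencies are drawn from.

    ``uniform_range`` draws Uniform(low, high); ``rare_shifted`` draws a
    scaled Beta with its mode near maf 0.02, emulating the frequency spectrum
    of variants absent from an imputation panel. All draws are clipped to
    [floor, ceiling] = [0.01, 0.5].
    """

    kind: Literal["uniform_range", "rare_shifted"] = "uniform_range"
    low: float = 0.05
    high: float = 0.5
    beta_a: float = 1.3
    beta_b: float = 15.4
    floor: float = MAF_FLOOR
    ceiling: float = 0.5

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform_range":
            lo = max(self.low, self.floor)
            hi = min(self.high, self.ceiling)
            vals = rng.uniform(lo, hi, size=size)
        elif self.kind == "rare_shifted":
            raw = rng.beta(self.beta_a, self.beta_b, size=size)
            vals = self.floor + (self.ceiling - self.floor) * raw
        else:
            raise ValueError(f"unknown maf spectrum kind: {self.kind!r}")
        return np.clip(vals, self.floor, self.ceiling)

    def cdf(self, x: np.ndarray | float) -> np.ndarray:
        """CDF of the spectrum, used for analytic maf-bin masses."""
        from scipy import stats

        x = np.asarray(x, dtype=float)
        if self.kind == "uniform_range":
            lo = max(self.low, self.floor)
            hi = min(self.high, self.ceiling)
            return np.clip((x - lo) / (hi - lo), 0.0, 1.0)
        u = (x - self.floor) / (self.ceiling - self.floor)
        return stats.beta.cdf(np.clip(u, 0.0, 1.0), self.beta_a, self.beta_b)

    def bin_masses(self, edges: Sequence[float]) -> np.ndarray:
        edges = np.asarray(edges, dtype=float)
        masses = np.diff(self.cdf(edges))
        total = masses.sum()
        if total <= 0:
            raise ValueError("maf bins carry no spectrum mass")
        return masses / total


# ---------------------------------------------------------------------------
# two-locus construction
# ---------------------------------------------------------------------------


def _check_maf(p: float, name: str = "maf") -> float:
    p = float(p)
    if not (0.0 < p <= 0.5):
        raise ValueError(f"{name} must lie in (0, 0.5], got {p}")
    return p


def max_abs_r(p1: float, p2: float) -> float:
    """Maximum attainable |r| for two coupled minor alleles.

    With pmin = min(p1, p2) and pmax = max(p1, p2) the bound is
    sqrt(pmin*(1-pmax) / (pmax*(1-pmin))): perfect LD (r = 1) is only
    possible at equal frequencies, and a rare/common pair cannot reach
    high r^2.
    """
    p1, p2 = _check_maf(p1, "p1"), _check_maf(p2, "p2")
    pmin, pmax = min(p1, p2), max(p1, p2)
    return float(np.sqrt(pmin * (1 - pmax) / (pmax * (1 - pmin))))


def signed_r_bounds(p1: float, p2: float) -> tuple[float, float]:
    """Feasible (r_min, r_max) for the four-cell haplotype table.

    The positive bound is :func:`max_abs_r`; the negative bound is set by the
    constraint that both the minor/minor and major/major haplotype
    frequencies stay non-negative, which is more restrictive for rare
    alleles.
    """
    p1, p2 = _check_maf(p1, "p1"), _check_maf(p2, "p2")
    s = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    d_max = min(p1 * (1 - p2), (1 - p1) * p2)
    d_min = -min(p1 * p2, (1 - p1) * (1 - p2))
    return float(d_min / s), float(d_max / s)


def haplotype_frequencies(p1: float, p2: float, r: float) -> np.ndarray:
    """Four haplotype frequencies (f00, f01, f10, f11) at target correlation r.

    Order indexes (allele at locus 1, allele at locus 2) with 1 = minor.
    Raises :class:`InfeasibleLDError` naming the attainable bound when the
    target is outside the feasible region.
    """
    p1, p2 = _check_maf(p1, "p1"), _check_maf(p2, "p2")
    r = float(r)
    r_lo, r_hi = signed_r_bounds(p1, p2)
    if not (r_lo - 1e-12 <= r <= r_hi + 1e-12):
        raise InfeasibleLDError(
            f"r = {r:.4f} infeasible for maf ({p1}, {p2}); "
            f"attainable range is [{r_lo:.4f}, {r_hi:.4f}] "
            f"(|r| bound for coupled minor alleles: {max_abs_r(p1, p2):.4f})"
        )
    d = r * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    f = np.array(
        [
            (1 - p1) * (1 - p2) + d,
            (1 - p1) * p2 - d,
            p1 * (1 - p2) - d,
            p1 * p2 + d,
        ]
    )
    f = np.clip(f, 0.0, 1.0)
    return f / f.sum()


def sample_pair(
    n_samples: int,
    p1: float,
    p2: float,
    r_target: float,
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Two-SNP genotype panel with haplotype correlation ``r_target``.

    2n haplotypes are drawn from the exact four-cell haplotype distribution
    and paired at random into diploid genotypes, so expected dosage
    correlation equals the haplotype r (random mating, no inbreeding).
    """
    rng = np.random.default_rng(seed)
    freqs = haplotype_frequencies(p1, p2, r_target)
    cats = rng.choice(4, size=2 * int(n_samples), p=freqs)
    a1 = (cats >> 1) & 1  # allele at locus 1
    a2 = cats & 1
    alleles = np.stack([a1, a2], axis=1).astype(np.int8)
    panel = HaplotypePanel(
        alleles, positions=np.array([1, 2]), variant_ids=np.array(["snp1", "snp2"])
    )
    return panel.to_genotypes()


def _sample_pair_batch(
    reps: int,
    n_samples: int,
    p1: float,
    p2: float,
    r_target: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """(reps, n) dosage arrays for both loci; vectorized over replicates."""
    freqs = haplotype_frequencies(p1, p2, r_target)
    cum = np.cumsum(freqs)
    u = rng.random(size=(reps, 2 * n_samples))
    cats = np.searchsorted(cum, u).astype(np.int8)
    a1 = (cats >> 1) & 1
    a2 = cats & 1
    g1 = a1[:, 0::2] + a1[:, 1::2]
    g2 = a2[:, 0::2] + a2[:, 1::2]
    return g1.astype(np.float64), g2.astype(np.float64)


# ---------------------------------------------------------------------------
# locus-scale generator
# ---------------------------------------------------------------------------


def simulate_locus(
    n_samples: int,
    n_snps: int,
    block_spec: LDBlockSpec | None = None,
    maf_spec: MafSpectrum | None = None,
    seed: int | np.random.Generator | None = None,
    span_bp: int = WINDOW_BP,
    maf_walk_sd: float = 0.02,
) -> GenotypeMatrix:
    """Simulate a cis-window genotype panel with block-structured LD.

    Haplotypes come from a latent Gaussian with AR(1) serial correlation
    within each block; each variant's latent values are thresholded at the
    maf quantile (latent below the quantile = minor allele). Columns that
    come out monomorphic are redrawn independently at their target maf.
    Positions are uniform over ``span_bp`` (default 400 kb).

    Within a block, mafs follow a reflected random walk (step SD
    ``maf_walk_sd``) from a fresh spectrum draw at the block start: variants
    on a shared haplotype background have similar frequencies, without which
    high dosage r^2 between neighbors is unattainable (a rare/common pair
    cannot exceed a low r^2 bound regardless of the latent correlation).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    if block_spec is None:
        block_spec = LDBlockSpec.default_locus(n_snps)
    if block_spec.n_variants != n_snps:
        raise ValueError(
            f"block lengths sum to {block_spec.n_variants}, expected {n_snps}"
        )
    if maf_spec is None:
        maf_spec = MafSpectrum("uniform_range", low=0.05, high=0.5)

    from scipy import stats

    floor, ceil = maf_spec.floor, maf_spec.ceiling
    n_hap = 2 * int(n_samples)
    mafs = np.empty(n_snps)
    z = np.empty((n_hap, n_snps))
    j = 0
    for length, rho in zip(block_spec.block_lengths, block_spec.within_block_rho):
        mafs[j] = maf_spec.sample(1, rng)[0]
        z[:, j] = rng.standard_normal(n_hap)
        innov = np.sqrt(1.0 - rho * rho)
        for k in range(j + 1, j + length):
            step = rng.normal(0.0, maf_walk_sd)
            mafs[k] = _reflect(mafs[k - 1] + step, floor, ceil)
            z[:, k] = rho * z[:, k - 1] + innov * rng.standard_normal(n_hap)
        j += length
    thresholds = stats.norm.ppf(mafs)
    alleles = (z < thresholds).astype(np.int8)

    # monomorphic columns lose their LD context; redraw them independently
    for _ in range(100):
        mono = np.flatnonzero(alleles.std(axis=0) == 0)
        if mono.size == 0:
            break
        alleles[:, mono] = (
            rng.random((n_hap, mono.size)) < mafs[mono]
        ).astype(np.int8)
    else:  # pragma: no cover - probability ~ 0 for maf >= 0.01
        raise RuntimeError("could not obtain polymorphic columns")

    positions = np.sort(rng.choice(span_bp, size=n_snps, replace=False))
    ids = np.array([f"snp{k}" for k in range(n_snps)])
    panel = HaplotypePanel(alleles, positions, ids)
    return panel.to_genotypes()


def _reflect(x: float, lo: float, hi: float) -> float:
    """Reflect a scalar into [lo, hi] (one bounce is enough for small steps)."""
    if x < lo:
        x = lo + (lo - x)
    if x > hi:
        x = hi - (x - hi)
    return float(np.clip(x, lo, hi))


# ---------------------------------------------------------------------------
# LD and causal-set sampling
# ---------------------------------------------------------------------------


def ld_matrix(G: GenotypeMatrix, idx: Sequence[int] | None = None) -> np.ndarray:
    """Symmetric r^2 matrix (squared Pearson correlation of dosage columns).

    Constant columns are excluded with a warning; their rows/columns are NaN.
    """
    dos = G.dosages if idx is None else G.dosages[:, np.asarray(idx)]
    sd = dos.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{const.sum()} constant column(s) excluded from LD matrix",
            stacklevel=2,
        )
    m = dos.shape[1]
    r2 = np.full((m, m), np.nan)
    ok = ~const
    if ok.sum() >= 1:
        with np.errstate(invalid="ignore"):
            sub = np.corrcoef(dos[:, ok], rowvar=False)
        sub = np.atleast_2d(sub)
        r2[np.ix_(ok, ok)] = sub**2
        r2[np.arange(m)[ok], np.arange(m)[ok]] = 1.0
    return r2


def sample_causal_set(
    G: GenotypeMatrix,
    k: int,
    constraint: Literal["none", "pairwise_r2_min"] = "none",
    r2_min: float = 0.3,
    seed: int | np.random.Generator | None = None,
    max_tries: int = 2000,
) -> np.ndarray:
    """Draw k distinct causal variant indices, optionally within an LD clique.

    Under ``pairwise_r2_min`` every pair among the k chosen variants must
    exceed ``r2_min`` in dosage r^2; sampling retries up to ``max_tries``
    and raises rather than silently relaxing the constraint.
    """
    rng = np.random.default_rng(seed)
    if k > G.n_variants:
        raise ValueError("k exceeds the number of variants")
    if constraint == "none":
        return rng.choice(G.n_variants, size=k, replace=False)
    if constraint != "pairwise_r2_min":
        raise ValueError(f"unknown constraint {constraint!r}")
    for _ in range(max_tries):
        idx = rng.choice(G.n_variants, size=k, replace=False)
        r2 = ld_matrix(G, idx)
        off = r2[np.triu_indices(k, 1)]
        if np.all(off > r2_min):
            return idx
    raise RuntimeError(
        f"no set of {k} variants with pairwise r^2 > {r2_min} found "
        f"in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# real-data entry points
# ---------------------------------------------------------------------------


def _finalize_panel(
    dosages: np.ndarray,
    positions: np.ndarray,
    ids: np.ndarray,
    maf_floor: float,
    missing_threshold: float,
) -> GenotypeMatrix:
    dosages = np.asarray(dosages, dtype=float)
    miss = np.isnan(dosages)
    miss_rate = miss.mean(axis=0)
    if np.any(miss_rate > missing_threshold):
        bad = ids[miss_rate > missing_threshold]
        raise ValueError(
            f"{bad.size} variant(s) exceed missingness threshold "
            f"{missing_threshold}: {', '.join(map(str, bad[:5]))}"
        )
    if miss.any():
        warnings.warn(
            f"mean-imputing {int(miss.sum())} sporadic missing genotype(s)",
            stacklevel=3,
        )
        col_mean = np.nanmean(dosages, axis=0)
        dosages = np.where(miss, col_mean[None, :], dosages)

    # orient to the minor allele
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    maf = dosages.mean(axis=0) / 2.0

    keep = maf >= maf_floor
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} variant(s) below maf floor {maf_floor}",
            stacklevel=3,
        )
    if keep.sum() == 0:
        raise ValueError("no variants remain after maf filtering")
    order = np.argsort(positions[keep], kind="stable")
    return GenotypeMatrix(
        dosages[:, keep][:, order], positions[keep][order], ids[keep][order]
    )


def read_genotypes(
    path: str | Path,
    format: Literal["vcf", "dosage_tsv"] | None = None,
    maf_floor: float = MAF_FLOOR,
    missing_threshold: float = 0.05,
) -> GenotypeMatrix:
    """Load genotypes from VCF (GT or DS) or a plain dosage TSV.

    Dosages are re-oriented so the counted allele is the minor one; variants
    below the maf floor are dropped (counts logged via warnings); sporadic
    missing genotypes are mean-imputed, and variants whose missingness
    exceeds ``missing_threshold`` raise an error.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "dosage_tsv"
    if format == "vcf":
        return _read_vcf(path, maf_floor, missing_threshold)
    if format == "dosage_tsv":
        return _read_dosage_tsv(path, maf_floor, missing_threshold)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path: Path, maf_floor: float, missing_threshold: float) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, positions, ids = [], [], []
    has_ds = any(h["HeaderType"] == "FORMAT" and h["ID"] == "DS"
                 for h in vcf.header_iter())
    for variant in vcf:
        ds = variant.format("DS") if has_ds else None
        if ds is not None:
            row = np.asarray(ds, dtype=float).reshape(-1)
        else:
            row = np.empty(len(variant.genotypes))
            for i, gt in enumerate(variant.genotypes):
                a = [x for x in gt[:-1]]
                if any(x is None or x < 0 for x in a):
                    row[i] = np.nan
                elif any(x > 1 for x in a):
                    raise ValueError(
                        f"multi-allelic genotype at {variant.CHROM}:{variant.POS}"
                    )
                else:
                    row[i] = float(sum(a))
        rows.append(row)
        positions.append(variant.POS)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
    vcf.close()
    if not rows:
        raise ValueError(f"no variants in {path}")
    dosages = np.vstack(rows).T  # samples x variants
    return _finalize_panel(
        dosages, np.asarray(positions), np.asarray(ids), maf_floor, missing_threshold
    )


def _read_dosage_tsv(
    path: Path, maf_floor: float, missing_threshold: float
) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    required = {"variant_id", "position"}
    if not required.issubset(df.columns):
        raise ValueError(f"dosage TSV must carry columns {sorted(required)}")
    sample_cols = [c for c in df.columns if c not in ("variant_id", "position")]
    dosages = df[sample_cols].to_numpy(dtype=float).T
    return _finalize_panel(
        dosages,
        df["position"].to_numpy(),
        df["variant_id"].to_numpy(),
        maf_floor,
        missing_threshold,
    )


def write_dosage_tsv(G: GenotypeMatrix, path: str | Path, sample_ids=None) -> None:
    """Write variants x samples dosage TSV (the read_genotypes round-trip)."""
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(G.n_samples)]
    df = pd.DataFrame(G.dosages.T, columns=list(sample_ids))
    df.insert(0, "position", G.positions)
    df.insert(0, "variant_id", G.variant_ids)
    df.to_csv(path, sep="\t", index=False)
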
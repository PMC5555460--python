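"""Causal effect assignment and expression-trait simulation.

Effect sizes are parameterized by variance explained (VE) relative to unit
environmental noise: a variant with minor allele frequency p and allelic
effect beta (in trait standard-deviation units, sdu) explains
VE = 2 p (1-p) beta^2, so beta = sqrt(VE / (2 p (1-p))). Traits are simulated
additively on dosage,

    y = sum_i sign_i * beta_i * dosage_i + N(0, 1),

with no dominance and no re-standardization after adding genetic effects.

Sign scenarios ("4:0", "3:1", "2:2", ...) fix how many minor alleles push the
trait up versus down; which causal sites carry the negative signs is chosen
uniformly at random.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "CausalConfig",
    "TraitVector",
    "beta_from_ve",
    "ve_from_beta",
    "parse_scenario",
    "assign_effects",
    "simulate_trait",
]


def beta_from_ve(ve, p):
    """Allelic effect (sdu) explaining variance fraction ``ve`` at maf ``p``.

    beta = sqrt(ve / (2 p (1-p))), always positive; the sign of the minor
    allele's effect is applied separately.
    """
    ve = np.asarray(ve, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(ve < 0) or np.any(ve >= 1):
        raise ValueError("ve must lie in [0, 1)")
    if np.any(p <= 0) or np.any(p > 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    return np.sqrt(ve / (2.0 * p * (1.0 - p)))[()]


def ve_from_beta(beta, p):
    """Variance explained 2 p (1-p) beta^2 for effect ``beta`` at maf ``p``."""
    beta = np.asarray(beta, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    return (2.0 * p * (1.0 - p) * beta**2)[()]


def parse_scenario(scenario: str) -> tuple[int, int]:
    """Parse "pos:neg" sign-scenario labels like "4:0" or "2:2"."""
    m = re.fullmatch(r"(\d+):(\d+)", scenario.strip())
    if not m:
        raise ValueError(f"scenario must look like '4:0', got {scenario!r}")
    return int(m.group(1)), int(m.group(2))


@dataclass
class CausalConfig:
    """The simulated truth: which variants are causal and with what effect."""

    causal_idx: np.ndarray
    ve: np.ndarray
    sign: np.ndarray
    beta: np.ndarray
    maf: np.ndarray
    scenario: str

    def __post_init__(self) -> None:
        self.causal_idx = np.asarray(self.causal_idx, dtype=int)
        self.ve = np.asarray(self.ve, dtype=float)
        self.sign = np.asarray(self.sign, dtype=int)
        self.beta = np.asarray(self.beta, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        k = len(self.causal_idx)
        if not (len(self.ve) == len(self.sign) == len(self.beta) == len(self.maf) == k):
            raise ValueError("per-site arrays must share the causal count")
        if not np.isin(self.sign, (-1, 1)).all():
            raise ValueError("signs must be +/-1")
        pos, neg = parse_scenario(self.scenario)
        if pos + neg != k:
            raise ValueError(
                f"scenario {self.scenario!r} implies {pos + neg} sites, have {k}"
            )
        if (self.sign == 1).sum() != pos or (self.sign == -1).sum() != neg:
            raise ValueError("sign vector does not match the scenario counts")
        if not np.allclose(self.beta, beta_from_ve(self.ve, self.maf)):
            raise ValueError("beta inconsistent with ve and maf")

    @property
    def signed_beta(self) -> np.ndarray:
        return self.sign * self.beta

    @property
    def k(self) -> int:
        return len(self.causal_idx)

    def to_json(self, path: str | Path) -> None:
        payload = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "CausalConfig":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


@dataclass
class TraitVector:
    """Simulated expression trait on the sdu scale plus its seed record."""

    y: np.ndarray
    seed: object = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if not np.isfinite(self.y).all():
            raise ValueError("trait contains non-finite values")


def assign_effects(
    G: GenotypeMatrix,
    causal_idx: Sequence[int],
    ve_range: tuple[float, float] | Sequence[float] = (0.02, 0.10),
    scenario: str = "4:0",
    seed: int | np.random.Generator | None = None,
    ve_fixed: Sequence[float] | None = None,
) -> CausalConfig:
    """Draw per-site VE and signs, returning the simulated truth.

    VE is Uniform(ve_range) independently per site by default; ``ve_fixed``
    instead assigns an explicit per-site VE list (the fixed-grid variant of
    the two-SNP study, e.g. VE in {0.02, ..., 0.30}). Which sites receive
    negative signs under the scenario is uniform over site subsets.
    """
    rng = np.random.default_rng(seed)
    causal_idx = np.asarray(causal_idx, dtype=int)
    k = len(causal_idx)
    pos, neg = parse_scenario(scenario)
    if pos + neg != k:
        raise ValueError(f"scenario {scenario!r} needs {pos + neg} sites, got {k}")
    if ve_fixed is not None:
        ve = np.asarray(ve_fixed, dtype=float)
        if len(ve) != k:
            raise ValueError("ve_fixed length must match causal count")
    else:
        lo, hi = ve_range
        ve = rng.uniform(lo, hi, size=k)
    sign = np.ones(k, dtype=int)
    sign[rng.choice(k, size=neg, replace=False)] = -1
    maf = G.maf[causal_idx]
    beta = beta_from_ve(ve, maf)
    return CausalConfig(causal_idx, ve, sign, beta, maf, scenario)


def simulate_trait(
    G: GenotypeMatrix,
    config: CausalConfig,
    seed: int | np.random.Generator | None = None,
) -> TraitVector:
    """y = sum_i sign_i beta_i dosage_i + N(0,1), uncentered genetic term."""
    if np.any(config.causal_idx >= G.n_variants) or np.any(config.causal_idx < 0):
        raise ValueError("causal indices out of range for this panel")
    rng = np.random.default_rng(seed)
    genetic = G.dosages[:, config.causal_idx] @ config.signed_beta
    y = genetic + rng.standard_normal(G.n_samples)
    return TraitVector(y, seed=seed if not isinstance(seed, np.random.Generator) else None)
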
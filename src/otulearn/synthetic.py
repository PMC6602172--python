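"""Synthetic community tables with planted function-driving taxa.

The generator emulates the statistical shape of rarefied 16S OTU tables
from replicated microcosm experiments: sparse non-negative counts with every
row summing to a fixed sequencing depth, replicate groups of correlated
samples (microcosms inoculated from the same source community), and a
continuous target driven by a small planted set of positive- and
negative-effect taxa plus Gaussian noise.

Counts arise from log-normal latent abundances pushed through a softmax and
multinomially sampled at the fixed depth; the spread of the latent taxon
means is calibrated so that the expected fraction of zero cells matches the
requested ``sparsity``. The target is built from *relative* abundances of
the signal taxa (standardized across samples) so that sequencing depth never
leaks into the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_io import OtuTable, TargetVector

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "realized_effect_report"]


@dataclass
class SyntheticSpec:
    """Study-shaped generation parameters.

    Defaults mirror a replicated litter-decomposition microcosm design:
    groups of 3 replicate samples, rows rarefied to 1023 reads, roughly half
    of the count cells zero, and a planted signal of 20 taxa with equal
    numbers of positive and negative unit effects.
    """

    n_groups: int = 100
    replicates_per_group: int = 3
    n_taxa: int = 300
    n_signal_taxa: int = 20
    effect_sizes: np.ndarray | None = None  # default: alternating +1/-1
    depth: int = 1023
    within_group_correlation: float = 0.5
    noise_sd: float = 0.3
    sparsity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_signal_taxa > self.n_taxa:
            raise ValueError("n_signal_taxa exceeds n_taxa")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.within_group_correlation < 1:
            raise ValueError("within_group_correlation must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must be in [0, 1)")
        if self.effect_sizes is None:
            signs = np.where(np.arange(self.n_signal_taxa) % 2 == 0, 1.0, -1.0)
            self.effect_sizes = signs
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if len(self.effect_sizes) != self.n_signal_taxa:
            raise ValueError("effect_sizes length must equal n_signal_taxa")


@dataclass
class GroundTruth:
    """Planted signal taxa and their signed effects on the target."""

    taxon_ids: list[str]
    effects: np.ndarray

    @property
    def signs(self) -> np.ndarray:
        return np.sign(self.effects)


def _softmax_rows(L: np.ndarray) -> np.ndarray:
    L = L - L.max(axis=1, keepdims=True)
    E = np.exp(L)
    return E / E.sum(axis=1, keepdims=True)


def _calibrate_spread(z: np.ndarray, depth: int, sparsity: float) -> float:
    """Latent-mean spread sigma so E[fraction of zero cells] ~= sparsity.

    Uses the base composition only (per-sample latent noise adds a little
    extra sparsity on top); zero probability of a taxon with share p at
    fixed depth is (1 - p)^depth.
    """

    def zero_frac(sigma: float) -> float:
        p = _softmax_rows((sigma * z)[None, :])[0]
        return float(np.mean((1.0 - p) ** depth))

    lo, hi = 1e-6, 40.0
    if sparsity <= zero_frac(lo):
        raise ValueError(
            f"requested sparsity {sparsity} below the minimum "
            f"{zero_frac(lo):.3f} achievable at this depth and taxon count"
        )
    if sparsity >= zero_frac(hi):
        raise ValueError(f"requested sparsity {sparsity} is too high")
    return float(brentq(lambda s: zero_frac(s) - sparsity, lo, hi))


def generate(spec: SyntheticSpec) -> tuple[OtuTable, TargetVector, GroundTruth]:
    """Draw a (table, target, ground truth) triple from the spec.

    Per replicate group a latent log-abundance profile is drawn; each
    replicate perturbs it with a variance split controlled by
    ``within_group_correlation`` (rho), so replicate latents correlate at
    rho. Rows are multinomial at ``depth``. Signal taxa are chosen among the
    upper half of baseline abundance so their planted effects are realized
    (an effectively absent taxon cannot carry signal); a generation whose
    signal taxa are nearly absent anyway raises.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_groups * spec.replicates_per_group
    m = spec.n_taxa

    z = rng.standard_normal(m)  # taxon baseline shape
    sigma = _calibrate_spread(z, spec.depth, spec.sparsity)
    base = sigma * z

    rho = spec.within_group_correlation
    latent_sd = 1.0  # overall sample-to-sample latent variation
    group_part = rng.standard_normal((spec.n_groups, m))
    rep_part = rng.standard_normal((n, m))
    group_of = np.repeat(np.arange(spec.n_groups), spec.replicates_per_group)
    latent = base[None, :] + latent_sd * (
        np.sqrt(rho) * group_part[group_of] + np.sqrt(1 - rho) * rep_part
    )
    P = _softmax_rows(latent)
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(spec.depth, P[i])

    taxon_ids = [f"otu{j:04d}" for j in range(m)]
    group_ids = [f"g{g:03d}" for g in group_of]
    sample_ids = [
        f"g{g:03d}_r{i % spec.replicates_per_group}" for i, g in enumerate(group_of)
    ]

    # plant the signal among reasonably abundant taxa
    upper = np.argsort(base)[m // 2 :]
    signal_idx = np.sort(rng.choice(upper, size=spec.n_signal_taxa, replace=False))
    rel = counts[:, signal_idx] / spec.depth
    prevalence = (counts[:, signal_idx] > 0).mean(axis=0)
    if np.any(prevalence < 0.05) or np.any(rel.std(axis=0) == 0):
        raise ValueError(
            "infeasible sparsity/signal combination: a planted taxon is "
            "effectively absent"
        )
    zscores = (rel - rel.mean(axis=0)) / rel.std(axis=0)
    y = zscores @ spec.effect_sizes + spec.noise_sd * rng.standard_normal(n)

    table = OtuTable(
        sample_ids=sample_ids,
        taxon_ids=taxon_ids,
        counts=counts,
        group_ids=group_ids,
    )
    truth = GroundTruth(
        taxon_ids=[taxon_ids[j] for j in signal_idx],
        effects=spec.effect_sizes.copy(),
    )
    return table, TargetVector(y), truth


def realized_effect_report(
    table: OtuTable, target: TargetVector, truth: GroundTruth
) -> pd.DataFrame:
    """Per-signal-taxon realized correlation between relative abundance and
    the target, with a flag for sign agreement with the planted effect."""
    rel = table.relative_abundance()
    col = {t: j for j, t in enumerate(table.taxon_ids)}
    y = target.values
    yc = y - y.mean()
    rows = []
    for t, e in zip(truth.taxon_ids, truth.effects):
        x = rel[:, col[t]]
        xc = x - x.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        r = float((xc * yc).sum() / denom) if denom > 0 else 0.0
        rows.append(
            {
                "taxon_id": t,
                "effect": float(e),
                "realized_r": r,
                "sign_match": bool(np.sign(r) == np.sign(e)) if e != 0 else True,
            }
        )
    return pd.DataFrame(rows)
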
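"""Synthetic three-fraction Repli-seq with planted replication-timing shifts.

A latent per-bin replication-timing score s in [-3, 3] (piecewise-constant
early/late domains) maps to early/mid/late fraction weights through a
smooth softmax, (w_E, w_M, w_L) ∝ (e^{βs}, 1, e^{-βs}) with β = 1.2, so the
ideal log2(E/L) is 2βs/ln(2).  Per-bin counts are Poisson with per-fraction
totals at the configured sequencing depth.  Condition B shifts the latent
score inside planted blocks by exactly Δlog2·ln(2)/(2β), so the planted
Δlog2(E/L) is exact in expectation.  A repeat annotation places an
"MT2-like" class at elevated density inside earlier-shifting blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..repliseq import FRACTIONS, RTProfile, bin_and_normalize

__all__ = ["ShiftBlock", "RTScenario", "simulate_repliseq"]

LN2 = np.log(2.0)


@dataclass(frozen=True)
class ShiftBlock:
    chrom: str
    start: int
    end: int
    direction: str  # "earlier" | "later"
    delta_log2: float = 1.5


@dataclass
class RTScenario:
    """Study conditions for the synthetic Repli-seq experiment.

    Defaults: a 2 x 50 Mb genome at 100-kb bins, three million reads per
    fraction, one 2-Mb earlier-shifting and one 2-Mb later-shifting block
    (4% of the genome), blocks spanning several smoothing windows, and an
    MT2-like repeat class at 5x density inside the earlier block over a
    0.5% genome-wide background.
    """

    n_chromosomes: int = 2
    chromosome_length_bp: int = 50_000_000
    bin_size_bp: int = 100_000
    beta: float = 1.2
    sequencing_depth: int = 3_000_000
    domain_length_bins: tuple[int, int] = (20, 60)
    domain_level_range: tuple[float, float] = (0.3, 1.0)
    shifted_blocks: list[ShiftBlock] = field(default_factory=lambda: [
        ShiftBlock("chr1", 10_000_000, 12_000_000, "earlier", 1.5),
        ShiftBlock("chr2", 30_000_000, 32_000_000, "later", 1.5),
    ])
    repeat_length_bp: int = 500
    repeat_background_cov: float = 0.005
    repeat_inside_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.sequencing_depth <= 0:
            raise ValueError("depth must be positive")
        ivs = sorted((b.chrom, b.start, b.end) for b in self.shifted_blocks)
        for (c1, s1, e1), (c2, s2, e2) in zip(ivs, ivs[1:]):
            if c1 == c2 and s2 < e1:
                raise ValueError("shifted blocks must be disjoint")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chromosome_length_bp for i in range(self.n_chromosomes)
        }

    def earlier_intervals(self) -> list[ShiftBlock]:
        return [b for b in self.shifted_blocks if b.direction == "earlier"]


def _latent_profile(scenario: RTScenario, rng) -> pd.DataFrame:
    """Piecewise-constant latent score per bin, alternating early/late."""
    rows = []
    for chrom, size in scenario.chrom_sizes.items():
        n_bins = size // scenario.bin_size_bp + (size % scenario.bin_size_bp > 0)
        s = np.empty(n_bins)
        pos = 0
        sign = 1 if rng.random() < 0.5 else -1
        while pos < n_bins:
            length = rng.integers(*scenario.domain_length_bins)
            level = rng.uniform(*scenario.domain_level_range)
            s[pos : pos + length] = sign * level
            sign = -sign
            pos += length
        starts = np.arange(n_bins, dtype=np.int64) * scenario.bin_size_bp
        ends = np.minimum(starts + scenario.bin_size_bp, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends, "s": s}))
    return pd.concat(rows, ignore_index=True)


def _apply_shifts(latent: pd.DataFrame, scenario: RTScenario) -> tuple[pd.DataFrame, np.ndarray]:
    """Latent score for condition B plus the per-bin true shift direction."""
    out = latent.copy()
    direction = np.array([""] * len(out), dtype=object)
    for b in scenario.shifted_blocks:
        sel = (
            (out["chrom"] == b.chrom)
            & (out["start"] >= b.start)
            & (out["end"] <= b.end)
        ).to_numpy()
        ds = b.delta_log2 * LN2 / (2 * scenario.beta)
        out.loc[sel, "s"] = out.loc[sel, "s"] + (ds if b.direction == "earlier" else -ds)
        direction[sel] = b.direction
    return out, direction


def _counts_from_latent(latent: pd.DataFrame, scenario: RTScenario, rng) -> pd.DataFrame:
    s = latent["s"].to_numpy()
    logits = np.stack([scenario.beta * s, np.zeros_like(s), -scenario.beta * s])
    w = np.exp(logits - logits.max(axis=0))
    w /= w.sum(axis=0)
    df = latent[["chrom", "start", "end"]].copy()
    for k, frac in enumerate(FRACTIONS):
        expected = scenario.sequencing_depth * w[k] / w[k].sum()
        df[frac] = rng.poisson(expected)
    return df


def _repeat_annotation(scenario: RTScenario, rng) -> pd.DataFrame:
    """MT2-like repeats enriched inside earlier blocks plus a uniform
    LINE-like background class."""
    rows = []
    earlier = scenario.earlier_intervals()
    rl = scenario.repeat_length_bp

    def place(chrom, lo, hi, coverage, cls):
        span = hi - lo
        n = int(round(coverage * span / rl))
        if n <= 0:
            return
        starts = np.sort(rng.integers(lo, max(lo + 1, hi - rl), size=n))
        for s in starts:
            rows.append({"chrom": chrom, "start": int(s), "end": int(s + rl), "class": cls})

    for chrom, size in scenario.chrom_sizes.items():
        blocks = sorted((b.start, b.end) for b in earlier if b.chrom == chrom)
        pos = 0
        for s, e in blocks:
            place(chrom, pos, s, scenario.repeat_background_cov, "MT2-like")
            place(
                chrom, s, e,
                scenario.repeat_background_cov * scenario.repeat_inside_factor,
                "MT2-like",
            )
            pos = e
        place(chrom, pos, size, scenario.repeat_background_cov, "MT2-like")
        place(chrom, 0, size, 0.03, "LINE-like")
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)


def simulate_repliseq(
    scenario: RTScenario | None = None,
    condition_shifts: bool = True,
    seed: int = 0,
) -> tuple[RTProfile, RTProfile, dict]:
    """Simulate two Repli-seq conditions with known ground truth.

    Returns ``(profile_a, profile_b, truth)`` where ``truth`` carries the
    per-bin true log2(E/L) of both conditions and shift direction
    (``truth["bins"]``), the planted blocks, the repeat annotation and the
    chromosome sizes.  Bit-reproducible given the seed.
    """
    scenario = scenario or RTScenario()
    rng = np.random.default_rng(seed)
    latent_a = _latent_profile(scenario, rng)
    if condition_shifts:
        latent_b, direction = _apply_shifts(latent_a, scenario)
    else:
        latent_b, direction = latent_a.copy(), np.array([""] * len(latent_a), dtype=object)
    counts_a = _counts_from_latent(latent_a, scenario, rng)
    counts_b = _counts_from_latent(latent_b, scenario, rng)
    prof_a = bin_and_normalize(counts_a, scenario.bin_size_bp, condition="A")
    prof_b = bin_and_normalize(counts_b, scenario.bin_size_bp, condition="B")
    truth_bins = latent_a[["chrom", "start", "end"]].copy()
    truth_bins["log2_el_a"] = 2 * scenario.beta * latent_a["s"] / LN2
    truth_bins["log2_el_b"] = 2 * scenario.beta * latent_b["s"] / LN2
    truth_bins["shift"] = direction
    truth = {
        "bins": truth_bins,
        "blocks": list(scenario.shifted_blocks),
        "repeats": _repeat_annotation(scenario, rng),
        "chrom_sizes": scenario.chrom_sizes,
    }
    return prof_a, prof_b, truth
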
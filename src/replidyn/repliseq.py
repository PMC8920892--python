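"""Replication-timing (Repli-seq) analysis.

Reads from early/mid/late S-phase fractions are counted over fixed genomic
bins (100 kb default), normalized to reads per million per fraction, and the
early/late ratio log2(E/L) is smoothed per chromosome with fixed-span
tricube local-linear regression (loess, degree 1).  Downstream calls:

* differential-RT regions between two conditions at a fold cutoff
  (2-fold, or 1.5-fold for a transitional S-phase comparison);
* early/late replication domains by circular binary segmentation with
  permutation-based split acceptance;
* per-gene stage classification (early/mid/late = argmax read density over
  the gene body; ties break toward the earlier stage);
* repeat-class enrichment inside differential regions with an empirical
  permutation p-value.

Coordinates are 0-based half-open everywhere (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import merge_intervals, overlap_bp, total_bp

__all__ = [
    "RTProfile",
    "DifferentialRTRegion",
    "RTDomain",
    "bin_and_normalize",
    "smooth_log2el",
    "differential_rt",
    "segment_domains",
    "classify_genes",
    "repeat_enrichment",
    "genome_fraction",
]

FRACTIONS = ("early", "mid", "late")


@dataclass
class RTProfile:
    """Binned three-fraction Repli-seq signal for one condition.

    ``bins`` holds sorted, non-overlapping rows (chrom, start, end) with raw
    counts per fraction, RPM-normalized densities and (after smoothing) the
    per-bin log2(E/L).  log2_el is defined only where early+late counts > 0.
    """

    bins: pd.DataFrame
    bin_size: int
    condition: str = ""

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", *FRACTIONS}
        missing = required - set(self.bins.columns)
        if missing:
            raise ValueError(f"profile missing columns: {sorted(missing)}")
        for chrom, sub in self.bins.groupby("chrom", sort=False):
            if np.any(np.diff(sub["start"].to_numpy()) <= 0):
                raise ValueError(f"bins not sorted on {chrom}")
            if np.any(sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]):
                raise ValueError(f"overlapping bins on {chrom}")

    def same_grid(self, other: "RTProfile") -> bool:
        a = self.bins[["chrom", "start", "end"]].reset_index(drop=True)
        b = other.bins[["chrom", "start", "end"]].reset_index(drop=True)
        return a.equals(b)


@dataclass
class DifferentialRTRegion:
    chrom: str
    start: int
    end: int
    direction: str  # "earlier" | "later" (in condition b relative to a)
    delta_log2_el: float
    member_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def size_bp(self) -> int:
        return self.end - self.start


@dataclass
class RTDomain:
    chrom: str
    start: int
    end: int
    state: str  # "early" | "late"
    mean_log2_el: float

    @property
    def size_bp(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# binning


def bin_and_normalize(
    data: pd.DataFrame,
    bin_size: int = 100_000,
    chrom_sizes: dict[str, int] | None = None,
    condition: str = "",
) -> RTProfile:
    """Count reads over fixed genomic bins and normalize to RPM per fraction.

    ``data`` is either a fragment table (chrom, start, end, fraction) —
    fragments are assigned to the bin containing their midpoint — or an
    already-binned count table (chrom, start, end, early, mid, late).
    A chromosome length that is not a multiple of the bin size leaves a
    truncated final bin (with a warning), never a silently dropped one.
    """
    if "fraction" in data.columns:
        counts = _bin_fragments(data, bin_size, chrom_sizes)
    else:
        counts = data.copy()
        for chrom, sub in counts.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if np.any(s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]):
                raise ValueError(f"overlapping input bins on {chrom}")
        counts = counts.sort_values(["chrom", "start"]).reset_index(drop=True)
    for frac in FRACTIONS:
        tot = counts[frac].sum()
        counts[f"{frac}_norm"] = counts[frac] * 1e6 / tot if tot > 0 else np.nan
    covered = counts[list(FRACTIONS)].sum(axis=1) > 0
    counts["missing"] = ~covered
    for frac in FRACTIONS:
        counts.loc[~covered, f"{frac}_norm"] = np.nan
    return RTProfile(bins=counts, bin_size=bin_size, condition=condition)


def _bin_fragments(frags: pd.DataFrame, bin_size: int, chrom_sizes):
    bad = set(frags["fraction"]) - set(FRACTIONS)
    if bad:
        raise ValueError(f"unknown fraction labels: {sorted(bad)}")
    sizes = dict(chrom_sizes or {})
    for chrom, sub in frags.groupby("chrom", sort=False):
        sizes.setdefault(chrom, int(sub["end"].max()))
    rows = []
    for chrom in sorted(sizes):
        L = sizes[chrom]
        n_bins = int(np.ceil(L / bin_size))
        if L % bin_size != 0:
            warnings.warn(
                f"{chrom}: length {L} not a multiple of {bin_size}; last bin truncated"
            )
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = np.minimum(starts + bin_size, L)
        table = {f: np.zeros(n_bins, dtype=np.int64) for f in FRACTIONS}
        sub = frags[frags["chrom"] == chrom]
        mid = ((sub["start"].to_numpy() + sub["end"].to_numpy()) // 2).astype(np.int64)
        idx = np.clip(mid // bin_size, 0, n_bins - 1)
        for f in FRACTIONS:
            sel = (sub["fraction"] == f).to_numpy()
            np.add.at(table[f], idx[sel], 1)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends, **table}
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# loess smoothing


def _loess_fixed_span(x: np.ndarray, y: np.ndarray, half_span: float) -> np.ndarray:
    """Degree-1 local regression with tricube weights over a fixed window."""
    out = np.empty_like(y)
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        sel = d < half_span
        if sel.sum() < 2:
            out[i] = y[i]
            continue
        u = d[sel] / half_span
        w = (1 - u**3) ** 3
        xs, ys = x[sel] - x0, y[sel]
        sw = w.sum()
        mx, my = (w * xs).sum() / sw, (w * ys).sum() / sw
        sxx = (w * (xs - mx) ** 2).sum()
        if sxx <= 0:
            out[i] = my
        else:
            slope = (w * (xs - mx) * (ys - my)).sum() / sxx
            out[i] = my + slope * (0.0 - mx)
    return out


def smooth_log2el(
    profile: RTProfile,
    span_bp: float = 500_000,
    pseudocount: float = 0.5,
    min_bins: int = 5,
) -> RTProfile:
    """Compute and loess-smooth log2(E/L) per chromosome.

    log2_el_raw = log2((early_norm + c) / (late_norm + c)); smoothing uses
    tricube local-linear regression over ``span_bp``.  Missing bins are
    interpolated only inside covered stretches; chromosomes with fewer than
    ``min_bins`` covered bins are excluded with a warning.
    """
    df = profile.bins.copy()
    raw = np.log2(
        (df["early_norm"] + pseudocount) / (df["late_norm"] + pseudocount)
    )
    covered = (df["early"] + df["late"]) > 0
    raw = raw.where(covered & ~df["missing"], np.nan)
    df["log2_el_raw"] = raw
    smoothed = np.full(len(df), np.nan)
    for chrom, sub in df.groupby("chrom", sort=False):
        valid = sub["log2_el_raw"].notna().to_numpy()
        if valid.sum() < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} covered bins; excluded")
            continue
        centers = (0.5 * (sub["start"] + sub["end"])).to_numpy(dtype=float)
        y = sub["log2_el_raw"].to_numpy(dtype=float)
        fit = _loess_fixed_span(centers[valid], y[valid], half_span=span_bp / 2.0)
        vals = np.full(len(sub), np.nan)
        vals[valid] = fit
        # interpolate missing bins strictly inside the covered span
        inner = ~valid
        lo, hi = np.argmax(valid), len(valid) - 1 - np.argmax(valid[::-1])
        inner[: lo + 1] = False
        inner[hi:] = False
        if inner.any():
            vals[inner] = np.interp(centers[inner], centers[valid], fit)
        smoothed[sub.index.to_numpy()] = vals
    df["log2_el"] = smoothed
    return RTProfile(bins=df, bin_size=profile.bin_size, condition=profile.condition)


# ---------------------------------------------------------------------------
# differential RT


def differential_rt(
    a: RTProfile, b: RTProfile, fold: float = 2.0, max_gap_bins: int = 1
) -> list[DifferentialRTRegion]:
    """Bins shifting replication timing in condition b relative to a.

    delta = log2_el_b - log2_el_a per bin; bins at or beyond ±log2(fold)
    (inclusive boundary) are called earlier/later and merged into maximal
    runs, bridging up to ``max_gap_bins`` missing bins.
    """
    if not a.same_grid(b):
        raise ValueError("profiles must share an identical bin grid")
    thr = np.log2(fold)
    delta = b.bins["log2_el"].to_numpy() - a.bins["log2_el"].to_numpy()
    call = np.zeros(len(delta), dtype=int)  # +1 earlier, -1 later
    with np.errstate(invalid="ignore"):
        call[delta >= thr] = 1
        call[delta <= -thr] = -1
    missing = ~np.isfinite(delta)
    regions: list[DifferentialRTRegion] = []
    df = a.bins
    for chrom, sub in df.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        i = 0
        while i < len(idx):
            c = call[idx[i]]
            if c == 0:
                i += 1
                continue
            members = [i]
            j = i + 1
            while j < len(idx):
                if call[idx[j]] == c:
                    members.append(j)
                    j += 1
                elif missing[idx[j]]:
                    # bridge a short missing gap if the same call resumes
                    g = j
                    while g < len(idx) and missing[idx[g]] and g - j < max_gap_bins:
                        g += 1
                    if g < len(idx) and call[idx[g]] == c and g - j <= max_gap_bins:
                        members.extend(range(j, g + 1))
                        j = g + 1
                    else:
                        break
                else:
                    break
            mem_idx = idx[np.asarray(members)]
            non_missing = mem_idx[~missing[mem_idx]]
            regions.append(
                DifferentialRTRegion(
                    chrom=chrom,
                    start=int(df.loc[mem_idx[0], "start"]),
                    end=int(df.loc[mem_idx[-1], "end"]),
                    direction="earlier" if c > 0 else "later",
                    delta_log2_el=float(np.nanmean(delta[non_missing])),
                    member_bins=mem_idx,
                )
            )
            i = j
    return regions


def genome_fraction(regions: list[DifferentialRTRegion], profile: RTProfile) -> float:
    """Fraction of the binned genome covered by differential-RT regions."""
    total = int((profile.bins["end"] - profile.bins["start"]).sum())
    called = sum(r.size_bp for r in regions)
    return called / total if total else 0.0


# ---------------------------------------------------------------------------
# circular binary segmentation


def _max_circular_stat(x: np.ndarray, min_width: int):
    """Maximal |t| over all arcs x[i:j] vs. their complement."""
    n = len(x)
    if n < 2 * min_width:
        return None
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    sd = x.std()
    if sd == 0:
        return None
    i_idx, j_idx = np.triu_indices(n + 1, k=min_width)
    k = j_idx - i_idx
    keep = (k >= min_width) & (n - k >= min_width)
    i_idx, j_idx, k = i_idx[keep], j_idx[keep], k[keep]
    if len(k) == 0:
        return None
    arc = s[j_idx] - s[i_idx]
    mean_arc = arc / k
    mean_comp = (total - arc) / (n - k)
    t = np.abs(mean_arc - mean_comp) / (sd * np.sqrt(1.0 / k + 1.0 / (n - k)))
    best = int(np.argmax(t))
    return int(i_idx[best]), int(j_idx[best]), float(t[best])


def _split_significant(x, stat, alpha, n_perm, min_width, rng):
    """Permutation test of the maximal arc statistic with early stopping."""
    allowed = int(np.floor(alpha * n_perm))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(x)
        res = _max_circular_stat(perm, min_width)
        if res is not None and res[2] >= stat:
            exceed += 1
            if exceed > allowed:
                return False
    return True


def segment_domains(
    profile: RTProfile,
    alpha: float = 0.01,
    min_width: int = 2,
    n_perm: int = 200,
    seed: int = 0,
) -> list[RTDomain]:
    """Early/late replication domains by circular binary segmentation.

    Recursively finds the arc maximizing the mean-shift t statistic,
    accepts the split when it survives a permutation test at level
    ``alpha``, and labels the resulting segments early (mean log2_el > 0)
    or late; adjacent same-state segments merge into domains.
    """
    rng = np.random.default_rng(seed)
    df = profile.bins
    if "log2_el" not in df.columns:
        raise ValueError("profile must be smoothed first (smooth_log2el)")
    domains: list[RTDomain] = []
    for chrom, sub in df.groupby("chrom", sort=False):
        y = sub["log2_el"].to_numpy(dtype=float)
        valid = np.isfinite(y)
        # segment each covered stretch independently
        start_idx = None
        stretches = []
        for i, v in enumerate(valid):
            if v and start_idx is None:
                start_idx = i
            elif not v and start_idx is not None:
                stretches.append((start_idx, i))
                start_idx = None
        if start_idx is not None:
            stretches.append((start_idx, len(y)))
        for lo, hi in stretches:
            x = y[lo:hi]
            cuts = sorted(_cbs_recurse(x, alpha, min_width, n_perm, rng))
            bounds = [0] + cuts + [len(x)]
            for a, b in zip(bounds, bounds[1:]):
                mean = float(x[a:b].mean())
                domains.append(
                    RTDomain(
                        chrom=chrom,
                        start=int(sub["start"].iloc[lo + a]),
                        end=int(sub["end"].iloc[lo + b - 1]),
                        state="early" if mean > 0 else "late",
                        mean_log2_el=mean,
                    )
                )
    return _merge_domains(domains)


def _cbs_recurse(x, alpha, min_width, n_perm, rng) -> list[int]:
    res = _max_circular_stat(x, min_width)
    if res is None:
        return []
    i, j, stat = res
    if not _split_significant(x, stat, alpha, n_perm, min_width, rng):
        return []
    cuts = []
    if i > 0:
        cuts.append(i)
    if j < len(x):
        cuts.append(j)
    pieces = [(0, i), (i, j), (j, len(x))]
    out = list(cuts)
    for a, b in pieces:
        if b - a >= 2 * min_width:
            out.extend(a + c for c in _cbs_recurse(x[a:b], alpha, min_width, n_perm, rng))
    return sorted(set(out))


def _merge_domains(domains: list[RTDomain]) -> list[RTDomain]:
    out: list[RTDomain] = []
    for d in domains:
        if out and out[-1].chrom == d.chrom and out[-1].state == d.state and out[-1].end == d.start:
            prev = out[-1]
            w1, w2 = prev.size_bp, d.size_bp
            out[-1] = RTDomain(
                prev.chrom,
                prev.start,
                d.end,
                prev.state,
                (prev.mean_log2_el * w1 + d.mean_log2_el * w2) / (w1 + w2),
            )
        else:
            out.append(d)
    return out


def domain_size_test(sizes_a, sizes_b) -> dict[str, float]:
    """Two-sided Student's t-test comparing domain-size distributions."""
    res = stats.ttest_ind(np.asarray(sizes_a, float), np.asarray(sizes_b, float))
    return {"statistic": float(res.statistic), "pvalue": float(res.pvalue)}


# ---------------------------------------------------------------------------
# gene classification


def classify_genes(
    profile: RTProfile,
    genes: pd.DataFrame,
    other: RTProfile | None = None,
    de_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Classify genes as early/mid/late replicating (argmax read density
    over the gene body; ties break toward the earlier stage).

    With a second condition, each gene's shift is ``earlier`` when the stage
    index decreases in ``other`` (late→mid, late→early, mid→early),
    ``later`` when it increases, else ``none``.  A DE table (gene, class in
    {up, down, unchanged}) is joined when given.  The returned frame carries
    the E/L-vs-stage consistency rate in ``attrs["el_consistency"]``.
    """
    calls = _gene_densities(profile, genes)
    if other is not None:
        calls_b = _gene_densities(other, genes)
        order = {"early": 0, "mid": 1, "late": 2}
        shifts = []
        for sa, sb in zip(calls["stage"], calls_b["stage"]):
            if pd.isna(sa) or pd.isna(sb):
                shifts.append(np.nan)
            elif order[sb] < order[sa]:
                shifts.append("earlier")
            elif order[sb] > order[sa]:
                shifts.append("later")
            else:
                shifts.append("none")
        calls["stage_b"] = calls_b["stage"]
        calls["shift"] = shifts
    if de_table is not None:
        calls = calls.merge(
            de_table.rename(columns={"class": "expression_change"}),
            on="gene",
            how="left",
        )
    unamb = calls[calls["stage"].isin(["early", "late"]) & calls["mean_log2_el"].notna()]
    if len(unamb):
        agree = (
            (unamb["stage"] == "early") == (unamb["mean_log2_el"] > 0)
        ).mean()
        calls.attrs["el_consistency"] = float(agree)
    else:
        calls.attrs["el_consistency"] = np.nan
    return calls


def _gene_densities(profile: RTProfile, genes: pd.DataFrame) -> pd.DataFrame:
    df = profile.bins
    rows = []
    for _, g in genes.iterrows():
        sub = df[
            (df["chrom"] == g["chrom"])
            & (df["end"] > g["start"])
            & (df["start"] < g["end"])
        ]
        if len(sub) == 0 or sub["missing"].all():
            rows.append(
                {"gene": g["name"], "chrom": g["chrom"], "start": g["start"],
                 "end": g["end"], "early": np.nan, "mid": np.nan, "late": np.nan,
                 "stage": np.nan, "mean_log2_el": np.nan}
            )
            continue
        ov = (
            np.minimum(sub["end"], g["end"]) - np.maximum(sub["start"], g["start"])
        ).to_numpy(dtype=float)
        w = ov / ov.sum()
        dens = {
            f: float(np.nansum(w * sub[f"{f}_norm"].to_numpy())) for f in FRACTIONS
        }
        stage = FRACTIONS[int(np.argmax([dens[f] for f in FRACTIONS]))]
        mean_el = (
            float(np.nansum(w * sub["log2_el"].to_numpy()))
            if "log2_el" in sub
            else np.nan
        )
        rows.append(
            {"gene": g["name"], "chrom": g["chrom"], "start": g["start"],
             "end": g["end"], **dens, "stage": stage, "mean_log2_el": mean_el}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeat enrichment


def repeat_enrichment(
    regions: list[DifferentialRTRegion],
    repeats: pd.DataFrame,
    chrom_sizes: dict[str, int],
    n_permutations: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """log2 fold enrichment of repeat classes inside differential-RT regions.

    enrichment = log2[(class bp in regions / region bp) /
                      (class bp genome-wide / genome bp)].
    The empirical p-value shuffles region placements uniformly within their
    chromosome (lengths preserved) ``n_permutations`` times; classes absent
    genome-wide are reported missing rather than ±inf.
    """
    if len(repeats) == 0:
        raise ValueError("repeat annotation is empty")
    rng = np.random.default_rng(seed)
    genome_bp = sum(chrom_sizes.values())
    region_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in regions:
        region_by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    region_bp = sum(e - s for ivs in region_by_chrom.values() for s, e in ivs)
    out = []
    for cls, sub in repeats.groupby("class", sort=True):
        cls_bp = 0
        by_chrom = {}
        for chrom, rows in sub.groupby("chrom", sort=False):
            s, e = merge_intervals(rows["start"].to_numpy(), rows["end"].to_numpy())
            by_chrom[chrom] = (s, e)
            cls_bp += int(np.sum(e - s))
        if cls_bp == 0:
            out.append({"class": cls, "log2_enrichment": np.nan, "pvalue": np.nan})
            continue
        obs = _enrichment(region_by_chrom, by_chrom, region_bp, cls_bp, genome_bp)
        hits = 0
        for _ in range(n_permutations):
            shuffled = {
                chrom: [
                    (s0, s0 + (e - s))
                    for (s, e), s0 in zip(
                        ivs,
                        rng.integers(
                            0,
                            np.maximum(
                                1, chrom_sizes[chrom] - np.array([e - s for s, e in ivs])
                            ),
                        ),
                    )
                ]
                for chrom, ivs in region_by_chrom.items()
            }
            perm = _enrichment(shuffled, by_chrom, region_bp, cls_bp, genome_bp)
            if (obs >= 0 and perm >= obs) or (obs < 0 and perm <= obs):
                hits += 1
        pvalue = (1 + hits) / (1 + n_permutations)
        out.append({"class": cls, "log2_enrichment": obs, "pvalue": pvalue})
    return pd.DataFrame(out)


def _enrichment(region_by_chrom, cls_by_chrom, region_bp, cls_bp, genome_bp):
    ov = 0
    for chrom, ivs in region_by_chrom.items():
        if chrom not in cls_by_chrom:
            continue
        rs = np.array([s for s, _ in ivs])
        re_ = np.array([e for _, e in ivs])
        cs, ce = cls_by_chrom[chrom]
        ov += overlap_bp(rs, re_, cs, ce)
    dens_in = ov / region_bp if region_bp else 0.0
    dens_genome = cls_bp / genome_bp
    if dens_in == 0:
        return -np.inf
    return float(np.log2(dens_in / dens_genome))
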
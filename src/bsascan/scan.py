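"""SNP-index / deltaSNP-index genome scan and candidate-region calling.

For a pooled bulk at a parent-polymorphic site, the SNP-index is the fraction
of reads carrying the donor-parent allele, DepM / (DepM + DepW); the
deltaSNP-index is the resistant-bulk index minus the susceptible-bulk index.
Sites are kept when the two parents are opposite homozygotes and both bulks
reach a minimum depth.  Indices are averaged in wide sliding windows (1 Mb
window, 5 kb step by default), and window means are compared against
depth-conditional null quantiles obtained by Monte-Carlo simulation of an
unselected BC2F2 bulk pair (bulk genotypes 1:2:1 at a segregating site, read
counts binomial at the window's depth).  Runs of significant windows are
merged into candidate regions.

Orientation convention: "Mut" is the donor allele, so an index of 1 means the
bulk carries only donor reads at that site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .variants import ad_col, gt_col, rd_col, site_table_samples

DEFAULT_WINDOW = 1_000_000
DEFAULT_STEP = 5_000
DEFAULT_MIN_DEPTH = 10
DEFAULT_MIN_SITES = 5
DEFAULT_LEVELS = (0.95, 0.99, 0.999)


def snp_index(dep_m: int, dep_w: int) -> float:
    """SNP-index: DepM / (DepM + DepW), the donor-allele read fraction."""
    total = dep_m + dep_w
    if dep_m < 0 or dep_w < 0:
        raise ValueError("depths must be non-negative")
    if total == 0:
        raise ValueError("SNP-index undefined at zero total depth")
    return dep_m / total


def delta_snp_index(index_res: float, index_sus: float) -> float:
    """deltaSNP-index: resistant-bulk index minus susceptible-bulk index."""
    for v in (index_res, index_sus):
        if not 0.0 <= v <= 1.0:
            raise ValueError("SNP-indices must lie in [0, 1]")
    return index_res - index_sus


# ---------------------------------------------------------------------------
# Site filtering
# ---------------------------------------------------------------------------

DROP_REASONS = ("missing_parent_gt", "non_informative", "low_depth", "zero_depth")


def filter_informative_sites(sites: pd.DataFrame, res_bulk: str, sus_bulk: str,
                             donor: str, recurrent: str,
                             min_depth: int = DEFAULT_MIN_DEPTH
                             ) -> tuple[pd.DataFrame, dict]:
    """Keep parent-polymorphic sites with adequate bulk depth; compute indices.

    A site is informative when the donor and recurrent parents are opposite
    homozygotes; depths are oriented so DepM counts reads carrying the donor
    allele.  Both bulks must have total depth >= ``min_depth``.

    Returns ``(records, drop_counts)``; records have one row per retained site
    with per-bulk donor/recurrent depths, both indices and their difference.
    """
    for s in (res_bulk, sus_bulk, donor, recurrent):
        if gt_col(s) not in sites.columns:
            raise KeyError(f"sample {s!r} not in site table ({site_table_samples(sites)})")
    gt_d = sites[gt_col(donor)].to_numpy()
    gt_r = sites[gt_col(recurrent)].to_numpy()
    drops = {k: 0 for k in DROP_REASONS}

    missing = (gt_d == "./.") | (gt_r == "./.")
    donor_alt = (gt_d == "1/1") & (gt_r == "0/0")
    donor_ref = (gt_d == "0/0") & (gt_r == "1/1")
    informative = (donor_alt | donor_ref) & ~missing
    drops["missing_parent_gt"] = int(missing.sum())
    drops["non_informative"] = int((~informative & ~missing).sum())

    rd_res = sites[rd_col(res_bulk)].to_numpy()
    ad_res = sites[ad_col(res_bulk)].to_numpy()
    rd_sus = sites[rd_col(sus_bulk)].to_numpy()
    ad_sus = sites[ad_col(sus_bulk)].to_numpy()
    # orient depths to the donor allele
    depm_res = np.where(donor_alt, ad_res, rd_res)
    depw_res = np.where(donor_alt, rd_res, ad_res)
    depm_sus = np.where(donor_alt, ad_sus, rd_sus)
    depw_sus = np.where(donor_alt, rd_sus, ad_sus)
    tot_res = depm_res + depw_res
    tot_sus = depm_sus + depw_sus

    zero = informative & ((tot_res == 0) | (tot_sus == 0))
    deep = informative & (tot_res >= min_depth) & (tot_sus >= min_depth)
    drops["zero_depth"] = int(zero.sum())
    drops["low_depth"] = int((informative & ~deep & ~zero).sum())

    keep = deep
    with np.errstate(invalid="ignore", divide="ignore"):
        idx_res = np.where(tot_res > 0, depm_res / np.maximum(tot_res, 1), np.nan)
        idx_sus = np.where(tot_sus > 0, depm_sus / np.maximum(tot_sus, 1), np.nan)
    records = pd.DataFrame({
        "chrom": sites["chrom"].to_numpy()[keep],
        "pos": sites["pos"].to_numpy()[keep],
        "depm_res": depm_res[keep], "depw_res": depw_res[keep],
        "depm_sus": depm_sus[keep], "depw_sus": depw_sus[keep],
        "index_res": idx_res[keep], "index_sus": idx_sus[keep],
    })
    records["delta"] = records["index_res"] - records["index_sus"]
    return records.reset_index(drop=True), drops


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def sliding_windows(records: pd.DataFrame, chrom_lengths: Mapping[str, int],
                    window: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP,
                    min_sites: int = DEFAULT_MIN_SITES) -> pd.DataFrame:
    """Mean indices/delta per sliding window across each chromosome.

    Windows are half-open [start, start+window) internally and reported with
    1-based inclusive coordinates; starts are 1, 1+step, 1+2*step, ... while
    the start lies on the chromosome.  Partial chromosome-end windows are
    retained and flagged.  Windows with fewer than ``min_sites`` sites are
    masked (kept in the table, excluded from region calling).
    """
    if window < step:
        raise ValueError("window must be >= step")
    out = []
    for chrom, length in chrom_lengths.items():
        sub = records.loc[records["chrom"] == chrom].sort_values("pos")
        pos = sub["pos"].to_numpy()
        cols = {c: sub[c].to_numpy(dtype=float) for c in
                ("index_res", "index_sus", "delta", "depm_res", "depw_res", "depm_sus", "depw_sus")}
        csum = {c: np.concatenate([[0.0], np.cumsum(v)]) for c, v in cols.items()}
        starts = np.arange(1, length + 1, step, dtype=np.int64)
        ends = np.minimum(starts + window - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n = hi - lo
        safe = np.maximum(n, 1)

        def wmean(c):
            return (csum[c][hi] - csum[c][lo]) / safe

        df = pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends, "n_sites": n,
            "mean_index_res": np.where(n > 0, wmean("index_res"), np.nan),
            "mean_index_sus": np.where(n > 0, wmean("index_sus"), np.nan),
            "mean_delta": np.where(n > 0, wmean("delta"), np.nan),
            "mean_depth_res": np.where(n > 0, wmean("depm_res") + wmean("depw_res"), np.nan),
            "mean_depth_sus": np.where(n > 0, wmean("depm_sus") + wmean("depw_sus"), np.nan),
        })
        df["masked"] = df["n_sites"] < min_sites
        df["partial"] = (df["end"] - df["start"] + 1) < window
        out.append(df)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# Null model & thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NullModel:
    """Monte-Carlo null for an unselected BC2F2 bulk pair at a segregating site.

    A segregating site descends from a self of a heterozygous BC2F1, so each
    bulk member's donor dosage is 0/1/2 with probabilities 1/4, 1/2, 1/4; the
    bulk allele frequency is the mean dosage / 2 over ``n_bulk`` individuals
    (equivalently Binomial(2 n_bulk, 1/2) / (2 n_bulk)), and each bulk's donor
    read count is Binomial(depth, frequency).  delta is the difference of the
    two simulated indices.
    """

    n_bulk: int = 30
    levels: tuple[float, ...] = DEFAULT_LEVELS
    replicates: int = 10_000
    error_rate: float = 0.0

    def __post_init__(self):
        if self.replicates < 1_000:
            raise ValueError("need at least 1,000 replicates")
        if not all(0 < l < 1 for l in self.levels):
            raise ValueError("significance levels must lie in (0, 1)")


def _simulate_null_delta(nm: NullModel, d_res: int, d_sus: int,
                         rng: np.random.Generator) -> np.ndarray:
    two_n = 2 * nm.n_bulk
    e = nm.error_rate
    deltas = np.empty(nm.replicates)
    f1 = rng.binomial(two_n, 0.5, nm.replicates) / two_n
    f2 = rng.binomial(two_n, 0.5, nm.replicates) / two_n
    f1 = f1 * (1 - e) + (1 - f1) * e
    f2 = f2 * (1 - e) + (1 - f2) * e
    i1 = rng.binomial(d_res, f1) / d_res
    i2 = rng.binomial(d_sus, f2) / d_sus
    deltas = i1 - i2
    return deltas


def null_thresholds(nm: NullModel, depth_pairs: Sequence[tuple[float, float]],
                    seed: int = 0) -> pd.DataFrame:
    """|delta| null quantiles for each (resistant, susceptible) depth pair.

    Depths are rounded to integers and de-duplicated before simulation.
    Thresholds are made monotone non-increasing in total depth by isotonic
    regression (least-squares projection), which removes Monte-Carlo jitter.
    Zero-depth pairs get NaN thresholds (the window stays masked).
    """
    from scipy.optimize import isotonic_regression

    rng = np.random.default_rng(seed)
    pairs = sorted({(int(round(a)), int(round(b))) for a, b in depth_pairs})
    rows = []
    for d1, d2 in pairs:
        if d1 <= 0 or d2 <= 0:
            rows.append({"depth_res": d1, "depth_sus": d2,
                         **{_level_col(l): np.nan for l in nm.levels}})
            continue
        deltas = np.abs(_simulate_null_delta(nm, d1, d2, rng))
        qs = np.quantile(deltas, nm.levels)
        rows.append({"depth_res": d1, "depth_sus": d2,
                     **{_level_col(l): q for l, q in zip(nm.levels, qs)}})
    df = pd.DataFrame(rows)
    valid = (df["depth_res"] > 0) & (df["depth_sus"] > 0)
    if valid.sum() > 1:
        order = np.argsort((df.loc[valid, "depth_res"] + df.loc[valid, "depth_sus"]).to_numpy(),
                           kind="stable")
        for l in nm.levels:
            col = _level_col(l)
            vals = df.loc[valid, col].to_numpy()[order]
            smoothed = isotonic_regression(vals, increasing=False).x
            tmp = df.loc[valid, col].to_numpy()
            tmp[order] = smoothed
            df.loc[valid, col] = tmp
    return df


def _level_col(level: float) -> str:
    # valid identifier so windows.itertuples keeps the name (thr_95, thr_99_9)
    return "thr_" + f"{level * 100:g}".replace(".", "_")


def attach_thresholds(windows: pd.DataFrame, nm: NullModel, seed: int = 0) -> pd.DataFrame:
    """Join per-window null thresholds keyed by rounded window mean depths."""
    win = windows.copy()
    win["_dr"] = win["mean_depth_res"].fillna(0).round().astype(int)
    win["_ds"] = win["mean_depth_sus"].fillna(0).round().astype(int)
    pairs = list({(a, b) for a, b in zip(win["_dr"], win["_ds"])})
    thr = null_thresholds(nm, pairs, seed=seed)
    merged = win.merge(thr, left_on=["_dr", "_ds"], right_on=["depth_res", "depth_sus"],
                       how="left").drop(columns=["_dr", "_ds", "depth_res", "depth_sus"])
    merged.index = windows.index
    return merged


# ---------------------------------------------------------------------------
# Region calling
# ---------------------------------------------------------------------------

@dataclass
class CandidateRegion:
    """A merged run of significant windows harboring a putative trait locus."""

    chrom: str
    start: int
    end: int
    peak_delta: float
    level: float                 # highest significance level attained in the region
    n_windows: int
    effective_variants: pd.DataFrame | None = None

    @property
    def length_mb(self) -> float:
        return round_half_up((self.end - self.start) / 1e6, 2)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def region_length_mb(start: int, end: int) -> float:
    """Region length in Mb, rounded half-up to 2 decimals."""
    return round_half_up((end - start) / 1e6, 2)


def call_candidate_regions(windows: pd.DataFrame, level: float,
                           step: int = DEFAULT_STEP, levels: Sequence[float] = DEFAULT_LEVELS,
                           sites: pd.DataFrame | None = None) -> list[CandidateRegion]:
    """Merge windows whose |mean delta| exceeds the null threshold at ``level``.

    Windows that overlap or lie within one step of each other join the same
    region; the region spans the first significant window's start to the last
    one's end.  When an annotated site table is given, the HIGH/MODERATE-impact
    sites inside each region are attached as its effective variants.
    """
    col = _level_col(level)
    if col not in windows.columns:
        raise KeyError(f"windows lack thresholds at level {level}; run attach_thresholds")
    usable = windows.loc[~windows["masked"] & windows[col].notna()]
    sig = usable.loc[usable["mean_delta"].abs() > usable[col]]
    regions: list[CandidateRegion] = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples():
            if cur is not None and row.start <= cur["end"] + step:
                cur["end"] = max(cur["end"], row.end)
                cur["rows"].append(row)
            else:
                if cur is not None:
                    regions.append(_finish_region(chrom, cur, windows, levels, sites))
                cur = {"start": int(row.start), "end": int(row.end), "rows": [row]}
        if cur is not None:
            regions.append(_finish_region(chrom, cur, windows, levels, sites))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _finish_region(chrom: str, cur: dict, windows: pd.DataFrame,
                   levels: Sequence[float], sites: pd.DataFrame | None) -> CandidateRegion:
    deltas = np.array([r.mean_delta for r in cur["rows"]])
    peak = float(deltas[np.argmax(np.abs(deltas))])
    attained = 0.0
    for l in sorted(levels):
        col = _level_col(l)
        if col in windows.columns and any(
                abs(r.mean_delta) > getattr(r, col) for r in cur["rows"]
                if not np.isnan(getattr(r, col))):
            attained = l
    eff = None
    if sites is not None and "impact" in sites.columns:
        inside = (sites["chrom"] == chrom) & (sites["pos"] >= cur["start"]) & (sites["pos"] <= cur["end"])
        eff = sites.loc[inside & sites["impact"].isin(("HIGH", "MODERATE")),
                        [c for c in ("chrom", "pos", "ref", "alt", "impact", "consequence")
                         if c in sites.columns]].reset_index(drop=True)
    return CandidateRegion(chrom, cur["start"], cur["end"], peak, attained,
                           len(cur["rows"]), eff)


def regions_to_bed(regions: Sequence[CandidateRegion]) -> str:
    """BED text (0-based half-open) for the called regions."""
    lines = []
    for r in regions:
        name = f"len={r.length_mb}Mb;level={r.level:g}"
        lines.append(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{name}\t{abs(r.peak_delta):.4f}")
    return "\n".join(lines) + ("\n" if lines else "")


def plot_scan(windows: pd.DataFrame, path, level: float | None = None) -> None:
    """Per-chromosome index tracks (resistant, susceptible, delta) as a PNG/PDF."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.4 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = windows.loc[(windows["chrom"] == chrom) & ~windows["masked"]]
        x = (sub["start"] + sub["end"]) / 2e6
        ax.plot(x, sub["mean_index_res"], lw=0.8, label="resistant bulk")
        ax.plot(x, sub["mean_index_sus"], lw=0.8, label="susceptible bulk")
        ax.plot(x, sub["mean_delta"], lw=1.2, color="k", label="delta")
        if level is not None and _level_col(level) in sub.columns:
            ax.plot(x, sub[_level_col(level)], lw=0.8, ls="--", color="r",
                    label=f"{level:.1%} threshold")
            ax.plot(x, -sub[_level_col(level)], lw=0.8, ls="--", color="r")
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_ylabel(chrom)
        ax.set_ylim(-1.05, 1.05)
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
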
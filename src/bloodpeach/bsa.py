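"""BSA-seq locus mapping with the pooled Euclidean-distance statistic.

For each SNP the two phenotype pools' A/C/G/T read counts are converted to
base-frequency vectors and contrasted with

    ED = sqrt((A_mut - A_wt)^2 + (C_mut - C_wt)^2
              + (G_mut - G_wt)^2 + (T_mut - T_wt)^2),

raised to a power (k = 5 by default) to sharpen linked peaks against
drift noise, then averaged over sliding windows (100 kb window, 10 kb step
by default). Windows whose aggregated ED^k exceeds the genome-wide
empirical 95th percentile are merged into candidate intervals.

``EDScan`` is the model object; ``EDScan(sites, chrom_lengths).fit()``
returns an :class:`EDScanResults` carrying the per-site statistics, window
table, threshold and candidate intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from bloodpeach.io import BASES, interval_to_bed

_MUT_COLS = [f"{b}_mut" for b in BASES]
_WT_COLS = [f"{b}_wt" for b in BASES]

#: hard-filter clauses in the order they are checked; each maps a column to
#: the KEEP condition (GATK-style removal thresholds inverted)
_FILTER_CLAUSES = (
    ("DP", "dp", lambda v: v >= 4),
    ("QD", "qd", lambda v: v >= 2.0),
    ("FS", "fs", lambda v: v <= 60.0),
    ("MQ", "mq", lambda v: v >= 40.0),
    ("MQRankSum", "mq_rank_sum", lambda v: v >= -12.5),
    ("ReadPosRankSum", "read_pos_rank_sum", lambda v: v >= -8.0),
)


@dataclass
class ScanConfig:
    """Sliding-window scan parameters.

    window/step in bp (defaults 100 kb / 10 kb), ``power`` the ED exponent
    (default 5), ``threshold_level`` the empirical quantile used as the
    screening threshold (default 0.95, genome-wide), ``aggregation`` the
    within-window summary of ED^k (``mean`` or ``sum``), and
    ``min_snps_per_window`` below which a window's statistic is undefined.
    ``threshold_scope='chrom'`` switches to per-chromosome thresholds;
    ``strict_missing=True`` makes missing quality annotations fail the
    filter; ``dp_is_remove=True`` flips the depth clause to the literal
    remove-reading (drop sites with dp >= 4).
    """

    window: int = 100_000
    step: int = 10_000
    power: float = 5.0
    threshold_level: float = 0.95
    aggregation: str = "mean"
    min_snps_per_window: int = 1
    threshold_scope: str = "genome"
    strict_missing: bool = False
    dp_is_remove: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError(f"need 0 < step <= window, got {self.step}, {self.window}")
        if not 0 < self.threshold_level < 1:
            raise ValueError(f"threshold_level must be in (0,1), got {self.threshold_level}")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError(f"aggregation must be mean or sum, got {self.aggregation!r}")
        if self.power < 1:
            raise ValueError("power must be >= 1")


# ---------------------------------------------------------------------------
# per-site operations


def filter_snps(
    sites: pd.DataFrame, *, strict_missing: bool = False, dp_is_remove: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the hard site filter; returns (kept, rejection log).

    A site is kept iff dp >= 4 and no quality clause fails (QD < 2.0,
    FS > 60.0, MQ < 40.0, MQRankSum < -12.5, ReadPosRankSum < -8.0).
    Missing annotations pass unless ``strict_missing``. The log has one row
    per dropped site with the comma-joined names of the failing clauses.
    Kept and rejected partition the input exactly.
    """
    n = len(sites)
    fail_names = [[] for _ in range(n)]
    keep = np.ones(n, dtype=bool)
    for name, col, ok in _FILTER_CLAUSES:
        vals = sites[col].to_numpy(dtype=float)
        missing = np.isnan(vals)
        passing = np.where(missing, not strict_missing, ok(vals))
        if name == "DP" and dp_is_remove:
            # literal remove-reading of "DP >= 4": high-depth sites dropped
            passing = np.where(missing, not strict_missing, vals < 4)
        bad = ~passing
        keep &= passing
        for i in np.flatnonzero(bad):
            fail_names[i].append(name)
    kept = sites[keep].reset_index(drop=True)
    rejected = sites[~keep].copy()
    rejected["reason"] = [",".join(fail_names[i]) for i in np.flatnonzero(~keep)]
    return kept, rejected.reset_index(drop=True)


def pool_frequencies(site: Mapping[str, float] | pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Base-frequency vectors (mut, wt) over (A, C, G, T) for one site.

    A pool with zero total depth yields a vector of NaN — the site is
    unusable for the scan.
    """
    out = []
    for cols in (_MUT_COLS, _WT_COLS):
        counts = np.array([float(site[c]) for c in cols])
        if (counts < 0).any():
            raise ValueError("negative read counts")
        total = counts.sum()
        out.append(counts / total if total > 0 else np.full(4, np.nan))
    return out[0], out[1]


def euclidean_distance(freq_mut: np.ndarray, freq_wt: np.ndarray) -> float:
    """ED between two base-frequency vectors; in [0, sqrt(2)], symmetric."""
    f1, f2 = np.asarray(freq_mut, dtype=float), np.asarray(freq_wt, dtype=float)
    for f in (f1, f2):
        if f.shape != (4,):
            raise ValueError("frequency vectors must have 4 components")
        if np.isnan(f).any():
            raise ValueError("undefined frequency vector (zero-depth pool)")
        if abs(f.sum() - 1.0) > 1e-9 or (f < 0).any():
            raise ValueError(f"frequencies must be non-negative and sum to 1, got {f}")
    return float(np.sqrt(((f1 - f2) ** 2).sum()))


def transform_ed(ed_values, power: float = 5.0) -> np.ndarray:
    """Elementwise ED^k; strictly monotone on non-negatives, so rank-preserving."""
    if power < 1:
        raise ValueError("power must be >= 1")
    return np.power(np.asarray(ed_values, dtype=float), power)


def site_ed(sites: pd.DataFrame, power: float = 5.0) -> pd.DataFrame:
    """Vectorised per-site ED and ED^k; drops sites with a zero-depth pool."""
    mut = sites[_MUT_COLS].to_numpy(dtype=float)
    wt = sites[_WT_COLS].to_numpy(dtype=float)
    tm, tw = mut.sum(axis=1), wt.sum(axis=1)
    usable = (tm > 0) & (tw > 0)
    fm = mut[usable] / tm[usable, None]
    fw = wt[usable] / tw[usable, None]
    ed = np.sqrt(((fm - fw) ** 2).sum(axis=1))
    out = sites[usable].reset_index(drop=True).copy()
    out["ed"] = ed
    out["ed_power"] = transform_ed(ed, power)
    return out


# ---------------------------------------------------------------------------
# windows, threshold, intervals


def window_scan(
    sites: pd.DataFrame, chrom_lengths: Mapping[str, int], cfg: ScanConfig
) -> pd.DataFrame:
    """Aggregate ED^k over sliding windows.

    Windows start at 1, 1+step, ... while start <= chromosome length; the
    last windows truncate at the chromosome end. Windows with fewer than
    ``min_snps_per_window`` sites carry NaN (excluded from thresholding).
    Requires ``sites`` sorted by (chrom, pos).
    """
    for chrom, grp in sites.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"sites on {chrom} are not sorted by position")
    rows = []
    for chrom, length in chrom_lengths.items():
        grp = sites[sites["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        vals = grp["ed_power"].to_numpy()
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        starts = np.arange(1, length + 1, cfg.step)
        ends = np.minimum(starts + cfg.window - 1, length)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="right")
        n_snps = hi - lo
        sums = csum[hi] - csum[lo]
        with np.errstate(invalid="ignore"):
            stat = sums / n_snps if cfg.aggregation == "mean" else sums.astype(float)
        stat = np.where(n_snps >= cfg.min_snps_per_window, stat, np.nan)
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "start": starts, "end": ends,
                 "n_snps": n_snps, "stat": stat}
            )
        )
    return pd.concat(rows, ignore_index=True)


def compute_threshold(windows: pd.DataFrame, cfg: ScanConfig) -> tuple[float, int]:
    """Empirical quantile of the defined window statistics.

    Linear interpolation between order statistics (numpy default), so the
    threshold is bit-for-bit reproducible. Returns (threshold, n windows
    contributing).
    """
    stats = windows["stat"].to_numpy(dtype=float)
    stats = stats[~np.isnan(stats)]
    if len(stats) == 0:
        raise ValueError("no defined window statistics to take a quantile of")
    return float(np.quantile(stats, cfg.threshold_level)), int(len(stats))


def call_candidate_intervals(
    windows: pd.DataFrame, threshold: float, step: int
) -> pd.DataFrame:
    """Merge maximal runs of consecutive supra-threshold windows.

    Consecutive means same chromosome with starts ``step`` apart. The
    interval spans the union of its member windows; the peak window is the
    member with the highest statistic (ties -> smaller start).
    """
    hot = windows[windows["stat"] > threshold].sort_values(["chrom", "start"])
    intervals = []
    run: list[pd.Series] = []

    def close(run):
        if not run:
            return
        peak = max(run, key=lambda w: (w["stat"], -w["start"]))
        intervals.append(
            {
                "chrom": run[0]["chrom"],
                "start": int(run[0]["start"]),
                "end": int(max(w["end"] for w in run)),
                "n_windows": len(run),
                "max_stat": float(peak["stat"]),
                "peak_start": int(peak["start"]),
                "peak_end": int(peak["end"]),
            }
        )

    for _, w in hot.iterrows():
        if run and w["chrom"] == run[-1]["chrom"] and w["start"] - run[-1]["start"] == step:
            run.append(w)
        else:
            close(run)
            run = [w]
    close(run)
    cols = ["chrom", "start", "end", "n_windows", "max_stat", "peak_start", "peak_end"]
    return pd.DataFrame(intervals, columns=cols)


# ---------------------------------------------------------------------------
# model / results


class EDScan:
    """Euclidean-distance BSA scan over a SNP site table.

    Parameters
    ----------
    sites
        Site table (see :data:`bloodpeach.io.SITE_COLUMNS`).
    chrom_lengths
        Mapping contig -> length in bp.
    config
        :class:`ScanConfig`; defaults follow the standard ED-BSA recipe.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        chrom_lengths: Mapping[str, int],
        config: ScanConfig | None = None,
    ):
        self.sites = sites
        self.chrom_lengths = dict(chrom_lengths)
        self.config = config or ScanConfig()

    @classmethod
    def from_files(
        cls,
        sites_path,
        genome_path,
        config: ScanConfig | None = None,
        *,
        dialect: str = "tsv",
        mut_sample: str | None = None,
        wt_sample: str | None = None,
    ) -> "EDScan":
        from bloodpeach import io

        sites = io.read_sites(sites_path, dialect,
                              mut_sample=mut_sample, wt_sample=wt_sample)
        lengths = io.read_chrom_lengths(genome_path)
        return cls(sites, lengths, config)

    def fit(self) -> "EDScanResults":
        cfg = self.config
        kept, rejected = filter_snps(
            self.sites, strict_missing=cfg.strict_missing,
            dp_is_remove=cfg.dp_is_remove,
        )
        kept = kept.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        scored = site_ed(kept, cfg.power)
        windows = window_scan(scored, self.chrom_lengths, cfg)
        if cfg.threshold_scope == "chrom":
            thresholds = {
                c: compute_threshold(w, cfg)[0]
                for c, w in windows.groupby("chrom", sort=False)
            }
            # mask sub-threshold windows per chromosome, then merge runs
            per_win_thr = windows["chrom"].map(thresholds).to_numpy(dtype=float)
            masked = windows.copy()
            masked.loc[~(windows["stat"].to_numpy() > per_win_thr), "stat"] = np.nan
            threshold = float("nan")
            intervals = call_candidate_intervals(masked, float("-inf"), cfg.step)
            n_thr = int(windows["stat"].notna().sum())
        else:
            threshold, n_thr = compute_threshold(windows, cfg)
            thresholds = None
            intervals = call_candidate_intervals(windows, threshold, cfg.step)
        return EDScanResults(
            model=self,
            sites_used=scored,
            n_sites_in=len(self.sites),
            n_sites_rejected=len(rejected),
            rejection_log=rejected,
            window_stats=windows,
            threshold=threshold,
            per_chrom_thresholds=thresholds,
            n_windows_used=n_thr,
            candidate_intervals=intervals,
        )


@dataclass
class EDScanResults:
    """Fitted ED scan: windows, threshold and candidate intervals."""

    model: EDScan
    sites_used: pd.DataFrame
    n_sites_in: int
    n_sites_rejected: int
    rejection_log: pd.DataFrame
    window_stats: pd.DataFrame
    threshold: float
    per_chrom_thresholds: dict | None
    n_windows_used: int
    candidate_intervals: pd.DataFrame
    _ranked: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._ranked = self.candidate_intervals.sort_values(
            "max_stat", ascending=False
        ).reset_index(drop=True)

    @property
    def top_interval(self) -> pd.Series | None:
        """Candidate interval with the highest peak statistic, if any."""
        return self._ranked.iloc[0] if len(self._ranked) else None

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Euclidean-distance BSA scan",
            "=" * 60,
            f"sites: {self.n_sites_in} in, {self.n_sites_rejected} filtered, "
            f"{len(self.sites_used)} scored",
            f"window {cfg.window} bp, step {cfg.step} bp, ED^{cfg.power:g}, "
            f"{cfg.aggregation} aggregation",
            f"threshold: {self.threshold:.6g} "
            f"(empirical {cfg.threshold_level:.0%} quantile of "
            f"{self.n_windows_used} windows)",
            f"candidate intervals: {len(self.candidate_intervals)}",
        ]
        for _, iv in self._ranked.iterrows():
            lines.append(
                f"  {iv.chrom}:{iv.start}-{iv.end}  "
                f"peak {iv.peak_start}-{iv.peak_end}  max ED^k {iv.max_stat:.4g}"
            )
        return "\n".join(lines)

    def to_bed(self, path) -> None:
        from bloodpeach.io import write_bed

        write_bed(
            (
                (iv.chrom, int(iv.start), int(iv.end), f"candidate_{i + 1}",
                 float(iv.max_stat))
                for i, iv in self._ranked.iterrows()
            ),
            path,
        )

    def run_summary(self) -> dict:
        return {
            "config": asdict(self.model.config),
            "threshold": self.threshold,
            "n_windows_used": self.n_windows_used,
            "n_candidate_intervals": len(self.candidate_intervals),
        }

    def plot(self, chrom: str | None = None, ax=None):
        """Per-chromosome Manhattan-style plot of window ED^k."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(9, 3))
        w = self.window_stats
        if chrom is not None:
            w = w[w["chrom"] == chrom]
        offset = 0
        for c, grp in w.groupby("chrom", sort=False):
            mid = (grp["start"] + grp["end"]) / 2 + offset
            ax.plot(mid, grp["stat"], ".", ms=3, label=c)
            offset += self.model.chrom_lengths.get(c, grp["end"].max())
        if np.isfinite(self.threshold):
            ax.axhline(self.threshold, color="red", lw=1, ls="--")
        ax.set_xlabel("position (bp)")
        ax.set_ylabel(f"mean ED^{self.model.config.power:g}")
        return ax
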
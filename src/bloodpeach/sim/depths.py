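"""Pooled-sequencing read-depth sampling and the end-to-end BSA simulation.

Depth model: per site and pool, total depth ~ Poisson(mean depth) and base
counts ~ Multinomial(depth, pool base frequencies). This is the simplest
model consistent with pooled whole-genome sequencing of a bulk; there is no
read-level error profile (an optional uniform miscall rate can be enabled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from bloodpeach.io import BASES, SITE_COLUMNS
from bloodpeach.sim.config import SimConfig

_BASE_IDX = {b: i for i, b in enumerate(BASES)}

# value ranges used to fill GATK-style annotations: "pass" draws sit safely
# inside the hard-filter acceptance region, "fail" draws sit outside it
_QC_PASS = {
    "qd": (10.0, 35.0),
    "fs": (0.0, 20.0),
    "mq": (50.0, 60.0),
    "mq_rank_sum": (-2.0, 2.0),
    "read_pos_rank_sum": (-2.0, 2.0),
}
_QC_FAIL = {
    "qd": (0.0, 1.99),
    "fs": (60.01, 100.0),
    "mq": (0.0, 39.99),
    "mq_rank_sum": (-20.0, -12.51),
    "read_pos_rank_sum": (-15.0, -8.01),
}


def sample_allele_depths(
    truth: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Turn true pooled allele frequencies into a noisy SNP site table.

    ``truth`` needs columns ``chrom, pos, ref, alt, truth_freq_mut,
    truth_freq_wt`` (frequencies of the alt base in each pool). Returns the
    canonical site table (see :data:`bloodpeach.io.SITE_COLUMNS`) with the
    ground-truth columns retained alongside.
    """
    if cfg.depth <= 0:
        raise ValueError(f"depth must be > 0, got {cfg.depth}")
    m = len(truth)
    ref_idx = truth["ref"].map(_BASE_IDX).to_numpy()
    alt_idx = truth["alt"].map(_BASE_IDX).to_numpy()
    out = {
        "chrom": truth["chrom"].to_numpy(),
        "pos": truth["pos"].to_numpy(),
        "ref": truth["ref"].to_numpy(),
    }
    totals = {}
    for pool in ("mut", "wt"):
        p_alt = truth[f"truth_freq_{pool}"].to_numpy(dtype=float)
        pvals = np.zeros((m, 4))
        pvals[np.arange(m), ref_idx] = 1.0 - p_alt
        pvals[np.arange(m), alt_idx] += p_alt
        if cfg.error_rate > 0:
            pvals = pvals * (1.0 - cfg.error_rate) + cfg.error_rate / 4.0
        n_reads = rng.poisson(cfg.depth, size=m)
        counts = rng.multinomial(n_reads, pvals)
        for j, b in enumerate(BASES):
            out[f"{b}_{pool}"] = counts[:, j]
        totals[pool] = n_reads

    for col in ("qd", "fs", "mq", "mq_rank_sum", "read_pos_rank_sum"):
        vals = rng.uniform(*_QC_PASS[col], size=m)
        if cfg.qc_fail_fraction > 0:
            fail = rng.random(m) < cfg.qc_fail_fraction
            vals[fail] = rng.uniform(*_QC_FAIL[col], size=int(fail.sum()))
        out[col] = vals
    dp = totals["mut"] + totals["wt"]
    if cfg.qc_fail_fraction > 0:
        fail = rng.random(m) < cfg.qc_fail_fraction
        dp = dp.copy()
        dp[fail] = rng.integers(0, 4, size=int(fail.sum()))
    out["dp"] = dp

    df = pd.DataFrame(out)
    df["alt"] = truth["alt"].to_numpy()
    df["truth_freq_mut"] = truth["truth_freq_mut"].to_numpy()
    df["truth_freq_wt"] = truth["truth_freq_wt"].to_numpy()
    return df[SITE_COLUMNS + ["alt", "truth_freq_mut", "truth_freq_wt"]]


@dataclass
class BsaSimulation:
    """Output bundle of :func:`simulate_bsa_experiment`."""

    sites: pd.DataFrame
    cfg: SimConfig
    causal_chrom: str
    causal_pos: int
    n_carriers: int
    n_noncarriers: int
    chrom_lengths: dict[str, int]


def simulate_bsa_experiment(cfg: SimConfig) -> BsaSimulation:
    """Simulate the full bulked-segregant design and return its site table.

    The cross is a carrier x non-carrier F1: the blood parent is
    heterozygous for a haplotype bearing the causal element (and an alt
    allele at every informative SNP on that haplotype); the other parent is
    homozygous reference. Offspring phenotype follows the dominant model,
    two bulks of ``cfg.bulk_size`` are drawn, and pooled allele depths are
    sampled at every SNP. Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)

    chroms, positions = [], []
    for name in cfg.chrom_names:
        pos = np.arange(cfg.snp_spacing, cfg.chrom_len + 1, cfg.snp_spacing)
        if name == cfg.causal_chrom and cfg.causal_pos not in pos:
            pos = np.sort(np.append(pos, cfg.causal_pos))
        chroms.extend([name] * len(pos))
        positions.extend(pos.tolist())
    chrom_arr = np.array(chroms)
    pos_arr = np.array(positions)
    L = len(pos_arr)
    causal_idx = int(
        np.flatnonzero((chrom_arr == cfg.causal_chrom) & (pos_arr == cfg.causal_pos))[0]
    )

    # parent-1 gametes: haplotype 0 carries the causal element and the alt
    # allele at every SNP; recombination via Haldane between adjacent SNPs
    from bloodpeach.sim.cross import Locus, sample_gamete_haplotypes

    loci = [
        Locus(name=f"snp{i}", chrom=c, cm=p / 1e6 * cfg.recomb_rate)
        for i, (c, p) in enumerate(zip(chroms, positions))
    ]
    H = sample_gamete_haplotypes(loci, cfg.n_offspring, rng)
    carrier = H[:, causal_idx] == 0

    n_car, n_non = int(carrier.sum()), int((~carrier).sum())
    if n_car < cfg.bulk_size or n_non < cfg.bulk_size:
        raise ValueError(
            f"cannot fill bulks of {cfg.bulk_size}: {n_car} carriers, "
            f"{n_non} non-carriers"
        )
    mut_pool = rng.choice(np.flatnonzero(carrier), cfg.bulk_size, replace=False)
    wt_pool = rng.choice(np.flatnonzero(~carrier), cfg.bulk_size, replace=False)

    # pooled alt frequency = mean dosage / 2; the non-carrier parent only
    # ever contributes reference alleles, so dosage is the hap-0 indicator
    freq_mut = (H[mut_pool] == 0).mean(axis=0) / 2.0
    freq_wt = (H[wt_pool] == 0).mean(axis=0) / 2.0

    ref_idx = rng.integers(0, 4, size=L)
    alt_idx = (ref_idx + rng.integers(1, 4, size=L)) % 4
    truth = pd.DataFrame(
        {
            "chrom": chrom_arr,
            "pos": pos_arr,
            "ref": np.array(BASES)[ref_idx],
            "alt": np.array(BASES)[alt_idx],
            "truth_freq_mut": freq_mut,
            "truth_freq_wt": freq_wt,
        }
    )
    sites = sample_allele_depths(truth, cfg, rng)
    return BsaSimulation(
        sites=sites,
        cfg=cfg,
        causal_chrom=cfg.causal_chrom,
        causal_pos=cfg.causal_pos,
        n_carriers=n_car,
        n_noncarriers=n_non,
        chrom_lengths={name: cfg.chrom_len for name in cfg.chrom_names},
    )
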
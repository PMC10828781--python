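"""Marker–phenotype statistics: Mendelian ratios, chi-square tests,
co-segregation, haplotype→colour rules, FDP classes, carrier ratios.

Genotypes are written as unordered allele pairs (``"0/9"``, ``"R1R2"``,
``"D1D2"`` …). The chi-square goodness-of-fit statistic is plain Pearson
without continuity correction — the convention that reproduces the printed
worked examples in this trait system exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import gcd
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: ordinal fruit-development-period classes (days), earliest first
FDP_CLASSES = ("60-90", "90-120", "120-150")

#: genotype of the 9 bp insertion -> expected FDP class
_INS9_TO_FDP = {"9/9": "60-90", "0/9": "90-120", "0/0": "120-150"}

#: (D haplotype pair, T haplotype pair) -> blood-flesh colour intensity,
#: valid only in the presence of the blood TE
_COLOR_RULES = {
    ("D1D1", "T1T1"): "dark",
    ("D1D2", "T1T1"): "blood",
    ("D2D2", "T1T1"): "light",
    ("D2D2", "T1T2"): "none",
}


@dataclass(frozen=True)
class MarkerGenotype:
    """Multi-locus genotype; unset fields may be None."""

    blood_te: str | None = None  # "R1R2" (carrier) | "R2R2" (non-carrier)
    d_hap: str | None = None  # D1D1 | D1D2 | D2D2
    t_hap: str | None = None  # T1T1 | T1T2 | T2T2
    ins9: str | None = None  # "0/0" | "0/9" | "9/9"


def _normalise_genotype(g: str) -> tuple[str, str]:
    if "/" in g:
        a, b = g.split("/")
    elif len(g) % 2 == 0:
        a, b = g[: len(g) // 2], g[len(g) // 2 :]
    else:
        raise ValueError(f"cannot parse genotype {g!r}")
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def expected_offspring_ratio(parent1: str, parent2: str) -> dict[str, int]:
    """Punnett-square offspring ratio for a single diploid locus.

    Genotypes are ``"a/b"``; the result maps offspring genotype (alleles
    sorted) to its ratio term, reduced to lowest integers. E.g.
    ``0/9 x 0/9 -> {"9/9": 1, "0/9": 2, "0/0": 1}``.
    """
    a = _normalise_genotype(parent1)
    b = _normalise_genotype(parent2)
    counts: dict[str, int] = {}
    for x in a:
        for y in b:
            key = "/".join(sorted((x, y)))
            counts[key] = counts.get(key, 0) + 1
    g = 0
    for v in counts.values():
        g = gcd(g, v)
    return {k: v // g for k, v in sorted(counts.items(), reverse=True)}


@dataclass
class ChiSquareResult:
    """Pearson goodness-of-fit test against an expected ratio."""

    statistic: float
    df: int
    alpha: float
    critical_value: float
    reject: bool
    p_value: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]

    def summary(self) -> str:
        verdict = "deviates from" if self.reject else "consistent with"
        obs = ", ".join(f"{v:g}" for v in self.observed)
        return (
            f"chi2 = {self.statistic:.2f} (df={self.df}, "
            f"chi2_{self.alpha:g} = {self.critical_value:.2f}, "
            f"p = {self.p_value:.3g}): observed ({obs}) "
            f"{verdict} expected ratio"
        )


def chi_square_critical(df: int, alpha: float = 0.05) -> float:
    """Upper-tail chi-square quantile (e.g. df=2, alpha=0.05 -> 5.99)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    return float(stats.chi2.isf(alpha, df))


def chi_square_gof(
    observed: Sequence[float],
    ratio: Sequence[float] | Mapping[str, float],
    alpha: float = 0.05,
) -> ChiSquareResult:
    """Pearson chi-square of observed counts against an expected ratio.

    No continuity correction. ``ratio`` may be a sequence (``[1, 2, 1]``)
    or the mapping returned by :func:`expected_offspring_ratio` (order is
    taken as given). A class with expected count 0 but nonzero observations
    is an error — collapse classes explicitly instead.
    """
    if isinstance(ratio, Mapping):
        ratio = list(ratio.values())
    obs = np.asarray(observed, dtype=float)
    rat = np.asarray(ratio, dtype=float)
    if obs.shape != rat.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed and ratio must be 1-D of equal length >= 2")
    if (rat < 0).any() or rat.sum() <= 0:
        raise ValueError("expected ratio must be non-negative with positive sum")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total observed count must be > 0")
    exp = total * rat / rat.sum()
    if ((exp == 0) & (obs > 0)).any():
        raise ValueError(
            "expected count 0 with nonzero observations; collapse classes first"
        )
    ok = exp > 0
    statistic = float((((obs - exp) ** 2)[ok] / exp[ok]).sum())
    df = len(obs) - 1
    crit = chi_square_critical(df, alpha)
    return ChiSquareResult(
        statistic=statistic,
        df=df,
        alpha=alpha,
        critical_value=crit,
        reject=statistic > crit,
        p_value=float(stats.chi2.sf(statistic, df)),
        observed=tuple(float(v) for v in obs),
        expected=tuple(float(v) for v in exp),
    )


@dataclass
class ConcordanceResult:
    """Marker presence vs binary phenotype 2x2 agreement."""

    concordance: float
    table: pd.DataFrame  # rows: carrier/non-carrier; cols: phenotype +/-
    n: int
    n_missing: int


def cosegregation_concordance(
    marker: Sequence, phenotype: Sequence
) -> ConcordanceResult:
    """Fraction of individuals where marker presence matches the phenotype.

    Inputs are boolean-like vectors of equal length; entries where either
    value is missing (None/NaN) are dropped and counted. Returns the
    concordance and the 2x2 contingency table.
    """
    m = pd.Series(list(marker))
    p = pd.Series(list(phenotype))
    if len(m) != len(p):
        raise ValueError(f"length mismatch: {len(m)} markers vs {len(p)} phenotypes")
    ok = m.notna() & p.notna()
    n_missing = int((~ok).sum())
    mb = m[ok].astype(bool).to_numpy()
    pb = p[ok].astype(bool).to_numpy()
    n = len(mb)
    if n == 0:
        raise ValueError("no complete observations")
    tab = pd.DataFrame(
        [
            [int((mb & pb).sum()), int((mb & ~pb).sum())],
            [int((~mb & pb).sum()), int((~mb & ~pb).sum())],
        ],
        index=["carrier", "non-carrier"],
        columns=["phenotype+", "phenotype-"],
    )
    concordant = tab.loc["carrier", "phenotype+"] + tab.loc["non-carrier", "phenotype-"]
    return ConcordanceResult(
        concordance=concordant / n, table=tab, n=n, n_missing=n_missing
    )


def color_intensity_rule(g: MarkerGenotype) -> str:
    """Blood-flesh colour intensity from the TE / D / T haplotype combination.

    Without the blood TE every combination is non-blood (``"none"``). With
    it, only the four combinations observed in cultivars map to a class;
    anything else is the explicit ``"unclassified"`` sentinel, never a
    guessed colour.
    """
    for fieldname in ("blood_te", "d_hap", "t_hap"):
        if getattr(g, fieldname) is None:
            raise ValueError(f"genotype field {fieldname!r} required")
    if g.blood_te == "R2R2":
        return "none"
    if g.blood_te != "R1R2":
        raise ValueError(f"unknown blood_te genotype {g.blood_te!r}")
    return _COLOR_RULES.get((g.d_hap, g.t_hap), "unclassified")


def fdp_classify(fdp_days: float) -> str:
    """Bin a fruit-development period (days) into its class.

    Boundary days go to the earlier bin: [60, 90] -> 60-90,
    (90, 120] -> 90-120, (120, 150] -> 120-150; anything outside
    [60, 150] is the ``"out-of-range"`` sentinel.
    """
    if fdp_days <= 0:
        raise ValueError(f"fdp_days must be positive, got {fdp_days}")
    if 60 <= fdp_days <= 90:
        return "60-90"
    if 90 < fdp_days <= 120:
        return "90-120"
    if 120 < fdp_days <= 150:
        return "120-150"
    return "out-of-range"


def genotype_expected_fdp(ins9: str) -> str:
    """Expected FDP class of a 9 bp-insertion genotype (9/9 earliest)."""
    key = "/".join(sorted(_normalise_genotype(ins9), reverse=True))
    key = {"9/0": "0/9"}.get(key, key)
    if key not in _INS9_TO_FDP:
        raise ValueError(f"unknown 9 bp-insertion genotype {ins9!r}")
    return _INS9_TO_FDP[key]


def carrier_ratio(table: pd.DataFrame, *, group_col: str = "group",
                  carrier_col: str = "carrier") -> pd.DataFrame:
    """Per-group carrier counts and percentages.

    ``table`` has one row per accession with a group label and a boolean
    carrier flag. Returns a frame with n, carriers, percent (exact) and
    percent_int (nearest integer, the precision such surveys print).
    """
    if len(table) == 0:
        raise ValueError("empty accession table")
    rows = []
    for group, grp in table.groupby(group_col, sort=False):
        n = len(grp)
        if n == 0:
            raise ValueError(f"empty group {group!r}")
        carriers = int(grp[carrier_col].astype(bool).sum())
        pct = 100.0 * carriers / n
        rows.append(
            {"group": group, "n": n, "carriers": carriers,
             "percent": pct, "percent_int": int(round(pct))}
        )
    return pd.DataFrame(rows)
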
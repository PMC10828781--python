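"""Study-design parameters for the synthetic BSA experiment."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class SimConfig:
    """Design of a simulated F1 bulked-segregant experiment.

    Defaults mirror the study design this package models: two bulks of 15
    F1 individuals each, pooled sequencing at 30x per pool, a dominant
    causal insertion centred on a 10 Mb chromosome.

    Parameters
    ----------
    seed
        Seed for all randomness in the simulation.
    n_chrom, chrom_len
        Genome layout; chromosomes are named ``chr1..chrN``.
    snp_spacing
        Distance in bp between informative SNPs along each chromosome.
    causal_chrom, causal_pos
        Location of the causal (dominant) insertion locus.
    n_offspring
        F1 population size (the two crosses in the modelled study ranged
        from ~50 to ~130 individuals).
    bulk_size
        Individuals per phenotype pool (default 15).
    depth
        Mean read depth per site per pool (default 30).
    recomb_rate
        Uniform genetic map density, cM/Mb (Haldane mapping function).
    te_effect_on_fdp
        Ordinal advancement (in fruit-development-period classes) conferred
        by carrying the causal element; default one class earlier.
    error_rate
        Uniform per-read base-miscall probability (0 disables).
    qc_fail_fraction
        Probability, per quality-annotation clause, that a site is given a
        value failing the hard filter (exercises the site filter).
    """

    seed: int = 0
    n_chrom: int = 1
    chrom_len: int = 10_000_000
    snp_spacing: int = 2_000
    causal_chrom: str = "chr1"
    causal_pos: int = 5_000_000
    n_offspring: int = 100
    bulk_size: int = 15
    depth: float = 30.0
    recomb_rate: float = 1.0
    te_effect_on_fdp: int = 1
    error_rate: float = 0.0
    qc_fail_fraction: float = 0.0
    chrom_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"depth must be > 0, got {self.depth}")
        if not 1 <= self.causal_pos <= self.chrom_len:
            raise ValueError(
                f"causal_pos {self.causal_pos} outside [1, {self.chrom_len}]"
            )
        if self.bulk_size < 1:
            raise ValueError("bulk_size must be >= 1")
        if self.n_offspring < 2 * self.bulk_size:
            raise ValueError(
                f"n_offspring {self.n_offspring} cannot supply two bulks of "
                f"{self.bulk_size}"
            )
        if self.snp_spacing < 1 or self.chrom_len < 1 or self.n_chrom < 1:
            raise ValueError("genome layout parameters must be positive")
        self.chrom_names = tuple(f"chr{i + 1}" for i in range(self.n_chrom))
        if self.causal_chrom not in self.chrom_names:
            raise ValueError(f"causal_chrom {self.causal_chrom!r} not simulated")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chrom_names"] = list(self.chrom_names)
        return d
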
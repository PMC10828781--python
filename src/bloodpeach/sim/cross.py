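"""F1 cross simulation: Mendelian gamete sampling with Haldane recombination.

Each parent is phased (an ordered pair of haplotype alleles per locus); a
gamete picks one haplotype at the first locus of each chromosome and then
switches haplotype between adjacent loci with the Haldane probability
``r = (1 - exp(-2 d / 100)) / 2`` for map distance ``d`` in cM. Loci on
different chromosomes assort independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: ordinal fruit-development-period classes, earliest first (days)
FDP_CLASSES = ("60-90", "90-120", "120-150")


@dataclass(frozen=True)
class Locus:
    """A named marker with a genetic-map position."""

    name: str
    chrom: str = "chr1"
    cm: float = 0.0


@dataclass
class Individual:
    """One F1 offspring: per-locus ordered allele pair (parent-1 gamete first)."""

    id: str
    genotype: dict[str, tuple[str, str]]
    flesh: str | None = None
    fdp_class: str | None = None

    def dosage(self, locus: str, allele: str) -> int:
        """Copy number (0/1/2) of ``allele`` at ``locus``."""
        return sum(a == allele for a in self.genotype[locus])

    def unordered(self, locus: str) -> tuple[str, str]:
        return tuple(sorted(self.genotype[locus]))  # type: ignore[return-value]


def haldane_r(d_cm: float) -> float:
    """Recombination fraction for a map distance in centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))


def sample_gamete_haplotypes(
    loci: Sequence[Locus], n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` gametes; returns an (n, len(loci)) 0/1 haplotype-index array.

    ``loci`` must be sorted by (chrom, cm). Column j says which parental
    haplotype the gamete carries at locus j.
    """
    L = len(loci)
    H = np.empty((n, L), dtype=np.int8)
    if L == 0:
        return H
    H[:, 0] = rng.integers(0, 2, size=n)
    for j in range(1, L):
        if loci[j].chrom != loci[j - 1].chrom:
            H[:, j] = rng.integers(0, 2, size=n)
            continue
        d = loci[j].cm - loci[j - 1].cm
        if d < 0:
            raise ValueError("loci must be sorted by (chrom, cm)")
        switch = rng.random(n) < haldane_r(d)
        H[:, j] = np.where(switch, 1 - H[:, j - 1], H[:, j - 1])
    return H


def _sorted_loci(loci: Sequence[Locus]) -> list[Locus]:
    return sorted(loci, key=lambda l: (l.chrom, l.cm))


def simulate_cross(
    loci: Sequence[Locus],
    parent1: Mapping[str, tuple[str, str]],
    parent2: Mapping[str, tuple[str, str]],
    n_offspring: int,
    rng: np.random.Generator,
) -> list[Individual]:
    """Cross two phased parents and return ``n_offspring`` F1 individuals.

    ``parent1``/``parent2`` map locus name to its ordered haplotype allele
    pair. Both parents must cover exactly the loci given; a marker known to
    one parent only is an error.
    """
    loci = _sorted_loci(loci)
    names = [l.name for l in loci]
    for marker in names:
        in1, in2 = marker in parent1, marker in parent2
        if in1 != in2:
            only = "parent1" if in1 else "parent2"
            raise ValueError(f"marker {marker!r} genotyped in {only} only")
        if not in1:
            raise ValueError(f"marker {marker!r} missing from both parents")

    h1 = sample_gamete_haplotypes(loci, n_offspring, rng)
    h2 = sample_gamete_haplotypes(loci, n_offspring, rng)
    p1 = [parent1[m] for m in names]
    p2 = [parent2[m] for m in names]
    out = []
    for i in range(n_offspring):
        geno = {
            m: (p1[j][h1[i, j]], p2[j][h2[i, j]]) for j, m in enumerate(names)
        }
        out.append(Individual(id=f"F1_{i + 1:04d}", genotype=geno))
    return out


def assign_phenotypes(
    individuals: Sequence[Individual],
    *,
    te_locus: str = "blood_te",
    te_allele: str = "R1",
    ins9_locus: str = "ins9",
    te_dominant: bool = True,
    te_effect_on_fdp: int = 1,
) -> list[Individual]:
    """Set flesh colour and FDP class from genotypes (in place; returns input).

    Flesh colour follows a dominant-presence model by default: any copy of
    the element-bearing haplotype gives blood flesh. The FDP class comes
    from the 9 bp insertion genotype (9/9 earliest, 0/0 latest) and element
    carriers are advanced ``te_effect_on_fdp`` classes, floored at the
    earliest class.
    """
    for ind in individuals:
        carrier = False
        if te_locus in ind.genotype:
            copies = ind.dosage(te_locus, te_allele)
            carrier = copies >= (1 if te_dominant else 2)
            ind.flesh = "blood" if carrier else "none"
        if ins9_locus in ind.genotype:
            n9 = ind.dosage(ins9_locus, "9")
            idx = 2 - n9  # 9/9 -> 0 (earliest), 0/9 -> 1, 0/0 -> 2
            if carrier:
                idx = max(0, idx - te_effect_on_fdp)
            ind.fdp_class = FDP_CLASSES[idx]
    return list(individuals)


@dataclass
class Bulk:
    """A phenotype pool of selected individuals."""

    label: str
    members: list[Individual] = field(default_factory=list)

    def allele_frequency(self, locus: str, allele: str) -> float:
        """Pooled frequency of ``allele`` = mean dosage / 2."""
        if not self.members:
            raise ValueError(f"bulk {self.label!r} is empty")
        return float(np.mean([m.dosage(locus, allele) for m in self.members])) / 2.0


def build_bulks(
    individuals: Sequence[Individual],
    bulk_size: int,
    rng: np.random.Generator,
    *,
    phenotype: str = "flesh",
    mut_value: str = "blood",
) -> tuple[Bulk, Bulk]:
    """Draw the mutant (blood) and wild-type pools without replacement."""
    mut = [i for i in individuals if getattr(i, phenotype) == mut_value]
    wt = [i for i in individuals if getattr(i, phenotype) != mut_value
          and getattr(i, phenotype) is not None]
    if len(mut) < bulk_size or len(wt) < bulk_size:
        raise ValueError(
            f"need {bulk_size} individuals per class, have "
            f"{len(mut)} {mut_value!r} and {len(wt)} other"
        )
    pick_mut = rng.choice(len(mut), size=bulk_size, replace=False)
    pick_wt = rng.choice(len(wt), size=bulk_size, replace=False)
    return (
        Bulk("mut", [mut[i] for i in sorted(pick_mut)]),
        Bulk("wt", [wt[i] for i in sorted(pick_wt)]),
    )
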
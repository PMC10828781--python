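"""Genome fixtures: plant intact LTR retrotransposons, derive edited genomes.

An intact element is ``5'LTR + internal + 3'LTR`` inserted with a
target-site duplication (TSD): the ``tsd_len`` bp of host sequence ending at
the insertion point are duplicated on the far side of the element, as a real
integration would. Per-LTR divergence applies independent point mutations to
the two LTR copies so that planted elements have a known twin-LTR distance
for the insertion-age clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from bloodpeach.io import GffElement

_ALPHABET = np.array(list("ACGT"))


def random_genome(length: int, rng: np.random.Generator,
                  gc: float = 0.38) -> str:
    """Uniform-ish random sequence at a plant-like GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_ALPHABET, size=length, p=p))


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply point substitutions at the given per-base rate (to other bases)."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    n = rng.binomial(len(arr), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(arr), size=n, replace=False)
    for i in pos:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


@dataclass
class PlantSpec:
    """Recipe for one element insertion.

    ``insertion_point`` is 1-based: the element goes immediately after that
    host position, and the ``tsd_len`` host bases ending there are
    duplicated after the element.
    """

    id: str
    contig: str
    insertion_point: int
    ltr_seq: str
    internal_seq: str
    tsd_len: int = 5
    per_ltr_divergence: float = 0.0

    @property
    def element_length(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)


@dataclass
class PlantedElement:
    """Ground truth for one planted element (coordinates in the new genome)."""

    id: str
    contig: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    tsd: str
    seq: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def to_gff_element(self) -> GffElement:
        return GffElement(
            id=self.id, contig=self.contig, start=self.start, end=self.end,
            ltr5=self.ltr5, ltr3=self.ltr3,
        )


def random_element_spec(
    rng: np.random.Generator,
    *,
    id: str,
    contig: str,
    insertion_point: int,
    ltr_len: int = 516,
    total_len: int = 6688,
    tsd_len: int = 5,
    per_ltr_divergence: float = 0.0,
) -> PlantSpec:
    """Random intact-element recipe; defaults shaped like the blood TE
    (6688 bp total with 516 bp LTRs)."""
    internal = random_genome(total_len - 2 * ltr_len, rng)
    ltr = random_genome(ltr_len, rng)
    return PlantSpec(
        id=id, contig=contig, insertion_point=insertion_point,
        ltr_seq=ltr, internal_seq=internal, tsd_len=tsd_len,
        per_ltr_divergence=per_ltr_divergence,
    )


def plant_elements(
    genome: Mapping[str, str],
    specs: Sequence[PlantSpec],
    rng: np.random.Generator | None = None,
    *,
    length_bounds: tuple[int, int] | None = (2000, 7000),
) -> tuple[dict[str, str], list[PlantedElement]]:
    """Insert elements into ``genome``; return the new genome and truth table.

    Truth coordinates are 1-based inclusive in the *output* genome; the LTR
    spans bracket the element. Raises if two insertions' TSD windows
    overlap (the elements would interleave) or an insertion point is out of
    range.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    by_contig: dict[str, list[PlantSpec]] = {}
    for s in specs:
        if s.contig not in genome:
            raise KeyError(f"spec {s.id}: unknown contig {s.contig!r}")
        if not s.tsd_len <= s.insertion_point <= len(genome[s.contig]):
            raise ValueError(
                f"spec {s.id}: insertion point {s.insertion_point} out of range"
            )
        if length_bounds is not None and not (
            length_bounds[0] <= s.element_length <= length_bounds[1]
        ):
            raise ValueError(
                f"spec {s.id}: element length {s.element_length} outside "
                f"{length_bounds}"
            )
        by_contig.setdefault(s.contig, []).append(s)

    new_genome = {name: seq for name, seq in genome.items()}
    truth: list[PlantedElement] = []
    for contig, contig_specs in by_contig.items():
        contig_specs.sort(key=lambda s: s.insertion_point)
        for a, b in zip(contig_specs, contig_specs[1:]):
            if b.insertion_point - a.insertion_point < max(a.tsd_len, b.tsd_len):
                raise ValueError(
                    f"overlapping insertions: {a.id}, {b.id} on {contig}"
                )
        seq = genome[contig]
        pieces: list[str] = []
        prev = 0
        offset = 0
        for s in contig_specs:
            i = s.insertion_point
            tsd = seq[i - s.tsd_len : i]
            ltr5 = mutate_sequence(s.ltr_seq, s.per_ltr_divergence, rng)
            ltr3 = mutate_sequence(s.ltr_seq, s.per_ltr_divergence, rng)
            elem = ltr5 + s.internal_seq + ltr3
            pieces.append(seq[prev:i])
            pieces.append(elem + tsd)
            start = i + offset + 1
            end = start + len(elem) - 1
            truth.append(
                PlantedElement(
                    id=s.id, contig=contig, start=start, end=end,
                    ltr5=(start, start + len(ltr5) - 1),
                    ltr3=(end - len(ltr3) + 1, end),
                    tsd=tsd, seq=elem,
                )
            )
            offset += len(elem) + s.tsd_len
            prev = i
        pieces.append(seq[prev:])
        new_genome[contig] = "".join(pieces)
    truth.sort(key=lambda e: (e.contig, e.start))
    return new_genome, truth


@dataclass
class Edit:
    """Per-element action for :func:`derive_target_genome`.

    ``action`` is one of ``keep`` (element intact in the target),
    ``delete_element`` (clean excision incl. one TSD copy — the target
    never saw the insertion), ``degrade_element`` (mutate the element body
    to ``identity``), ``delete_flank`` (remove ``flank_len`` bp next to the
    element so anchoring must fail).
    """

    action: str = "keep"
    identity: float = 0.85
    flank_side: str = "up"
    flank_len: int = 500

    _ACTIONS = ("keep", "delete_element", "degrade_element", "delete_flank")

    def __post_init__(self) -> None:
        if self.action not in self._ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")


def _expected_label(edit: Edit, hi_id: float, lo_id: float) -> str:
    if edit.action == "keep":
        return "HIGH_SHARED"
    if edit.action == "delete_element":
        return "INSERTION"
    if edit.action == "delete_flank":
        return "UNKNOWN"
    # degrade: label follows where the target identity lands
    if edit.identity >= hi_id:
        return "HIGH_SHARED"
    if edit.identity >= lo_id:
        return "LOW_SHARED"
    return "ELIMINATION"


def derive_target_genome(
    query_genome: Mapping[str, str],
    truth: Sequence[PlantedElement],
    edits: Mapping[str, Edit | str],
    rng: np.random.Generator | None = None,
    *,
    hi_id: float = 0.95,
    lo_id: float = 0.80,
) -> tuple[dict[str, str], dict[str, str]]:
    """Apply per-element edits to a copy of the query genome.

    Returns ``(target genome, expected class label per element id)``.
    Elements not named in ``edits`` are kept. String values in ``edits``
    are shorthand for ``Edit(action=...)``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    by_id = {e.id: e for e in truth}
    for eid in edits:
        if eid not in by_id:
            raise KeyError(f"edit references unknown element id {eid!r}")
    norm: dict[str, Edit] = {}
    for e in truth:
        ed = edits.get(e.id, Edit("keep"))
        if isinstance(ed, str):
            ed = Edit(ed)
        norm[e.id] = ed

    target = {name: list(seq) for name, seq in query_genome.items()}
    expected: dict[str, str] = {}
    # apply right-to-left so earlier coordinates stay valid
    for el in sorted(truth, key=lambda e: (e.contig, -e.start)):
        ed = norm[el.id]
        seq = target[el.contig]
        s0, e0 = el.start - 1, el.end  # python slice of the element
        if ed.action == "delete_element":
            # remove element plus the downstream TSD copy: clean pre-insertion locus
            del seq[s0 : e0 + len(el.tsd)]
        elif ed.action == "degrade_element":
            body = "".join(seq[s0:e0])
            seq[s0:e0] = list(mutate_sequence(body, 1.0 - ed.identity, rng))
        elif ed.action == "delete_flank":
            if ed.flank_side == "up":
                cut_lo = max(0, s0 - ed.flank_len)
                del seq[cut_lo:s0]
            else:
                del seq[e0 : e0 + ed.flank_len]
        expected[el.id] = _expected_label(ed, hi_id, lo_id)
    return {name: "".join(seq) for name, seq in target.items()}, expected


def build_pav_fixture(
    n_elements: int,
    actions: Sequence[Edit | str],
    seed: int,
    *,
    contig_len: int | None = None,
    element_total_len: int = 3000,
    ltr_len: int = 300,
    spacing: int = 4000,
    per_ltr_divergence: float = 0.0,
) -> tuple[dict[str, str], list[PlantedElement], dict[str, str], dict[str, str]]:
    """One-call presence/absence test fixture.

    Plants ``n_elements`` elements evenly spaced on one contig of a random
    genome, then derives a target genome applying ``actions`` cyclically.
    Returns ``(query genome, truth table, target genome, expected labels)``.
    """
    rng = np.random.default_rng(seed)
    step = element_total_len + spacing
    if contig_len is None:
        contig_len = step * n_elements + 2 * spacing
    base = {"tig1": random_genome(contig_len, rng)}
    specs = [
        random_element_spec(
            rng, id=f"elem{i + 1:03d}", contig="tig1",
            insertion_point=spacing + i * step,
            ltr_len=ltr_len, total_len=element_total_len,
            per_ltr_divergence=per_ltr_divergence,
        )
        for i in range(n_elements)
    ]
    query, truth = plant_elements(base, specs, rng)
    edits = {
        t.id: (a if isinstance(a, Edit) else Edit(a))
        for t, a in zip(truth, [actions[i % len(actions)] for i in range(n_elements)])
    }
    target, expected = derive_target_genome(query, truth, edits, rng)
    return query, truth, target, expected
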
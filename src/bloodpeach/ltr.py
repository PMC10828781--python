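"""Cross-genome LTR-retrotransposon presence/absence classification and dating.

The approach anchors each intact element by its 500 bp flanking fragments:
both flanks are aligned to the target genome, and only elements whose two
flanks align *uniquely*, to the same target contig, in the same orientation
and within 20 kb of each other are interpretable. The geometry of the two
anchors then says whether the element's locus in the target carries the
insertion (inner gap about the element length), lacks it (anchors nearly
adjacent), or is uninterpretable. Present loci are typed by aligning the
query's middle sequence (the element) against the target span between the
anchors:

* ``HIGH_SHARED``  — identity >= 95% and coverage >= 95%
* ``LOW_SHARED``   — identity >= 80% and coverage >= 50%
* ``ELIMINATION``  — locus present but the element body decayed below that
* ``INSERTION``    — element in the query only (clean pre-insertion locus)
* ``UNKNOWN``      — anchoring failed (non-unique, cross-contig, > 20 kb …)

Anchoring uses an exact 31-mer seeded, ungapped +1/−1 extension aligner —
deliberately simple so that desk-scale runs are deterministic; externally
produced hits can be supplied instead for real assemblies.

Insertion ages use the twin-LTR clock: the two LTRs are identical at
integration, so the Jukes–Cantor distance K between them divided by twice
the substitution rate estimates the insertion time, T = K / (2 mu).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from bloodpeach.io import GenomeIndex, GffElement

HIGH_SHARED = "HIGH_SHARED"
LOW_SHARED = "LOW_SHARED"
INSERTION = "INSERTION"
ELIMINATION = "ELIMINATION"
UNKNOWN = "UNKNOWN"
LABELS = (HIGH_SHARED, LOW_SHARED, INSERTION, ELIMINATION, UNKNOWN)


@dataclass(frozen=True)
class LtrElement:
    """An intact LTR retrotransposon, 1-based inclusive coordinates."""

    id: str
    contig: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.start <= self.ltr5[0] <= self.ltr5[1]
                < self.ltr3[0] <= self.ltr3[1] <= self.end):
            raise ValueError(
                f"{self.id}: LTR spans must lie inside [{self.start}, {self.end}] "
                "in order and not overlap"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @classmethod
    def from_gff(cls, g: GffElement) -> "LtrElement":
        return cls(id=g.id, contig=g.contig, start=g.start, end=g.end,
                   ltr5=g.ltr5, ltr3=g.ltr3)


def filter_intact(
    elements: Sequence[LtrElement], bounds: tuple[int, int] = (2000, 7000)
) -> list[LtrElement]:
    """Keep elements whose total length is within ``bounds`` (inclusive)."""
    lo, hi = bounds
    return [e for e in elements if lo <= e.length <= hi]


@dataclass
class Flanks:
    """500 bp (default) fragments immediately up/downstream of an element."""

    up: str | None
    down: str | None
    up_span: tuple[int, int] | None
    down_span: tuple[int, int] | None


def extract_flanks(
    element: LtrElement,
    genome: GenomeIndex,
    flank_len: int = 500,
    min_flank: int = 100,
) -> Flanks:
    """Extract both flanks, clipped at contig ends.

    A flank shorter than ``min_flank`` after clipping is returned as None —
    such elements cannot be anchored and are classified UNKNOWN.
    """
    if element.contig not in genome:
        raise KeyError(f"{element.id}: contig {element.contig!r} not in genome")
    L = genome.lengths[element.contig]
    if element.start < 1 or element.end > L:
        raise ValueError(f"{element.id}: element outside contig bounds")
    up_s, up_e = max(1, element.start - flank_len), element.start - 1
    dn_s, dn_e = element.end + 1, min(L, element.end + flank_len)
    up = down = None
    up_span = down_span = None
    if up_e - up_s + 1 >= min_flank:
        up = genome.fetch(element.contig, up_s, up_e)
        up_span = (up_s, up_e)
    if dn_e - dn_s + 1 >= min_flank:
        down = genome.fetch(element.contig, dn_s, dn_e)
        down_span = (dn_s, dn_e)
    return Flanks(up=up, down=down, up_span=up_span, down_span=down_span)


# ---------------------------------------------------------------------------
# exact-seed ungapped aligner

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_hashes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(hashes, 0-based start positions) of all valid k-mers.

    The hash is the exact 2-bit packing of the k-mer (injective for
    k <= 31), so seed matches are exact matches, never collisions.
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, np.int64)
    h = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        h |= (codes[j : j + n].astype(np.uint64) & np.uint64(3)) << np.uint64(2 * j)
    bad = np.concatenate([[0], np.cumsum(codes >= 4)])
    valid = (bad[k:] - bad[:-k]) == 0
    pos = np.flatnonzero(valid).astype(np.int64)
    return h[valid], pos


class TargetIndex:
    """Sorted exact k-mer index over every contig of a target genome."""

    def __init__(self, genome: GenomeIndex, k: int = 31):
        self.genome = genome
        self.k = k
        self._contigs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for name in genome:
            codes = _encode(genome.sequence(name))
            hashes, pos = _kmer_hashes(codes, k)
            order = np.argsort(hashes, kind="stable")
            self._contigs[name] = (hashes[order], pos[order], codes)

    def seed_positions(self, contig: str, query_hashes: np.ndarray,
                       query_pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """All (target_pos, query_pos) exact seed matches on one contig."""
        hashes, pos, _ = self._contigs[contig]
        lo = np.searchsorted(hashes, query_hashes, side="left")
        hi = np.searchsorted(hashes, query_hashes, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            return np.empty(0, np.int64), np.empty(0, np.int64)
        tpos = np.concatenate([pos[l:h] for l, h in zip(lo, hi) if h > l])
        qpos = np.repeat(query_pos[counts > 0], counts[counts > 0])
        return tpos, qpos

    def codes(self, contig: str) -> np.ndarray:
        return self._contigs[contig][2]


@dataclass
class AnchorHit:
    """Best placement of one flank on the target genome."""

    side: str  # "up" | "down"
    contig: str
    start: int  # 1-based target start of the flank alignment
    end: int  # 1-based inclusive
    orientation: str  # "+" | "-"
    score: float
    second_best_score: float
    unique: bool


def _ungapped_score(qcodes: np.ndarray, tcodes: np.ndarray, tstart: int) -> tuple[float, int, int]:
    """Score (+1 match / −1 mismatch) of the flank laid on the target at
    0-based offset ``tstart``; returns (score, clip_start, overlap_len)."""
    L = len(qcodes)
    q0 = max(0, -tstart)
    t0 = tstart + q0
    n = min(L - q0, len(tcodes) - t0)
    if n <= 0:
        return -np.inf, q0, 0
    q = qcodes[q0 : q0 + n]
    t = tcodes[t0 : t0 + n]
    matches = int(np.count_nonzero((q == t) & (q < 4)))
    return float(2 * matches - n), q0, n


def anchor_flank(
    flank: str,
    target: TargetIndex,
    *,
    side: str = "up",
    margin: float | None = None,
    min_score: float | None = None,
) -> AnchorHit | None:
    """Place a flank on the target with the exact-seed, ungapped aligner.

    Candidate loci are seed diagonals clustered within one flank length;
    each is scored by full ungapped extension. The hit is ``unique`` iff
    the best score clears ``min_score`` (default half the flank length) and
    exceeds the runner-up by ``margin`` (default 10% of the flank length).
    Returns None when no seed matches at all.
    """
    if not flank:
        raise ValueError("empty flank sequence")
    L = len(flank)
    if margin is None:
        margin = max(1.0, 0.1 * L)
    if min_score is None:
        min_score = L / 2
    candidates: list[tuple[float, str, int, str]] = []  # score, contig, tstart0, orient
    for orient, seq in (("+", flank), ("-", revcomp(flank))):
        qcodes = _encode(seq)
        qh, qp = _kmer_hashes(qcodes, target.k)
        if len(qh) == 0:
            continue
        for contig in target.genome:
            tpos, qpos = target.seed_positions(contig, qh, qp)
            if len(tpos) == 0:
                continue
            diags = np.unique(tpos - qpos)
            tcodes = target.codes(contig)
            # cluster nearby diagonals (indel wobble) into one locus
            groups: list[list[int]] = [[int(diags[0])]]
            for d in diags[1:]:
                if d - groups[-1][-1] <= L:
                    groups[-1].append(int(d))
                else:
                    groups.append([int(d)])
            for grp in groups:
                best = max(
                    (_ungapped_score(qcodes, tcodes, d) + (d,) for d in grp),
                    key=lambda t: t[0],
                )
                score, q0, n = best[0], best[1], best[2]
                if n > 0:
                    candidates.append((score, contig, best[3] + q0, orient))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    score, contig, t0, orient = candidates[0]
    second = candidates[1][0] if len(candidates) > 1 else -np.inf
    unique = score >= min_score and (score - second) >= margin
    return AnchorHit(
        side=side,
        contig=contig,
        start=int(t0) + 1,
        end=int(t0) + L,
        orientation=orient,
        score=score,
        second_best_score=float(second),
        unique=unique,
    )


@dataclass
class AnchorGeometry:
    """Relative placement of the two flank anchors on the target."""

    kind: str  # "present" | "absent" | "other" | "unanchored"
    contig: str | None = None
    gap: int | None = None  # inner distance between the anchors (bp)
    inner_span: tuple[int, int] | None = None  # target span between anchors


def pair_anchors(
    up: AnchorHit | None,
    down: AnchorHit | None,
    element: LtrElement,
    *,
    max_anchor_span: int = 20_000,
    gap_tol: int = 1_000,
    len_tol: float = 0.2,
) -> AnchorGeometry:
    """Combine the two flank hits into a locus geometry.

    Retained only when both hits are unique, on the same contig, in the
    same orientation, and the inner distance between them is <= 20 kb;
    anything else is ``unanchored`` (classified UNKNOWN). A retained locus
    is ``absent`` when the anchors are (nearly) adjacent, ``present`` when
    their inner gap is within ±``len_tol`` of the element length, and
    ``other`` otherwise.
    """
    if (
        up is None or down is None
        or not (up.unique and down.unique)
        or up.contig != down.contig
        or up.orientation != down.orientation
    ):
        return AnchorGeometry(kind="unanchored")
    left, right = (up, down) if up.start <= down.start else (down, up)
    gap = right.start - left.end - 1
    if abs(gap) > max_anchor_span:
        return AnchorGeometry(kind="unanchored")
    geom = AnchorGeometry(
        kind="other",
        contig=up.contig,
        gap=gap,
        inner_span=(left.end + 1, right.start - 1) if gap > 0 else None,
    )
    if gap <= gap_tol:
        geom.kind = "absent"
    elif abs(gap - element.length) <= len_tol * element.length:
        geom.kind = "present"
    return geom


# ---------------------------------------------------------------------------
# classification

@dataclass
class ClassLabel:
    """Five-way call for one element with its supporting evidence."""

    element_id: str
    label: str
    identity: float | None = None
    coverage: float | None = None
    anchor_gap: int | None = None
    geometry: str | None = None


def middle_alignment_stats(query_middle: str, target_span: str) -> tuple[float, float]:
    """(identity, coverage) of the element body against the target span.

    Identity is 1 − edit distance / max(len); coverage is the target span
    length as a fraction of the element length (capped at 1).
    """
    import edlib

    if not query_middle:
        raise ValueError("empty query middle sequence")
    if not target_span:
        return 0.0, 0.0
    res = edlib.align(query_middle, target_span, mode="NW", task="distance")
    identity = 1.0 - res["editDistance"] / max(len(query_middle), len(target_span))
    coverage = min(1.0, len(target_span) / len(query_middle))
    return identity, coverage


def classify_element(
    element: LtrElement,
    geometry: AnchorGeometry,
    query_middle: str | None = None,
    target_genome: GenomeIndex | None = None,
    *,
    hi_id: float = 0.95,
    hi_cov: float = 0.95,
    lo_id: float = 0.80,
    lo_cov: float = 0.50,
) -> ClassLabel:
    """Turn anchor geometry (+ middle alignment where applicable) into a label."""
    out = ClassLabel(element_id=element.id, label=UNKNOWN,
                     anchor_gap=geometry.gap, geometry=geometry.kind)
    if geometry.kind == "absent":
        out.label = INSERTION
        return out
    if geometry.kind != "present":
        return out
    if query_middle is None or target_genome is None or geometry.inner_span is None:
        raise ValueError(f"{element.id}: present locus needs sequences to compare")
    span = target_genome.fetch(geometry.contig, *geometry.inner_span)
    identity, coverage = middle_alignment_stats(query_middle, span)
    out.identity, out.coverage = identity, coverage
    if identity >= hi_id and coverage >= hi_cov:
        out.label = HIGH_SHARED
    elif identity >= lo_id and coverage >= lo_cov:
        out.label = LOW_SHARED
    else:
        out.label = ELIMINATION
    return out


# ---------------------------------------------------------------------------
# insertion-age dating

@dataclass
class AgeEstimate:
    """Twin-LTR insertion age: raw divergence d, JC distance K, T = K/(2 mu)."""

    d: float
    K: float
    mu: float
    T: float


def estimate_age(ltr5_seq: str, ltr3_seq: str, mu: float = 1.5e-8) -> AgeEstimate:
    """Date an insertion from the divergence between its two LTRs.

    The LTR copies are globally aligned (Needleman–Wunsch); ``d`` is the
    mismatch proportion over gap-free columns, corrected with Jukes–Cantor
    K = −(3/4)·ln(1 − 4d/3) and converted to years with T = K / (2·mu).
    ``mu`` is the substitution rate in subs/site/year. Raises on JC
    saturation (d >= 0.75).
    """
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("both LTR sequences are required")
    if mu <= 0:
        raise ValueError("mu must be > 0")
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=2, mismatch_score=-1,
        open_gap_score=-5, extend_gap_score=-0.5,
    )
    aln = aligner.align(ltr5_seq.upper(), ltr3_seq.upper())[0]
    blocks_q, blocks_t = aln.aligned
    columns = mismatches = 0
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        a, b = ltr5_seq.upper()[qs:qe], ltr3_seq.upper()[ts:te]
        columns += len(a)
        mismatches += sum(x != y for x, y in zip(a, b))
    if columns == 0:
        raise ValueError("LTR sequences share no aligned columns")
    d = mismatches / columns
    if d >= 0.75:
        raise ValueError(f"JC saturation: d = {d:.3f} >= 0.75")
    K = -0.75 * np.log(1.0 - 4.0 * d / 3.0) + 0.0  # +0.0 normalises -0.0
    return AgeEstimate(d=d, K=float(K), mu=mu, T=float(K / (2.0 * mu)))


def element_age(element: LtrElement, genome: GenomeIndex,
                mu: float = 1.5e-8) -> AgeEstimate:
    """Age of one annotated element from its genome sequence."""
    ltr5 = genome.fetch(element.contig, *element.ltr5)
    ltr3 = genome.fetch(element.contig, *element.ltr3)
    return estimate_age(ltr5, ltr3, mu)


# ---------------------------------------------------------------------------
# model / results

@dataclass
class LtrParams:
    """Tunable thresholds of the presence/absence comparison."""

    flank_len: int = 500
    min_flank: int = 100
    k: int = 31
    min_score: float | None = None  # default: flank_len / 2
    margin: float | None = None  # default: 0.1 * flank_len
    max_anchor_span: int = 20_000
    gap_tol: int = 1_000
    len_tol: float = 0.2
    hi_id: float = 0.95
    hi_cov: float = 0.95
    lo_id: float = 0.80
    lo_cov: float = 0.50
    length_bounds: tuple[int, int] = (2000, 7000)
    mu: float = 1.5e-8


class LtrComparison:
    """Classify a query genome's intact elements against a target genome.

    Parameters
    ----------
    query_genome, target_genome
        :class:`~bloodpeach.io.GenomeIndex` or plain ``{contig: seq}``.
    elements
        Intact-element annotations on the query genome.
    params
        :class:`LtrParams`; all thresholds configurable.
    anchors
        Optional externally produced hits, mapping ``(element_id, side)``
        to :class:`AnchorHit` — substitutes for the internal aligner.
    """

    def __init__(
        self,
        query_genome: GenomeIndex | Mapping[str, str],
        elements: Iterable[LtrElement | GffElement],
        target_genome: GenomeIndex | Mapping[str, str],
        params: LtrParams | None = None,
        anchors: Mapping[tuple[str, str], AnchorHit] | None = None,
    ):
        self.query = (query_genome if isinstance(query_genome, GenomeIndex)
                      else GenomeIndex(query_genome))
        self.target = (target_genome if isinstance(target_genome, GenomeIndex)
                       else GenomeIndex(target_genome))
        self.elements = [
            e if isinstance(e, LtrElement) else LtrElement.from_gff(e)
            for e in elements
        ]
        self.params = params or LtrParams()
        self.anchors = dict(anchors) if anchors else {}

    def fit(self) -> "LtrComparisonResults":
        p = self.params
        intact = filter_intact(self.elements, p.length_bounds)
        index = TargetIndex(self.target, k=p.k)
        calls: list[ClassLabel] = []
        ages: dict[str, AgeEstimate | None] = {}
        for el in intact:
            flanks = extract_flanks(el, self.query, p.flank_len, p.min_flank)
            hits = {}
            for side, seq in (("up", flanks.up), ("down", flanks.down)):
                if (el.id, side) in self.anchors:
                    hits[side] = self.anchors[(el.id, side)]
                elif seq is None:
                    hits[side] = None
                else:
                    hits[side] = anchor_flank(
                        seq, index, side=side,
                        margin=p.margin, min_score=p.min_score,
                    )
            geometry = pair_anchors(
                hits["up"], hits["down"], el,
                max_anchor_span=p.max_anchor_span,
                gap_tol=p.gap_tol, len_tol=p.len_tol,
            )
            middle = self.query.fetch(el.contig, el.start, el.end)
            calls.append(
                classify_element(
                    el, geometry, middle, self.target,
                    hi_id=p.hi_id, hi_cov=p.hi_cov,
                    lo_id=p.lo_id, lo_cov=p.lo_cov,
                )
            )
            try:
                ages[el.id] = element_age(el, self.query, p.mu)
            except ValueError:
                ages[el.id] = None
        return LtrComparisonResults(
            model=self, intact_elements=intact, calls=calls, ages=ages
        )


@dataclass
class LtrComparisonResults:
    """Per-element labels, evidence and insertion ages."""

    model: LtrComparison
    intact_elements: list[LtrElement]
    calls: list[ClassLabel]
    ages: dict[str, AgeEstimate | None]
    table: pd.DataFrame = field(init=False, repr=False)

    def __post_init__(self) -> None:
        rows = []
        for el, call in zip(self.intact_elements, self.calls):
            age = self.ages.get(el.id)
            rows.append(
                {
                    "id": el.id,
                    "contig": el.contig,
                    "start": el.start,
                    "end": el.end,
                    "length": el.length,
                    "label": call.label,
                    "identity": call.identity,
                    "coverage": call.coverage,
                    "anchor_gap": call.anchor_gap,
                    "geometry": call.geometry,
                    "d": age.d if age else np.nan,
                    "K": age.K if age else np.nan,
                    "T_years": age.T if age else np.nan,
                }
            )
        self.table = pd.DataFrame(
            rows,
            columns=["id", "contig", "start", "end", "length", "label",
                     "identity", "coverage", "anchor_gap", "geometry",
                     "d", "K", "T_years"],
        )

    @property
    def class_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(LABELS, 0)
        counts.update(self.table["label"].value_counts().to_dict())
        return counts

    def labels(self) -> dict[str, str]:
        return dict(zip(self.table["id"], self.table["label"]))

    def summary(self) -> str:
        p = self.model.params
        lines = [
            "LTR-RT presence/absence comparison",
            "=" * 60,
            f"{len(self.model.elements)} annotated, "
            f"{len(self.intact_elements)} intact in {p.length_bounds} bp",
            f"flanks {p.flank_len} bp, uniqueness margin "
            f"{p.margin if p.margin is not None else 0.1 * p.flank_len:g}, "
            f"anchor span <= {p.max_anchor_span} bp",
            f"thresholds: high >= {p.hi_id:.0%}/{p.hi_cov:.0%}, "
            f"low >= {p.lo_id:.0%}/{p.lo_cov:.0%}",
            f"substitution rate mu = {p.mu:g} subs/site/year",
        ]
        for label in LABELS:
            lines.append(f"  {label:<12} {self.class_counts[label]}")
        dated = self.table["T_years"].dropna()
        if len(dated):
            lines.append(
                f"median insertion age {dated.median() / 1e6:.2f} My "
                f"({len(dated)} dated elements)"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def run_summary(self) -> dict:
        from dataclasses import asdict

        return {
            "params": asdict(self.model.params),
            "n_intact": len(self.intact_elements),
            "class_counts": self.class_counts,
        }
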
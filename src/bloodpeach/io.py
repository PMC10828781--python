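"""Readers, writers and coordinate plumbing shared by all stages.

Conventions: coordinates are 1-based inclusive everywhere inside the
package; conversion to BED's 0-based half-open happens only at the output
boundary (:func:`interval_to_bed` / :func:`bed_to_interval`).

The SNP site table is a :class:`pandas.DataFrame` with one row per site and
the columns in :data:`SITE_COLUMNS` (per-pool A/C/G/T read depths for the
mutant = blood pool and the wild-type = non-blood pool, plus the GATK-style
quality annotations used by the hard filter). Extra columns — e.g. the
simulator's ``truth_*`` ground-truth frequencies — ride along untouched.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

#: canonical site-table columns (TSV dialect written by the simulator)
SITE_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "A_mut",
    "C_mut",
    "G_mut",
    "T_mut",
    "A_wt",
    "C_wt",
    "G_wt",
    "T_wt",
    "qd",
    "fs",
    "mq",
    "mq_rank_sum",
    "read_pos_rank_sum",
    "dp",
]


class GenomeIndex:
    """Random access to contig sequences, 1-based inclusive.

    Wraps either an in-memory ``{contig: sequence}`` mapping or a
    ``pyfaidx.Fasta`` handle behind the same two-method surface.
    """

    def __init__(self, seqs: Mapping[str, str]):
        self._seqs = {name: str(s).upper() for name, s in seqs.items()}
        self.lengths = {name: len(s) for name, s in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``contig`` from ``start`` to ``end`` (1-based inclusive)."""
        if contig not in self._seqs:
            raise KeyError(f"unknown contig {contig!r}")
        L = self.lengths[contig]
        if start < 1 or end > L or start > end:
            raise ValueError(
                f"slice [{start}, {end}] out of bounds for {contig} (length {L})"
            )
        return self._seqs[contig][start - 1 : end]

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    def __iter__(self):
        return iter(self._seqs)


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Contig lengths from a ``.fai`` index or any two-column TSV (name, length)."""
    df = pd.read_csv(path, sep="\t", header=None)
    return dict(zip(df[0].astype(str), df[1].astype(int)))


# ---------------------------------------------------------------------------
# site tables


def write_sites(sites: pd.DataFrame, path: str | Path) -> None:
    # %.17g guarantees float64 values survive the text round-trip exactly
    sites.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_sites(path: str | Path, dialect: str = "tsv", *,
               mut_sample: str | None = None,
               wt_sample: str | None = None) -> pd.DataFrame:
    """Load a SNP site table.

    ``dialect='tsv'`` reads the package's own tab-separated layout;
    ``dialect='vcf'`` reads a VCF with per-sample ``AD`` (allelic depth),
    mapping ``mut_sample``/``wt_sample`` to the blood and non-blood pools.
    Malformed rows (negative depths, bad positions) are dropped and reported
    to stderr with their line numbers.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"site table missing columns: {missing}")
        depth_cols = [f"{b}_{p}" for p in ("mut", "wt") for b in BASES]
        bad = (df[depth_cols] < 0).any(axis=1) | (df["pos"] < 1)
        if bad.any():
            for idx in df.index[bad]:
                # +2: header line plus 1-based numbering
                print(f"{path}: line {idx + 2}: malformed row dropped",
                      file=sys.stderr)
            df = df[~bad].reset_index(drop=True)
        return df
    if dialect == "vcf":
        if mut_sample is None or wt_sample is None:
            raise ValueError("VCF input needs mut_sample and wt_sample names")
        return _read_sites_vcf(path, mut_sample, wt_sample)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_sites_vcf(path: str | Path, mut_sample: str, wt_sample: str) -> pd.DataFrame:
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    for s in (mut_sample, wt_sample):
        if s not in samples:
            raise ValueError(f"sample {s!r} not in VCF (has {samples})")
    rows = []
    for rec in vf:
        alleles = [rec.ref] + list(rec.alts or ())
        depths = {}
        ok = True
        for label, sample in (("mut", mut_sample), ("wt", wt_sample)):
            ad = rec.samples[sample].get("AD")
            counts = dict.fromkeys(BASES, 0)
            if ad is not None:
                for allele, d in zip(alleles, ad):
                    if d is None:
                        continue
                    if allele in counts:
                        counts[allele] += int(d)
                    else:
                        ok = False  # indel / symbolic allele: skip site
            depths[label] = counts
        if not ok:
            continue
        info = rec.info
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": rec.ref,
            **{f"{b}_mut": depths["mut"][b] for b in BASES},
            **{f"{b}_wt": depths["wt"][b] for b in BASES},
            "qd": info.get("QD", np.nan),
            "fs": info.get("FS", np.nan),
            "mq": info.get("MQ", np.nan),
            "mq_rank_sum": info.get("MQRankSum", np.nan),
            "read_pos_rank_sum": info.get("ReadPosRankSum", np.nan),
            "dp": info.get("DP", np.nan),
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


# ---------------------------------------------------------------------------
# intervals / BED


def interval_to_bed(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> BED 0-based half-open (start-1, end)."""
    if start < 1:
        raise ValueError(f"1-based start must be >= 1, got {start}")
    if end < start:
        raise ValueError(f"end {end} < start {start}")
    return start - 1, end


def bed_to_interval(bed_start: int, bed_end: int) -> tuple[int, int]:
    if bed_start < 0:
        raise ValueError(f"BED start must be >= 0, got {bed_start}")
    return bed_start + 1, bed_end


def write_bed(intervals: Iterable[tuple[str, int, int, str, float]],
              path: str | Path) -> None:
    """Write (chrom, start, end, name, score) rows, internal coords in, BED out."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score in intervals:
            b0, b1 = interval_to_bed(start, end)
            fh.write(f"{chrom}\t{b0}\t{b1}\t{name}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# GFF3 for LTR-RT annotations


@dataclass
class GffElement:
    """Parsed LTR_retrotransposon feature with its two long_terminal_repeat children."""

    id: str
    contig: str
    start: int
    end: int
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]


def write_elements_gff3(elements: Iterable[GffElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for el in elements:
            fh.write(
                f"{el.contig}\tbloodpeach\tLTR_retrotransposon\t{el.start}\t{el.end}"
                f"\t.\t+\t.\tID={el.id}\n"
            )
            for tag, (s, e) in (("ltr5", el.ltr5), ("ltr3", el.ltr3)):
                fh.write(
                    f"{el.contig}\tbloodpeach\tlong_terminal_repeat\t{s}\t{e}"
                    f"\t.\t+\t.\tID={el.id}_{tag};Parent={el.id}\n"
                )


def read_elements_gff3(path: str | Path) -> list[GffElement]:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    out = []
    for feat in db.features_of_type("LTR_retrotransposon"):
        ltrs = sorted(
            (c.start, c.end)
            for c in db.children(feat, featuretype="long_terminal_repeat")
        )
        if len(ltrs) != 2:
            raise ValueError(
                f"element {feat.id} has {len(ltrs)} long_terminal_repeat children, need 2"
            )
        out.append(
            GffElement(
                id=feat.id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                ltr5=ltrs[0],
                ltr3=ltrs[1],
            )
        )
    out.sort(key=lambda e: (e.contig, e.start))
    return out


# ---------------------------------------------------------------------------
# run summaries


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_summary(path: str | Path, *, config: Mapping, seed: int | None,
                      inputs: Iterable[str | Path] = ()) -> None:
    """JSON provenance record: resolved config, seed, versions, input checksums."""
    import scipy

    summary = {
        "config": dict(config),
        "seed": seed,
        "versions": {
            "bloodpeach": __import__("bloodpeach").__version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {str(p): file_sha256(p) for p in inputs},
    }
    Path(path).write_text(json.dumps(summary, indent=2, default=str) + "\n")
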
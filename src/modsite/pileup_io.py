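"""Alignment I/O: filtered pileup construction, downsampling, and read mixing.

The pileup is the per-position observation underlying every score in the
pipeline: counts of called bases, deletions and insertions for one sample
over a single (rRNA-style) reference.  Alignments are consumed from SAM/BAM;
reads must either carry MD tags or a reference FASTA must be supplied so the
reference base column can be reconstructed.

Internal coordinates are 0-based half-open (pysam convention); everything
reported to the user is 1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import EmptyInputError, FormatError, InvalidArgumentError

BASES = "ACGT"
_BASE_TO_IDX = {b: i for i, b in enumerate(BASES)}
# pileup count columns, in file order
COUNT_COLUMNS = ["n_A", "n_C", "n_G", "n_T", "n_del", "n_ins"]

# byte-value lookup: ASCII code -> base index, 255 for anything else (incl. N)
_BYTE_LUT = np.full(256, 255, dtype=np.uint8)
for _b, _i in _BASE_TO_IDX.items():
    _BYTE_LUT[ord(_b)] = _i
    _BYTE_LUT[ord(_b.lower())] = _i
_BYTE_LUT[ord("U")] = _BASE_TO_IDX["T"]
_BYTE_LUT[ord("u")] = _BASE_TO_IDX["T"]


@dataclass(frozen=True)
class AlignmentFilterConfig:
    """Which alignments contribute to a pileup.

    Defaults implement the preprocessing contract of the targeted protocol:
    secondary/supplementary alignments are dropped, MAPQ must be at least 1
    (removes unmapped and ambiguously placed reads), and only sense-strand
    reads count, because the targeted adapter yields forward reads and
    antisense molecules are a library artefact.
    """

    exclude_secondary: bool = True
    exclude_supplementary: bool = True
    min_mapq: int = 1
    forward_strand_only: bool = True

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise InvalidArgumentError("min_mapq must be >= 0")

    def passes(self, read: pysam.AlignedSegment) -> bool:
        if read.is_unmapped:
            return False
        if self.exclude_secondary and read.is_secondary:
            return False
        if self.exclude_supplementary and read.is_supplementary:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        if self.forward_strand_only and read.is_reverse:
            return False
        return True


class PileupMatrix:
    """Per-position base/deletion/insertion counts for one sample.

    Attributes
    ----------
    reference : str
        Reference sequence name.
    ref_seq : str
        Reference bases (``N`` where unknown), length L.
    counts : ndarray, shape (L, 6)
        Columns ``A, C, G, T, del, ins``.  ``n_A+n_C+n_G+n_T+n_del`` is the
        read depth at the position; insertions are counted once per read
        carrying >= 1 inserted base immediately after the position (anchored
        left) and do not consume depth.
    """

    def __init__(self, reference: str, ref_seq: str, counts: np.ndarray):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 6:
            raise InvalidArgumentError("counts must have shape (L, 6)")
        if len(ref_seq) != counts.shape[0]:
            raise InvalidArgumentError("ref_seq length must match counts rows")
        if (counts < 0).any():
            raise InvalidArgumentError("negative counts")
        self.reference = reference
        self.ref_seq = ref_seq.upper().replace("U", "T")
        self.counts = counts

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        """Read depth per position (bases + deletions)."""
        return self.counts[:, :5].sum(axis=1)

    @property
    def positions(self) -> np.ndarray:
        """1-based positions."""
        return np.arange(1, self.length + 1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=COUNT_COLUMNS)
        df.insert(0, "ref_base", list(self.ref_seq))
        df.insert(0, "pos", self.positions)
        df.insert(0, "ref", self.reference)
        df["depth"] = self.depth
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PileupMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.sort_values("pos")
        return cls(
            reference=str(df["ref"].iloc[0]),
            ref_seq="".join(df["ref_base"].astype(str)),
            counts=df[COUNT_COLUMNS].to_numpy(),
        )

    def __add__(self, other: "PileupMatrix") -> "PileupMatrix":
        if other.reference != self.reference or other.length != self.length:
            raise InvalidArgumentError("cannot add pileups over different references")
        ref_seq = self.ref_seq if "N" not in self.ref_seq else other.ref_seq
        return PileupMatrix(self.reference, ref_seq, self.counts + other.counts)


def _single_reference(header: pysam.AlignmentHeader, reference_name: str | None) -> tuple[str, int]:
    names = list(header.references)
    if not names:
        raise FormatError("alignment file has no reference sequences in its header")
    if reference_name is None:
        if len(names) > 1:
            raise InvalidArgumentError(
                f"multi-reference alignment file ({len(names)} references); "
                "name the target reference explicitly"
            )
        reference_name = names[0]
    if reference_name not in names:
        raise InvalidArgumentError(f"reference {reference_name!r} not in header")
    return reference_name, header.get_reference_length(reference_name)


def _require_index(path: str | Path) -> None:
    p = str(path)
    if p.endswith(".bam") and not (
        os.path.exists(p + ".bai") or os.path.exists(p[:-4] + ".bai") or os.path.exists(p + ".csi")
    ):
        raise IOError(
            f"BAM index not found for {p}; run `samtools index {p}` (or pysam.index) first"
        )


def pileup_from_bam(
    bam_path: str | Path,
    reference_fasta: str | Path | None = None,
    filters: AlignmentFilterConfig | None = None,
    reference_name: str | None = None,
) -> PileupMatrix:
    """Build a :class:`PileupMatrix` from a SAM/BAM file.

    Only alignments passing `filters` contribute.  A deletion is counted at
    every reference position the read spans with a deletion; an insertion is
    counted once per read at the reference position immediately left of the
    inserted bases.  Reference bases come from `reference_fasta` when given,
    otherwise they are reconstructed from MD tags.

    Raises
    ------
    IOError
        Missing BAM index.
    FormatError
        Neither MD tags nor a reference FASTA available.
    EmptyInputError
        No read passes the filters.
    """
    filters = filters or AlignmentFilterConfig()
    _require_index(bam_path)
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as af:
        ref_name, length = _single_reference(af.header, reference_name)
        counts = np.zeros((length, 6), dtype=np.int64)
        ref_arr = np.full(length, ord("N"), dtype=np.uint8)
        ref_known = False

        if reference_fasta is not None:
            with pysam.FastaFile(str(reference_fasta)) as fa:
                seq = fa.fetch(ref_name)
            if len(seq) != length:
                raise FormatError("reference FASTA length does not match BAM header")
            ref_arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
            ref_known = True

        n_used = 0
        md_missing = False
        for read in af.fetch(until_eof=True):
            if read.reference_name != ref_name or not filters.passes(read):
                continue
            n_used += 1
            _accumulate_read(read, counts)
            if not ref_known:
                if read.has_tag("MD"):
                    _fill_reference_from_read(read, ref_arr)
                else:
                    md_missing = True

    if n_used == 0:
        raise EmptyInputError(f"no alignment in {bam_path} passes the filters")
    if not ref_known and md_missing and (ref_arr == ord("N")).all():
        raise FormatError(
            "reads carry no MD tag and no reference FASTA was provided; "
            "cannot reconstruct reference bases"
        )
    return PileupMatrix(ref_name, ref_arr.tobytes().decode(), counts)


def _accumulate_read(read: pysam.AlignedSegment, counts: np.ndarray) -> None:
    seq = read.query_sequence
    qbytes = np.frombuffer(seq.encode(), dtype=np.uint8) if seq else None
    rpos = read.reference_start
    qpos = 0
    for op, ln in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if qbytes is not None:
                idx = _BYTE_LUT[qbytes[qpos : qpos + ln]]
                ok = idx != 255
                np.add.at(counts, (rpos + np.nonzero(ok)[0], idx[ok]), 1)
            rpos += ln
            qpos += ln
        elif op == 2:  # D
            counts[rpos : rpos + ln, 4] += 1
            rpos += ln
        elif op == 3:  # N
            rpos += ln
        elif op == 1:  # I — anchored to the left flanking reference position
            if rpos > 0:
                counts[rpos - 1, 5] += 1
            qpos += ln
        elif op == 4:  # S
            qpos += ln
        # H, P consume nothing we track


def _fill_reference_from_read(read: pysam.AlignedSegment, ref_arr: np.ndarray) -> None:
    seq = read.get_reference_sequence().upper()
    start = read.reference_start
    ref_arr[start : start + len(seq)] = np.frombuffer(seq.encode(), dtype=np.uint8)


def _passing_reads(
    bam_path: str | Path, filters: AlignmentFilterConfig
) -> tuple[pysam.AlignmentHeader, list[pysam.AlignedSegment]]:
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as af:
        header = af.header
        reads = [r for r in af.fetch(until_eof=True) if filters.passes(r)]
    return header, reads


def write_sorted_bam(
    header: pysam.AlignmentHeader, reads: Sequence[pysam.AlignedSegment], out_path: str | Path
) -> Path:
    """Write coordinate-sorted, indexed BAM."""
    out_path = Path(out_path)
    ordered = sorted(reads, key=lambda r: (r.reference_id, r.reference_start, r.query_name))
    hd = header.to_dict()
    hd.setdefault("HD", {})
    hd["HD"]["SO"] = "coordinate"
    with pysam.AlignmentFile(str(out_path), "wb", header=pysam.AlignmentHeader.from_dict(hd)) as out:
        for r in ordered:
            out.write(r)
    pysam.index(str(out_path))
    return out_path


def downsample_bam(
    bam_path: str | Path,
    n: int,
    seed: int,
    out_path: str | Path,
    filters: AlignmentFilterConfig | None = None,
) -> Path:
    """Sample exactly `n` passing reads uniformly without replacement.

    Fixed seed gives an identical selection; asking for more reads than are
    available is an error, never a silent truncation.
    """
    filters = filters or AlignmentFilterConfig()
    header, reads = _passing_reads(bam_path, filters)
    if n > len(reads):
        raise InvalidArgumentError(
            f"requested {n} reads but only {len(reads)} pass the filters in {bam_path}"
        )
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(reads), size=n, replace=False)
    return write_sorted_bam(header, [reads[i] for i in picked], out_path)


def round_half_away(x: float) -> int:
    """Round half away from zero (0.5% of 1000 reads -> exactly 5)."""
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def mix_bams(
    bam_a: str | Path,
    bam_b: str | Path,
    n_total: int,
    fraction_a: float,
    seed: int,
    out_path: str | Path,
    filters: AlignmentFilterConfig | None = None,
) -> Path:
    """In-silico mixture: `round(n_total * fraction_a)` reads from pool A,
    the remainder from pool B, each sampled without replacement.

    Emulates mixing modified (WT) and unmodified (KO/MUT) molecules at a
    defined stoichiometry.  Provenance (read name -> source pool) is written
    to ``<out>.sources.tsv``.
    """
    if not 0.0 <= fraction_a <= 1.0:
        raise InvalidArgumentError("fraction_a must be in [0, 1]")
    filters = filters or AlignmentFilterConfig()
    n_a = round_half_away(n_total * fraction_a)
    n_b = n_total - n_a
    header_a, reads_a = _passing_reads(bam_a, filters)
    header_b, reads_b = _passing_reads(bam_b, filters)
    if n_a > len(reads_a):
        raise InvalidArgumentError(f"pool A has {len(reads_a)} reads, need {n_a}")
    if n_b > len(reads_b):
        raise InvalidArgumentError(f"pool B has {len(reads_b)} reads, need {n_b}")
    rng = np.random.default_rng(seed)
    pick_a = [reads_a[i] for i in rng.choice(len(reads_a), size=n_a, replace=False)]
    pick_b = [reads_b[i] for i in rng.choice(len(reads_b), size=n_b, replace=False)]
    out = write_sorted_bam(header_a, pick_a + pick_b, out_path)
    prov = pd.DataFrame(
        {
            "read_name": [r.query_name for r in pick_a] + [r.query_name for r in pick_b],
            "source": ["a"] * n_a + ["b"] * n_b,
        }
    )
    prov.to_csv(str(out) + ".sources.tsv", sep="\t", index=False)
    return out
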
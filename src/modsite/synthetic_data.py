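"""Synthetic direct RNA-seq error-profile data with known modification signatures.

Real targeted direct rRNA-seq yields full-length sense-strand reads over a
single reference; RNA modifications perturb basecalling not only at the
modified nucleotide but across the 5-mer the pore reads, out to offsets
-3..+3 for some marks.  This module generates references, per-position
pileup count matrices and full SAM/BAM read sets in which those signatures
are injected with known position, strength, context kernel and
stoichiometry, so every downstream stage (scoring, outlier calling,
calibration, benchmarking) can be tested against ground truth.

Error model, per read and reference position: one categorical draw over
``(match, mismatch x3, deletion, insertion)``.  A read drawn in the
insertion category calls the reference base and additionally carries a
single inserted nucleotide anchored immediately after the position, so base
counts plus deletions always conserve depth.  Replicate-to-replicate
variability is Dirichlet-multinomial: each replicate's per-position
category probabilities are drawn from a Dirichlet centred on the effective
error vector with concentration kappa (kappa = inf recovers exact
multinomial sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import InvalidArgumentError
from .pileup_io import BASES, PileupMatrix, write_sorted_bam

# category order for all probability vectors
CATEGORIES = ("match", "mm1", "mm2", "mm3", "del", "ins")
N_CAT = len(CATEGORIES)

#: typical direct RNA-seq background basecalling-error profile:
#: ~6% mismatch, 2% deletion, 1% insertion
DEFAULT_BASE_ERROR = np.array([0.91, 0.02, 0.02, 0.02, 0.02, 0.01])

#: strong base-modification signature (mismatch-dominated, as seen for
#: base methylations): 40% mismatch concentrated on one alternative base
DEFAULT_MOD_ERROR = np.array([0.50, 0.40, 0.02, 0.02, 0.04, 0.02])

KERNEL_OFFSETS = tuple(range(-3, 4))


def _check_prob_vector(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape != (N_CAT,):
        raise InvalidArgumentError(f"{name} must have {N_CAT} categories {CATEGORIES}")
    if (v < 0).any() or abs(v.sum() - 1.0) > 1e-12:
        raise InvalidArgumentError(f"{name} must be a probability vector summing to 1")
    return v


@dataclass(frozen=True)
class ReferenceSeq:
    """A single rRNA-style reference sequence (positions reported 1-based)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("U", "T")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 11:
            raise InvalidArgumentError("reference must be at least 11 nt (5-mer context)")
        if set(seq) - set(BASES):
            raise InvalidArgumentError(f"invalid characters in sequence: {set(seq) - set(BASES)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def to_fasta(self, path: str | Path, width: int = 70) -> Path:
        path = Path(path)
        lines = [f">{self.name}"]
        lines += [self.sequence[i : i + width] for i in range(0, self.length, width)]
        path.write_text("\n".join(lines) + "\n")
        try:
            pysam.faidx(str(path))
        except pysam.SamtoolsError:
            pass
        return path


@dataclass(frozen=True)
class ModProfile:
    """Error signature of one modified site.

    `base_error` is the unmodified categorical error vector, `mod_error` the
    vector of a fully modified molecule.  `context_kernel` maps offsets
    -3..+3 to weights in [0, 1] scaling how strongly the signature bleeds
    into neighbouring positions (w_0 = 1 at the site itself).
    """

    site: int  # 1-based
    base_error: np.ndarray = field(default_factory=lambda: DEFAULT_BASE_ERROR.copy())
    mod_error: np.ndarray = field(default_factory=lambda: DEFAULT_MOD_ERROR.copy())
    context_kernel: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    class_label: str = "other"

    def __post_init__(self) -> None:
        object.__setattr__(self, "base_error", _check_prob_vector(self.base_error, "base_error"))
        object.__setattr__(self, "mod_error", _check_prob_vector(self.mod_error, "mod_error"))
        if self.site < 1:
            raise InvalidArgumentError("site is 1-based and must be >= 1")
        kernel = dict(self.context_kernel)
        for off, w in kernel.items():
            if off not in KERNEL_OFFSETS:
                raise InvalidArgumentError("kernel offsets must lie in -3..+3")
            if not 0.0 <= w <= 1.0:
                raise InvalidArgumentError("kernel weights must lie in [0, 1]")
        if kernel.get(0, 1.0) != 1.0:
            raise InvalidArgumentError("kernel weight at the site itself (offset 0) must be 1")
        kernel[0] = 1.0
        object.__setattr__(self, "context_kernel", kernel)

    def weight(self, offset: int) -> float:
        return float(self.context_kernel.get(offset, 0.0))


@dataclass(frozen=True)
class SimConfig:
    """Sampling configuration for one simulated condition."""

    depth: int = 1000
    n_replicates: int = 3
    kappa: float = 2000.0  # Dirichlet concentration; inf = no overdispersion
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise InvalidArgumentError("depth must be >= 1")
        if self.n_replicates < 1:
            raise InvalidArgumentError("n_replicates must be >= 1")
        if not self.kappa > 0:
            raise InvalidArgumentError("kappa must be > 0")


def make_reference(length: int, gc: float = 0.5, seed: int = 0, name: str = "synthetic_18S") -> ReferenceSeq:
    """Random reference with the requested GC content (i.i.d. bases)."""
    if length < 11:
        raise InvalidArgumentError("length must be >= 11")
    if not 0.0 <= gc <= 1.0:
        raise InvalidArgumentError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])
    return ReferenceSeq(name=name, sequence=seq)


def effective_error(profile: ModProfile, s: float, offset: int = 0) -> np.ndarray:
    """Categorical error vector at stoichiometry `s` and context `offset`.

    Linear mixture ``(1 - s*w_o) * base_error + s*w_o * mod_error`` — the
    population average over a fraction `s` of modified molecules whose
    signature bleeds into offset `o` with kernel weight ``w_o``.
    """
    if not 0.0 <= s <= 1.0:
        raise InvalidArgumentError("stoichiometry s must be in [0, 1]")
    if offset not in KERNEL_OFFSETS:
        raise InvalidArgumentError("offset must lie in -3..+3")
    w = profile.weight(offset)
    return (1.0 - s * w) * profile.base_error + s * w * profile.mod_error


def position_error_matrix(
    ref: ReferenceSeq,
    profiles: Sequence[ModProfile],
    s: float,
    base_error: np.ndarray | None = None,
) -> np.ndarray:
    """(L, 6) per-position categorical error probabilities at stoichiometry `s`."""
    base = _check_prob_vector(
        DEFAULT_BASE_ERROR if base_error is None else np.asarray(base_error, float), "base_error"
    )
    P = np.tile(base, (ref.length, 1))
    for prof in profiles:
        if not 1 <= prof.site <= ref.length:
            raise InvalidArgumentError(f"profile site {prof.site} outside [1, {ref.length}]")
        for off in KERNEL_OFFSETS:
            pos = prof.site + off  # 1-based
            w = prof.weight(off)
            if w == 0.0 or not 1 <= pos <= ref.length:
                continue
            P[pos - 1] = (1.0 - s * w) * P[pos - 1] + s * w * prof.mod_error
    return P


def _replicate_probs(P: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """One replicate's per-position probabilities: Dirichlet(kappa * P)."""
    if not np.isfinite(kappa):
        return P
    g = rng.gamma(shape=np.maximum(kappa * P, 1e-12))
    return g / g.sum(axis=1, keepdims=True)


def _category_counts_to_pileup(ref: ReferenceSeq, cat_counts: np.ndarray) -> PileupMatrix:
    """Map (L, 6) category counts to base-space pileup counts.

    The three mismatch categories are, per position, the non-reference bases
    in alphabetical order; insertion reads call the reference base.
    """
    L = ref.length
    counts = np.zeros((L, 6), dtype=np.int64)
    ref_idx = _ref_indices(ref)
    mm = _mismatch_base_indices(ref_idx)  # (L, 3)
    counts[np.arange(L), ref_idx] = cat_counts[:, 0] + cat_counts[:, 5]
    for j in range(3):
        np.add.at(counts, (np.arange(L), mm[:, j]), cat_counts[:, 1 + j])
    counts[:, 4] = cat_counts[:, 4]
    counts[:, 5] = cat_counts[:, 5]
    return PileupMatrix(ref.name, ref.sequence, counts)


def _ref_indices(ref: ReferenceSeq) -> np.ndarray:
    lut = np.zeros(256, dtype=np.int64)
    for i, b in enumerate(BASES):
        lut[ord(b)] = i
    return lut[np.frombuffer(ref.sequence.encode(), dtype=np.uint8)]


def _mismatch_base_indices(ref_idx: np.ndarray) -> np.ndarray:
    """(L, 3) indices of the non-reference bases, alphabetical order."""
    all_idx = np.arange(4)
    out = np.empty((ref_idx.size, 3), dtype=np.int64)
    for b in range(4):
        out[ref_idx == b] = all_idx[all_idx != b]
    return out


def simulate_pileups(
    ref: ReferenceSeq,
    profiles: Sequence[ModProfile],
    s: float,
    cfg: SimConfig,
    base_error: np.ndarray | None = None,
) -> list[PileupMatrix]:
    """Draw one :class:`PileupMatrix` per replicate.

    Per replicate, per-position category probabilities are Dirichlet draws
    centred on the effective error vector (concentration ``cfg.kappa``);
    counts are multinomial at ``cfg.depth``.  Deterministic for fixed seed.
    """
    P = position_error_matrix(ref, profiles, s, base_error=base_error)
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_replicates):
        probs = _replicate_probs(P, cfg.kappa, rng)
        cat_counts = rng.multinomial(cfg.depth, probs)
        out.append(_category_counts_to_pileup(ref, cat_counts))
    return out


def _draw_read_categories(
    P: np.ndarray, n_reads: int, rng: np.random.Generator, chunk: int = 2000
) -> np.ndarray:
    """(n_reads, L) categorical draws with position-dependent probabilities."""
    L = P.shape[0]
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    out = np.empty((n_reads, L), dtype=np.int8)
    for lo in range(0, n_reads, chunk):
        hi = min(lo + chunk, n_reads)
        u = rng.random((hi - lo, L, 1))
        out[lo:hi] = (u > cum[None, :, :]).sum(axis=2, dtype=np.int8)
    return out


def _build_read(
    ref_chars: np.ndarray,
    mm_bases: np.ndarray,
    cats: np.ndarray,
    ins_bases: np.ndarray,
) -> tuple[str, list[tuple[int, int]], str]:
    """Assemble (seq, cigartuples, MD) for one full-span read.

    `cats` is the per-position category vector; `ins_bases` supplies one
    random base per position (used where cats == 5).
    """
    L = cats.size
    # called base per (non-deleted) position
    called = ref_chars.copy()
    for j in range(3):
        sel = cats == 1 + j
        called[sel] = mm_bases[sel, j]
    del_mask = cats == 4
    ins_mask = cats == 5

    seq_parts: list[str] = []
    cigar: list[tuple[int, int]] = []
    md_parts: list[str] = []
    md_run = 0

    def push_cigar(op: int, ln: int) -> None:
        if ln == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + ln)
        else:
            cigar.append((op, ln))

    i = 0
    while i < L:
        if del_mask[i]:
            j = i
            while j < L and del_mask[j]:
                j += 1
            push_cigar(2, j - i)
            md_parts.append(f"{md_run}^" + "".join(chr(c) for c in ref_chars[i:j]))
            md_run = 0
            i = j
            continue
        c = chr(called[i])
        seq_parts.append(c)
        push_cigar(0, 1)
        if called[i] == ref_chars[i]:
            md_run += 1
        else:
            md_parts.append(f"{md_run}{chr(ref_chars[i])}")
            md_run = 0
        if ins_mask[i] and i < L - 1:  # trailing insertions would be soft-clipped; skip
            seq_parts.append(chr(ins_bases[i]))
            push_cigar(1, 1)
        i += 1
    md_parts.append(str(md_run))
    return "".join(seq_parts), cigar, "".join(md_parts)


def simulate_reads(
    ref: ReferenceSeq,
    profiles: Sequence[ModProfile],
    s: float,
    cfg: SimConfig,
    out_dir: str | Path,
    prefix: str = "sim",
    base_error: np.ndarray | None = None,
) -> list[Path]:
    """Write one coordinate-sorted, indexed BAM per replicate.

    Reads are full reference span, forward strand, MAPQ 60, with MD tags —
    the read-level realisation of the :func:`simulate_pileups` model, so the
    pileup of an emitted BAM is a draw from that same distribution.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    P = position_error_matrix(ref, profiles, s, base_error=base_error)
    rng = np.random.default_rng(cfg.seed)
    ref_chars = np.frombuffer(ref.sequence.encode(), dtype=np.uint8).copy()
    mm_idx = _mismatch_base_indices(_ref_indices(ref))
    base_ords = np.frombuffer(BASES.encode(), dtype=np.uint8)
    mm_bases = base_ords[mm_idx]  # (L, 3) ASCII codes of the non-ref bases

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref.name, "LN": ref.length}],
            "PG": [{"ID": "modsite-sim", "PN": "modsite"}],
        }
    )
    paths = []
    for rep in range(cfg.n_replicates):
        probs = _replicate_probs(P, cfg.kappa, rng)
        cats = _draw_read_categories(probs, cfg.depth, rng)
        ins_bases = base_ords[rng.integers(0, 4, size=(cfg.depth, ref.length))]
        reads = []
        for k in range(cfg.depth):
            seq, cigar, md = _build_read(ref_chars, mm_bases, cats[k], ins_bases[k])
            a = pysam.AlignedSegment(header)
            a.query_name = f"{prefix}_rep{rep}_read{k}"
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = 0
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.set_tag("MD", md)
            a.set_tag("NM", int((cats[k] > 0).sum()))
            reads.append(a)
        path = out_dir / f"{prefix}_rep{rep}.bam"
        write_sorted_bam(header, reads, path)
        paths.append(path)
    return paths


def load_profile_tsv(path: str | Path) -> list[ModProfile]:
    """Read modification profiles from TSV.

    Columns: ``site, class_label, mod_mismatch, mod_del, mod_ins,
    w-3, w-2, w-1, w+1, w+2, w+3`` (kernel columns optional, default 0).
    The mismatch probability is concentrated on the first alternative base.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"site", "class_label", "mod_mismatch", "mod_del", "mod_ins"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidArgumentError(f"profile TSV missing columns: {sorted(missing)}")
    profiles = []
    for i in range(len(df)):
        row = df.iloc[i]
        mm, dl, ins = float(row["mod_mismatch"]), float(row["mod_del"]), float(row["mod_ins"])
        match = 1.0 - mm - dl - ins
        if match < 0:
            raise InvalidArgumentError(f"profile TSV row {i + 2}: error probabilities exceed 1")
        kernel = {0: 1.0}
        for off in (-3, -2, -1, 1, 2, 3):
            col = f"w{off:+d}"
            if col in df.columns:
                kernel[off] = float(row[col])
        profiles.append(
            ModProfile(
                site=int(row["site"]),
                mod_error=np.array([match, mm, 0.0, 0.0, dl, ins]),
                context_kernel=kernel,
                class_label=str(row["class_label"]),
            )
        )
    return profiles
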
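"""Paired-end pegRNA quantification and amplicon edit-frequency calling.

Read 1 identifies the construct by its 20-nt spacer (exact hash lookup,
optionally a 1-mismatch neighbourhood).  Read 2 confirms the construct
via the extension sequence, located relative to the 7-A run that is the
reverse-complemented poly-T terminator, and yields the 8-mer clonal
barcode sitting immediately 5' of that anchor.  A pair is assigned only
when both reads agree on the construct; pairs whose reads disagree (or
whose Read 2 cannot be confirmed) are dropped as discordant, which keeps
chimeric PCR artifacts from inflating counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import seqs
from .errors import PairingError, ValidationError
from .library import LibraryDesign, SampleSheet
from .simulate import ReadLayout


@dataclass
class AssignmentStats:
    """Per-sample accounting of read-pair fates.

    Invariant: ``assigned + unassigned_r1 + discordant == total_pairs``.
    ``discordant`` covers every pair whose spacer matched but whose Read 2
    failed to confirm the same construct.
    """

    total_pairs: int = 0
    assigned: int = 0
    unassigned_r1: int = 0
    discordant: int = 0
    barcode_unreadable: int = 0

    def check(self) -> None:
        if self.assigned + self.unassigned_r1 + self.discordant != self.total_pairs:
            raise AssertionError("assignment accounting does not conserve pairs")
        if self.barcode_unreadable > self.assigned:
            raise AssertionError("barcode_unreadable exceeds assigned")

    def as_dict(self) -> dict:
        d = {
            "total_pairs": self.total_pairs,
            "assigned": self.assigned,
            "unassigned_r1": self.unassigned_r1,
            "discordant": self.discordant,
            "barcode_unreadable": self.barcode_unreadable,
        }
        t = max(1, self.total_pairs)
        d.update(
            {
                "frac_assigned": self.assigned / t,
                "frac_unassigned_r1": self.unassigned_r1 / t,
                "frac_discordant": self.discordant / t,
            }
        )
        return d


@dataclass
class CountMatrix:
    """pegRNA x sample integer read counts with attached sample metadata."""

    counts: pd.DataFrame
    samples: SampleSheet

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        if list(self.counts.columns) != self.samples.sample_ids:
            raise ValidationError("count columns must match sample sheet order")

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.index.name = "construct_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, samples: SampleSheet) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="construct_id")
        return cls(df[samples.sample_ids], samples)


def _mismatch_neighbors(kmer: str):
    """All strings at Hamming distance exactly 1 from ``kmer``."""
    for i, c in enumerate(kmer):
        for b in "ACGT":
            if b != c:
                yield kmer[:i] + b + kmer[i + 1:]


def _hamming_leq(a: str, b: str, limit: int) -> bool:
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return False
    return True


def count_sample(
    r1_path: str | Path,
    r2_path: str | Path,
    lib: LibraryDesign,
    layout: ReadLayout | None = None,
    max_mismatch_spacer: int = 0,
    max_mismatch_ext: int = 1,
):
    """Quantify one sample from its paired FASTQ files.

    Returns ``(counts, barcode_rows, stats)`` where ``counts`` is a
    Series over all library constructs (zero-filled), ``barcode_rows``
    is a DataFrame (construct_id, barcode, reads) and ``stats`` is an
    :class:`AssignmentStats` with the conservation identity asserted.
    """
    if layout is None:
        layout = ReadLayout()
    if len(lib) == 0:
        raise ValidationError("cannot quantify against an empty library")
    if max_mismatch_spacer not in (0, 1):
        raise ValidationError("max_mismatch_spacer must be 0 or 1")

    spacer_to_cid: dict[str, str] = {}
    for c in lib.constructs:
        if c.spacer in spacer_to_cid:
            raise ValidationError(f"spacer {c.spacer} is not unique in the library")
        spacer_to_cid[c.spacer] = c.construct_id
    ext_rc = {c.construct_id: seqs.revcomp(c.extension) for c in lib.constructs}
    spacer_len = len(lib.constructs[0].spacer)
    off = layout.r1_spacer_offset

    anchor = "A" * len(seqs.TERMINATOR)
    anchor_expect = layout.r2_barcode_end
    jitter = layout.anchor_jitter
    lo = max(0, anchor_expect - jitter)
    hi = anchor_expect + jitter
    linker_len = len(seqs.LINKER)

    counts: dict[str, int] = {}
    bc_counts: dict[tuple[str, str], int] = {}
    stats = AssignmentStats()

    with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
        it1, it2 = iter(f1), iter(f2)
        while True:
            rec1 = next(it1, None)
            rec2 = next(it2, None)
            if rec1 is None and rec2 is None:
                break
            if rec1 is None or rec2 is None:
                raise PairingError("R1 and R2 have different record counts")
            stats.total_pairs += 1
            s1 = rec1.sequence.upper()
            kmer = s1[off: off + spacer_len]
            cid = spacer_to_cid.get(kmer)
            if cid is None and max_mismatch_spacer == 1:
                for nb in _mismatch_neighbors(kmer):
                    cid = spacer_to_cid.get(nb)
                    if cid is not None:
                        break
            if cid is None:
                stats.unassigned_r1 += 1
                continue

            s2 = rec2.sequence.upper()
            pos = s2.find(anchor, lo, hi + len(anchor))
            confirmed = False
            barcode = None
            if pos >= 0:
                # a barcode beginning with T's extends the A-run on R2;
                # the run END sits at a fixed distance from the linker
                run_end = pos + len(anchor)
                while run_end < len(s2) and s2[run_end] == "A":
                    run_end += 1
                ext_start = run_end + linker_len
                expected = ext_rc[cid]
                observed = s2[ext_start: ext_start + len(expected)]
                if len(observed) == len(expected) and _hamming_leq(
                    observed, expected, max_mismatch_ext
                ):
                    confirmed = True
                    term_start = run_end - len(seqs.TERMINATOR)
                    if term_start - seqs.BARCODE_LEN >= 0:
                        raw = s2[term_start - seqs.BARCODE_LEN: term_start]
                        if all(b in "ACGT" for b in raw):
                            barcode = seqs.revcomp(raw)
            if not confirmed:
                stats.discordant += 1
                continue

            stats.assigned += 1
            counts[cid] = counts.get(cid, 0) + 1
            if barcode is None:
                stats.barcode_unreadable += 1
            else:
                key = (cid, barcode)
                bc_counts[key] = bc_counts.get(key, 0) + 1

    stats.check()
    col = pd.Series(
        [counts.get(cid, 0) for cid in lib.construct_ids],
        index=lib.construct_ids,
        dtype=np.int64,
    )
    bc_rows = pd.DataFrame(
        [(cid, bc, n) for (cid, bc), n in bc_counts.items()],
        columns=["construct_id", "barcode", "reads"],
    )
    return col, bc_rows, stats


def merge_counts(
    columns: dict[str, pd.Series], sheet: SampleSheet, lib: LibraryDesign
) -> CountMatrix:
    """Assemble per-sample count columns into a CountMatrix.

    Constructs absent in a sample are zero-filled; column order follows
    the sample sheet.
    """
    if len(set(columns)) != len(columns):
        raise ValidationError("duplicate sample_id among count columns")
    missing = [s for s in sheet.sample_ids if s not in columns]
    if missing:
        raise ValidationError(f"no counts for samples: {missing}")
    mat = pd.DataFrame(index=lib.construct_ids)
    for sid in sheet.sample_ids:
        mat[sid] = columns[sid].reindex(lib.construct_ids).fillna(0).astype(np.int64)
    return CountMatrix(mat, sheet)


@dataclass(frozen=True)
class EditSpec:
    """A substitution edit located on a sequenced amplicon."""

    amplicon: str
    offset: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.amplicon[self.offset: self.offset + len(self.ref)] != self.ref:
            raise ValidationError("amplicon does not carry ref base(s) at offset")
        if len(self.ref) != len(self.alt):
            raise ValidationError("ref and alt must have equal length")


@dataclass
class EditFrequencyResult:
    percent: float
    n_alt: int
    n_readable: int
    n_failed_anchor: int


def edit_frequency(reads, spec: EditSpec, flank: int = 5) -> EditFrequencyResult:
    """Percent of anchored reads carrying the alternate base(s).

    Reads are anchored by an exact match of ``flank`` bases on each side
    of the edit position; reads failing anchoring (including reads with
    indels through the window) drop out of the denominator.
    """
    left = spec.amplicon[spec.offset - flank: spec.offset]
    right = spec.amplicon[
        spec.offset + len(spec.ref): spec.offset + len(spec.ref) + flank
    ]
    if len(left) < flank or len(right) < flank:
        raise ValidationError("edit too close to the amplicon end for this flank")
    n_alt = n_readable = n_failed = 0
    for read in reads:
        read = read.upper()
        idx = read.find(left)
        anchored = False
        while idx >= 0:
            base_start = idx + flank
            base_end = base_start + len(spec.ref)
            if read[base_end: base_end + flank] == right and base_end <= len(read):
                anchored = True
                break
            idx = read.find(left, idx + 1)
        if not anchored:
            n_failed += 1
            continue
        n_readable += 1
        if read[base_start:base_end] == spec.alt:
            n_alt += 1
    if n_readable == 0:
        raise ValidationError("no readable reads at the edit position")
    return EditFrequencyResult(
        percent=100.0 * n_alt / n_readable,
        n_alt=n_alt,
        n_readable=n_readable,
        n_failed_anchor=n_failed,
    )
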
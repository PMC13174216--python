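"""Clonal-barcode analysis of resistant populations.

Each lentiviral integration carries a random 8-mer barcode, so the
number of distinct barcodes recovered for a construct counts the number
of independently founded lineages behind its expansion.  Sequencing
errors spray low-count satellite barcodes around every real one; they
are absorbed by a directional-adjacency collapse (merge b into a when
Hamming(a, b) <= 1 and reads(a) >= 2*reads(b) - 1, the standard UMI
heuristic).  The per-unit report joins unique-barcode counts and
inverse-Simpson diversity with Z-scores and FDR so that recurrent
independent editing events can be told apart from single-clone
expansions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import seqs
from .library import LibraryDesign


@dataclass
class CollapseStats:
    n_skipped_bad_barcode: int = 0
    n_merged: int = 0
    n_dropped_low: int = 0


def _collapse_group(barcodes: list[str], reads: list[int]):
    """Directional-adjacency collapse within one (construct, sample)."""
    order = sorted(range(len(barcodes)), key=lambda i: (-reads[i], barcodes[i]))
    canonical: list[int] = []  # indices into barcodes
    merged_into: dict[int, int] = {}
    for i in order:
        target = None
        for j in canonical:
            if reads[j] >= 2 * reads[i] - 1 and seqs.hamming(
                barcodes[j], barcodes[i]
            ) <= 1:
                target = j
                break
        if target is None:
            canonical.append(i)
        else:
            merged_into[i] = target
    out_reads: dict[int, int] = {j: reads[j] for j in canonical}
    out_merged: dict[int, int] = {j: 1 for j in canonical}
    for i, j in merged_into.items():
        out_reads[j] += reads[i]
        out_merged[j] += 1
    return [
        (barcodes[j], out_reads[j], out_merged[j]) for j in canonical
    ], len(merged_into)


def collapse_barcodes(
    bt: pd.DataFrame, min_reads: int = 2
) -> tuple[pd.DataFrame, CollapseStats]:
    """Error-collapse a barcode table and drop sub-threshold barcodes.

    Input columns: construct_id, barcode, sample_id, reads.  Non-8-mer
    barcodes are skipped (counted in the stats).  Read totals are
    conserved by the merge step; thresholding then removes canonical
    barcodes with fewer than ``min_reads`` reads.
    """
    stats = CollapseStats()
    good = bt["barcode"].str.len() == seqs.BARCODE_LEN
    good &= bt["barcode"].str.fullmatch("[ACGT]+").fillna(False)
    stats.n_skipped_bad_barcode = int((~good).sum())
    bt = bt[good]

    rows = []
    for (cid, sid), grp in bt.groupby(["construct_id", "sample_id"], sort=False):
        merged, n_merged = _collapse_group(
            list(grp["barcode"]), list(grp["reads"].astype(int))
        )
        stats.n_merged += n_merged
        for bc, reads, n_raw in merged:
            if reads < min_reads:
                stats.n_dropped_low += 1
                continue
            rows.append(
                {
                    "construct_id": cid,
                    "canonical_barcode": bc,
                    "sample_id": sid,
                    "reads": reads,
                    "n_merged_raw_barcodes": n_raw,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "construct_id",
            "canonical_barcode",
            "sample_id",
            "reads",
            "n_merged_raw_barcodes",
        ],
    )
    return out, stats


def inverse_simpson(reads: np.ndarray) -> float:
    """Effective number of equally abundant barcodes."""
    reads = np.asarray(reads, dtype=float)
    total = reads.sum()
    if total <= 0:
        return float("nan")
    shares = reads / total
    return float(1.0 / np.sum(shares**2))


def clonality_report(
    cbt: pd.DataFrame,
    lib: LibraryDesign,
    scores: pd.DataFrame | None = None,
    results: pd.DataFrame | None = None,
    recurrent_min: int = 3,
    min_total_reads: int = 10,
    unit: str = "variant",
) -> pd.DataFrame:
    """Per-(unit, sample) barcode diversity and clonality classes.

    Classes: ``recurrent`` (>= recurrent_min unique barcodes),
    ``monoclonal`` (exactly 1), ``oligoclonal`` (in between),
    ``unpowered`` (total reads below ``min_total_reads``).  Z-scores
    (mean per unit/sample over the score table) and FDR from a results
    table are joined when provided; failed joins yield NA.
    """
    df = cbt.copy()
    vmap = {c.construct_id: c.variant_id for c in lib.constructs}
    df["variant_id"] = df["construct_id"].map(vmap)
    key = "variant_id" if unit == "variant" else "construct_id"

    rows = []
    for (uid, sid), grp in df.groupby([key, "sample_id"]):
        reads = grp["reads"].to_numpy()
        n_unique = int(len(grp))
        total = int(reads.sum())
        if total < min_total_reads:
            cls = "unpowered"
        elif n_unique >= recurrent_min:
            cls = "recurrent"
        elif n_unique == 1:
            cls = "monoclonal"
        else:
            cls = "oligoclonal"
        rows.append(
            {
                key: uid,
                "sample_id": sid,
                "n_unique_barcodes": n_unique,
                "total_reads": total,
                "effective_diversity": inverse_simpson(reads),
                "top_barcode_fraction": float(reads.max() / total) if total else np.nan,
                "clonality_class": cls,
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out

    if scores is not None and not scores.empty:
        sc = scores.copy()
        if "sample_id" not in sc.columns:
            sc["sample_id"] = (
                sc["arm"].astype(str)
                + "_d" + sc["day"].map(lambda d: f"{d:g}")
                + "_r" + sc["replicate"].astype(str)
            )
        zcol = (
            sc.groupby([key, "sample_id"])["z"].mean().rename("z").reset_index()
        )
        out = out.merge(zcol, on=[key, "sample_id"], how="left")
    if results is not None and not results.empty:
        res = results.reset_index()
        unit_col = res.columns[0]
        fdr_col = "efdr" if "efdr" in res.columns else "p_bh"
        join = res[[unit_col, fdr_col]].rename(
            columns={unit_col: key, fdr_col: "fdr"}
        )
        out = out.merge(join, on=key, how="left")
    return out
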
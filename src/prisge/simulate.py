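"""Ground-truthed synthetic prime-editing screens.

The generator reproduces the statistical structure a positive-selection
pegRNA screen analysis has to cope with:

* a plasmid library with 1-4 constructs per programmed variant, a
  fraction of synonymous controls, and log-normal abundance skew;
* per-construct editing efficiency drawn from a zero-inflated Beta
  (some constructs simply never edit -- structural false negatives);
* lentiviral transduction at low MOI (Poisson integrations, default
  mean 0.35) with one random 8-mer clonal barcode per integration;
* a lineage-level Bernoulli edit decision at time zero;
* Galton-Watson growth, size(t+dt) ~ Poisson(size(t) * 2^(g*dt)), with
  arm- and genotype-dependent net growth in doublings/day;
* bottleneck passaging (a fixed per-construct cell coverage retained at
  each harvest) followed by multinomial sequencing with per-base error.

Counts, clonal-barcode tables and paired FASTQ are all derived from the
same lineage table, so quantification can be checked against truth
exactly at zero sequencing error.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import seqs
from .errors import ConfigError, LayoutError
from .library import LibraryDesign, PegConstruct, SampleSheet

HARVEST_DAYS_DEFAULT = (3.0, 7.0, 11.0, 15.0, 19.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated screen.

    Defaults follow the experimental regime of the screens this package
    analyses: MOI 0.35, five harvests at days 3/7/11/15/19, three
    replicates, >= 500x bottleneck coverage, ~0.5 doublings/day baseline
    growth (about 10 doublings over the ~20 day course), and drug-arm
    net growth of +0.5 doublings/day for edited resistant lineages
    versus -0.5 for everything else.
    """

    n_variants: int = 50
    frac_synonymous: float = 0.2
    frac_resistant: float = 0.1
    constructs_per_variant: tuple[int, int] = (1, 4)
    editing_beta: tuple[float, float] = (2.0, 8.0)
    p_zero: float = 0.2
    library_skew_sigma: float = 0.5
    moi: float = 0.35
    coverage: float = 500.0
    baseline_growth: float = 0.5
    g_resistant_drug: float = 0.5
    g_sensitive_drug: float = -0.5
    pre_days: float = 4.0
    harvest_days: tuple[float, ...] = HARVEST_DAYS_DEFAULT
    bottleneck_coverage: float = 500.0
    depth_per_sample: int = 500_000
    base_error_rate: float = 0.0
    n_replicates: int = 3
    arms: tuple[str, ...] = ("vehicle", "drug")
    control_arm: str = "vehicle"
    spacer_len: int = 20
    extension_len: int = 25
    multi_integration: bool = False
    deterministic_growth: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_synonymous", "frac_resistant", "p_zero"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_variants < 2:
            raise ConfigError("n_variants must be >= 2")
        if self.frac_synonymous <= 0:
            raise ConfigError("a screen needs synonymous controls (frac_synonymous > 0)")
        if self.moi <= 0:
            raise ConfigError("moi must be > 0")
        if list(self.harvest_days) != sorted(set(self.harvest_days)):
            raise ConfigError("harvest_days must be strictly increasing")
        if self.depth_per_sample <= 0:
            raise ConfigError("depth_per_sample must be > 0")
        lo, hi = self.constructs_per_variant
        if not (1 <= lo <= hi <= 4):
            raise ConfigError("constructs_per_variant must be within 1..4")


@dataclass
class SimTruth:
    """Ground truth emitted by the generator."""

    efficiency: pd.Series  # per construct_id
    plasmid_abundance: pd.Series  # per construct_id, sums to 1
    variant_table: pd.DataFrame  # variant_id, resistant, is_control, effective_editing
    lineages: dict[int, pd.DataFrame] = field(default_factory=dict)
    barcode_collision_rate: float = float("nan")

    @property
    def resistant_variants(self) -> list[str]:
        vt = self.variant_table
        return list(vt.loc[vt["resistant"], "variant_id"])

    @property
    def control_variants(self) -> list[str]:
        vt = self.variant_table
        return list(vt.loc[vt["is_control"], "variant_id"])

    def founder_lineage_counts(self, replicate: int) -> pd.Series:
        """Edited founder lineages per resistant variant in one replicate."""
        lin = self.lineages[replicate]
        edited = lin[lin["edited"]]
        return edited.groupby("variant_id").size()


@dataclass(frozen=True)
class ReadLayout:
    """Geometry of the paired-end pegRNA sequencing reads.

    Read 1 starts ``r1_spacer_offset`` bases before the spacer (offset 0
    means the read begins at the spacer's first base).  Read 2 is the
    reverse complement of the cassette 3' end: constant suffix, then the
    reverse-complemented barcode, the poly-T terminator seen as a run of
    7 A's, the reverse-complemented linker, and finally the extension.
    """

    r1_spacer_offset: int = 0
    r1_length: int = 26
    r2_length: int = 110
    anchor_jitter: int = 2

    def __post_init__(self) -> None:
        if self.r1_spacer_offset < 0:
            raise LayoutError("r1_spacer_offset must be non-negative")

    @property
    def r2_barcode_end(self) -> int:
        """Expected 0-based position of the anchor start on Read 2."""
        return len(seqs.SUFFIX) + seqs.BARCODE_LEN

    def r2_required_length(self, extension_len: int) -> int:
        return (
            len(seqs.SUFFIX)
            + seqs.BARCODE_LEN
            + len(seqs.TERMINATOR)
            + len(seqs.LINKER)
            + extension_len
        )


def simulate_library(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Generate a library design plus per-construct ground truth.

    Returns ``(LibraryDesign, SimTruth)`` with lineage tables left empty
    (filled by :func:`simulate_screen`).
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_syn = max(1, int(round(cfg.frac_synonymous * cfg.n_variants)))
    n_res = int(round(cfg.frac_resistant * cfg.n_variants))
    if n_syn + n_res > cfg.n_variants:
        raise ConfigError("frac_synonymous + frac_resistant exceed the library")

    lo, hi = cfg.constructs_per_variant
    n_constructs_per = rng.integers(lo, hi + 1, size=cfg.n_variants)
    total = int(n_constructs_per.sum())
    spacers = seqs.random_distinct_dna(rng, total, cfg.spacer_len)
    extensions = seqs.random_distinct_dna(rng, total, cfg.extension_len)

    classes = ["synonymous"] * n_syn + ["missense"] * (cfg.n_variants - n_syn)
    resistant_flags = [False] * n_syn + [True] * n_res + [False] * (
        cfg.n_variants - n_syn - n_res
    )

    constructs: list[PegConstruct] = []
    rows = []
    k = 0
    for v in range(cfg.n_variants):
        variant_id = f"V{v:04d}"
        for j in range(n_constructs_per[v]):
            constructs.append(
                PegConstruct(
                    construct_id=f"{variant_id}_pg{j + 1}",
                    spacer=spacers[k],
                    extension=extensions[k],
                    scaffold_id="flip_extend",
                    variant_id=variant_id,
                    gene="GENE1",
                    variant_label=variant_id,
                    mutation_class=classes[v],
                    is_control=None,
                )
            )
            k += 1
        rows.append(
            {
                "variant_id": variant_id,
                "resistant": resistant_flags[v],
                "is_control": classes[v] == "synonymous",
                "n_constructs": int(n_constructs_per[v]),
            }
        )
    lib = LibraryDesign(constructs)

    a, b = cfg.editing_beta
    eff = rng.beta(a, b, size=total)
    eff[rng.random(total) < cfg.p_zero] = 0.0
    efficiency = pd.Series(eff, index=lib.construct_ids, name="editing_efficiency")

    abundance = np.exp(rng.normal(0.0, cfg.library_skew_sigma, size=total))
    abundance /= abundance.sum()
    plasmid = pd.Series(abundance, index=lib.construct_ids, name="plasmid_abundance")

    vt = pd.DataFrame(rows)
    eff_eci = []
    for variant_id in vt["variant_id"]:
        cids = lib.variant_index[variant_id]
        w = plasmid.loc[cids].to_numpy()
        eff_eci.append(float(np.average(efficiency.loc[cids], weights=w)))
    vt["effective_editing"] = eff_eci

    return lib, SimTruth(efficiency=efficiency, plasmid_abundance=plasmid, variant_table=vt)


@dataclass
class ScreenSim:
    """Counts, metadata and barcode truth for one simulated screen."""

    counts: pd.DataFrame  # constructs x samples, integer reads
    samples: SampleSheet
    barcode_table: pd.DataFrame  # construct_id, barcode, sample_id, reads
    truth: SimTruth


def _split_across_arms(rng, founder: np.ndarray, n_arms: int) -> list[np.ndarray]:
    """Multinomially split each founder lineage's cells across arms."""
    remaining = founder.astype(np.int64).copy()
    shares = []
    for a in range(n_arms, 1, -1):
        take = rng.binomial(remaining, 1.0 / a)
        shares.append(take)
        remaining -= take
    shares.append(remaining)
    return shares


def _barcode_strings(codes: np.ndarray) -> np.ndarray:
    """Decode base-4 integer codes into 8-mer DNA barcodes."""
    letters = np.array(list("ACGT"))
    out = np.empty(codes.shape[0], dtype="U8")
    digits = np.empty((codes.shape[0], seqs.BARCODE_LEN), dtype=np.int64)
    c = codes.astype(np.int64)
    for i in range(seqs.BARCODE_LEN - 1, -1, -1):
        digits[:, i] = c % 4
        c //= 4
    chars = letters[digits]
    for i in range(codes.shape[0]):
        out[i] = "".join(chars[i])
    return out


def simulate_screen(
    lib: LibraryDesign,
    truth: SimTruth,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> ScreenSim:
    """Run the transduction / selection / sequencing generative model.

    Each replicate is an independent transduction.  Within a replicate,
    every transduced cell founds a lineage carrying one construct and one
    random 8-mer barcode; lineages are expanded for ``pre_days`` under
    baseline growth, split across treatment arms, grown by Poisson
    branching with arm- and genotype-dependent rates, bottlenecked to
    ``bottleneck_coverage`` cells per construct at every harvest, and
    sequenced multinomially to ``depth_per_sample`` reads.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)

    n_constructs = len(lib)
    cids = np.array(lib.construct_ids)
    probs = truth.plasmid_abundance.loc[cids].to_numpy()
    eff = truth.efficiency.loc[cids].to_numpy()
    variant_of = np.array([c.variant_id for c in lib.constructs])
    resistant_variant = set(truth.resistant_variants)
    construct_resistant = np.array([v in resistant_variant for v in variant_of])

    n_cells = int(np.ceil(cfg.coverage * n_constructs / (1.0 - np.exp(-cfg.moi))))
    n_arms = len(cfg.arms)
    bottleneck_total = cfg.bottleneck_coverage * n_constructs

    sample_rows = []
    count_cols: dict[str, np.ndarray] = {}
    bc_frames = []
    collisions = []

    for rep in range(1, cfg.n_replicates + 1):
        if cfg.multi_integration:
            k = rng.poisson(cfg.moi, size=n_cells)
            n_lineages = int(k.sum())
        else:
            p_pos = 1.0 - np.exp(-cfg.moi)
            n_lineages = int(rng.binomial(n_cells, p_pos))
        constr_idx = rng.choice(n_constructs, size=n_lineages, p=probs)
        codes = rng.integers(0, 4**seqs.BARCODE_LEN, size=n_lineages)
        edited = rng.random(n_lineages) < eff[constr_idx]

        # within-construct barcode collision rate over the 4^8 space
        df_pairs = pd.DataFrame({"c": constr_idx, "b": codes})
        n_uni = df_pairs.drop_duplicates().shape[0]
        collisions.append(1.0 - n_uni / max(1, n_lineages))

        truth.lineages[rep] = pd.DataFrame(
            {
                "construct_id": cids[constr_idx],
                "variant_id": variant_of[constr_idx],
                "barcode_code": codes,
                "edited": edited,
            }
        )

        founder_mean = 2.0 ** (cfg.baseline_growth * cfg.pre_days)
        if cfg.deterministic_growth:
            founder = np.full(n_lineages, founder_mean)
            arm_sizes = [founder / n_arms for _ in cfg.arms]
        else:
            founder = rng.poisson(founder_mean, size=n_lineages)
            arm_sizes = _split_across_arms(rng, founder, n_arms)

        for arm, size0 in zip(cfg.arms, arm_sizes):
            if arm == cfg.control_arm:
                g = np.full(n_lineages, cfg.baseline_growth)
            else:
                g = np.where(
                    edited & construct_resistant[constr_idx],
                    cfg.g_resistant_drug,
                    cfg.g_sensitive_drug,
                )
            sizes = size0.astype(float)
            prev = 0.0
            for day in cfg.harvest_days:
                dt = day - prev
                lam = sizes * 2.0 ** (g * dt)
                if cfg.deterministic_growth:
                    sizes = lam
                else:
                    sizes = rng.poisson(lam).astype(float)
                prev = day
                total = sizes.sum()
                sample_id = f"{arm}_d{int(day) if float(day).is_integer() else day}_r{rep}"
                if total <= 0:
                    warnings.warn(
                        f"population extinct in {sample_id}; emitting zero counts",
                        stacklevel=2,
                    )
                    reads = np.zeros(n_lineages, dtype=np.int64)
                else:
                    p = sizes / total
                    if cfg.deterministic_growth:
                        reads = cfg.depth_per_sample * p
                    else:
                        reads = rng.multinomial(cfg.depth_per_sample, p)
                col = np.bincount(constr_idx, weights=reads, minlength=n_constructs)
                count_cols[sample_id] = col
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "replicate": rep,
                        "arm": arm,
                        "day": float(day),
                        "fastq_r1": "",
                        "fastq_r2": "",
                    }
                )
                nz = np.flatnonzero(reads)
                if nz.size:
                    bc = pd.DataFrame(
                        {
                            "construct_idx": constr_idx[nz],
                            "barcode_code": codes[nz],
                            "reads": np.asarray(reads)[nz],
                        }
                    )
                    bc = (
                        bc.groupby(["construct_idx", "barcode_code"], as_index=False)[
                            "reads"
                        ].sum()
                    )
                    bc["sample_id"] = sample_id
                    bc_frames.append(bc)
                # bottleneck passage: retain a fixed cell coverage
                if not cfg.deterministic_growth and total > bottleneck_total:
                    sizes = rng.binomial(
                        sizes.astype(np.int64), bottleneck_total / total
                    ).astype(float)
                elif cfg.deterministic_growth and total > bottleneck_total:
                    sizes = sizes * (bottleneck_total / total)

    truth.barcode_collision_rate = float(np.mean(collisions))

    counts = pd.DataFrame(count_cols, index=lib.construct_ids)
    if not cfg.deterministic_growth:
        counts = counts.astype(np.int64)
    sheet = SampleSheet(pd.DataFrame(sample_rows), control_arm=cfg.control_arm)

    if bc_frames:
        bt = pd.concat(bc_frames, ignore_index=True)
        bt["construct_id"] = cids[bt.pop("construct_idx").to_numpy()]
        bt["barcode"] = _barcode_strings(bt.pop("barcode_code").to_numpy())
        bt = bt[["construct_id", "barcode", "sample_id", "reads"]]
    else:
        bt = pd.DataFrame(columns=["construct_id", "barcode", "sample_id", "reads"])

    return ScreenSim(counts=counts, samples=sheet, barcode_table=bt, truth=truth)


def simulate_null_counts(
    n_units: int,
    rng: np.random.Generator,
    n_replicates: int = 3,
    harvest_days: tuple[float, ...] = HARVEST_DAYS_DEFAULT,
    arms: tuple[str, ...] = ("vehicle", "drug"),
    control_arm: str = "vehicle",
    mean_range: tuple[float, float] = (50.0, 2000.0),
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, SampleSheet]:
    """Counts with no drug (or time) effect: y_ij ~ NB(mu_i, alpha) i.i.d.

    Used to check the calibration of the likelihood-ratio test -- under
    this null its p-values should be uniform.  Unit means are drawn
    log-uniformly over ``mean_range``.
    """
    rows = []
    for rep in range(1, n_replicates + 1):
        for arm in arms:
            for day in harvest_days:
                sid = f"{arm}_d{day:g}_r{rep}"
                rows.append(
                    {"sample_id": sid, "replicate": rep, "arm": arm,
                     "day": float(day), "fastq_r1": "", "fastq_r2": ""}
                )
    sheet = SampleSheet(pd.DataFrame(rows), control_arm=control_arm)
    n_samples = len(rows)
    mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), n_units))
    if alpha > 0:
        r = 1.0 / alpha
        lam = rng.gamma(r, mu[:, None] / r, size=(n_units, n_samples))
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu[:, None], size=(n_units, n_samples))
    index = [f"U{i:05d}" for i in range(n_units)]
    return pd.DataFrame(counts, index=index, columns=[r["sample_id"] for r in rows]), sheet


def expected_resistant_proportion(
    e_i: float, g_res: float, g_sens: float, t: float, p0: float
) -> float:
    """Closed-form expected proportion of one resistant construct.

    Two-type exponential growth: a fraction ``e_i`` of the construct's
    cells are edited and grow at ``g_res`` doublings/day under drug;
    everything else (its unedited cells and all other constructs) grows
    at ``g_sens``.  ``p0`` is the construct's starting proportion.
    """
    grown_res = p0 * e_i * 2.0 ** (g_res * t)
    grown_sens = (p0 * (1 - e_i) + (1 - p0)) * 2.0 ** (g_sens * t)
    return (grown_res + p0 * (1 - e_i) * 2.0 ** (g_sens * t)) / (grown_res + grown_sens)


def _cassette(construct: PegConstruct, barcode: str) -> str:
    scaffold = seqs.SCAFFOLDS[construct.scaffold_id]
    return (
        construct.spacer
        + scaffold
        + construct.extension
        + seqs.LINKER
        + seqs.TERMINATOR
        + barcode
        + seqs.SUFFIX
    )


def _apply_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    if rate <= 0:
        return read
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if hits.size == 0:
        return read
    chars = list(read)
    for i in hits:
        alts = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alts[rng.integers(0, 3)]
    return "".join(chars)


def write_fastq(
    sim: ScreenSim,
    lib: LibraryDesign,
    layout: ReadLayout,
    cfg: SimConfig,
    outdir: str | Path,
    samples: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> SampleSheet:
    """Emit gzip paired FASTQ for the simulated samples.

    One read pair per sequenced molecule, taken from the barcode table.
    Read 1 carries the spacer at the configured offset; Read 2 carries
    the reverse-complemented cassette 3' end (suffix, barcode, 7-A
    anchor, linker, extension).  Substitution errors are applied i.i.d.
    at ``cfg.base_error_rate``.  Returns a sample sheet with FASTQ paths
    filled in.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_id = {c.construct_id: c for c in lib.constructs}

    for c in lib.constructs:
        if layout.r1_spacer_offset + len(c.spacer) > layout.r1_length:
            raise LayoutError(
                f"spacer of {c.construct_id} does not fit in Read 1 "
                f"(offset {layout.r1_spacer_offset}, length {layout.r1_length})"
            )
        if layout.r2_required_length(len(c.extension)) > layout.r2_length:
            raise LayoutError(
                f"extension of {c.construct_id} does not fit in Read 2 "
                f"(needs {layout.r2_required_length(len(c.extension))}, "
                f"length {layout.r2_length})"
            )

    sheet = sim.samples.to_frame()
    wanted = samples if samples is not None else list(sheet["sample_id"])
    bt = sim.barcode_table
    paths: dict[str, tuple[str, str]] = {}
    for sample_id in wanted:
        rows = bt[bt["sample_id"] == sample_id]
        p1 = outdir / f"{sample_id}_R1.fastq.gz"
        p2 = outdir / f"{sample_id}_R2.fastq.gz"
        with gzip.open(p1, "wt") as f1, gzip.open(p2, "wt") as f2:
            n = 0
            for construct_id, barcode, reads in zip(
                rows["construct_id"], rows["barcode"], rows["reads"]
            ):
                construct = by_id[construct_id]
                cass = _cassette(construct, barcode)
                pad = "G" * layout.r1_spacer_offset
                r1_full = (pad + cass)[: layout.r1_length].ljust(layout.r1_length, "G")
                r2_full = seqs.revcomp(cass)[: layout.r2_length]
                r2_full = r2_full.ljust(layout.r2_length, "G")
                q1 = "I" * len(r1_full)
                q2 = "I" * len(r2_full)
                for _ in range(int(reads)):
                    n += 1
                    name = f"@{sample_id}:{n}"
                    s1 = _apply_errors(rng, r1_full, cfg.base_error_rate)
                    s2 = _apply_errors(rng, r2_full, cfg.base_error_rate)
                    f1.write(f"{name}\n{s1}\n+\n{q1}\n")
                    f2.write(f"{name}\n{s2}\n+\n{q2}\n")
        paths[sample_id] = (str(p1), str(p2))

    sheet = sheet.copy()
    sheet["fastq_r1"] = sheet["sample_id"].map(lambda s: paths.get(s, ("", ""))[0])
    sheet["fastq_r2"] = sheet["sample_id"].map(lambda s: paths.get(s, ("", ""))[1])
    return SampleSheet(sheet, control_arm=sim.samples.control_arm)
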
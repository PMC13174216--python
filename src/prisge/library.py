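"""epegRNA library designs, sample sheets, validation, and representation QC.

A library is a table of prime-editing guide constructs.  Each construct
carries a 20-nt spacer (sequenced on Read 1), a variable-length 3'
extension encoding the programmed edit (RTT + PBS, sequenced on Read 2),
a scaffold identifier, and annotations linking it to the genetic variant
it programs.  Constructs programming synonymous (protein-silent) edits
serve as negative controls throughout the analysis: they define the null
distribution for Z-scores and the control set for empirical FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError

MUTATION_CLASSES = frozenset(
    {"missense", "synonymous", "nonsense", "splice", "deletion", "insertion"}
)

LIBRARY_COLUMNS = [
    "construct_id",
    "spacer",
    "extension",
    "scaffold_id",
    "variant_id",
    "gene",
    "variant_label",
    "mutation_class",
    "is_control",
]

SAMPLE_COLUMNS = ["sample_id", "replicate", "arm", "day", "fastq_r1", "fastq_r2"]


@dataclass(frozen=True)
class PegConstruct:
    """One epegRNA construct in a library."""

    construct_id: str
    spacer: str
    extension: str
    scaffold_id: str
    variant_id: str
    gene: str
    variant_label: str
    mutation_class: str
    is_control: bool | None = None

    def resolved_control(self) -> bool:
        """Control status: synonymous by default, explicit flag overrides."""
        if self.is_control is None:
            return self.mutation_class == "synonymous"
        return bool(self.is_control)


@dataclass
class LibraryDesign:
    """Ordered collection of constructs plus a variant -> constructs index."""

    constructs: list[PegConstruct]
    variant_index: dict[str, list[str]] = field(init=False)

    def __post_init__(self) -> None:
        ids = [c.construct_id for c in self.constructs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate construct_id(s): {dupes}")
        index: dict[str, list[str]] = {}
        for c in self.constructs:
            index.setdefault(c.variant_id, []).append(c.construct_id)
        self.variant_index = index

    def __len__(self) -> int:
        return len(self.constructs)

    def __iter__(self):
        return iter(self.constructs)

    def get(self, construct_id: str) -> PegConstruct:
        return self._by_id[construct_id]

    @property
    def _by_id(self) -> dict[str, PegConstruct]:
        return {c.construct_id: c for c in self.constructs}

    @property
    def construct_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs]

    @property
    def control_ids(self) -> list[str]:
        return [c.construct_id for c in self.constructs if c.resolved_control()]

    @property
    def control_variants(self) -> list[str]:
        seen: dict[str, bool] = {}
        for c in self.constructs:
            seen.setdefault(c.variant_id, True)
            if not c.resolved_control():
                seen[c.variant_id] = False
        return [v for v, ok in seen.items() if ok]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.constructs:
            d = {k: getattr(c, k) for k in LIBRARY_COLUMNS[:-1]}
            d["is_control"] = c.resolved_control()
            rows.append(d)
        return pd.DataFrame(rows, columns=LIBRARY_COLUMNS)


@dataclass
class ValidationReport:
    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    def add_error(self, code: str, message: str, construct_id: str = "") -> None:
        self.errors.append((code, message, construct_id))

    def add_warning(self, code: str, message: str, construct_id: str = "") -> None:
        self.warnings.append((code, message, construct_id))

    @property
    def ok(self) -> bool:
        return not self.errors

    def summary(self) -> dict[str, int]:
        return {"n_errors": len(self.errors), "n_warnings": len(self.warnings)}

    def codes(self) -> list[str]:
        return [code for code, _, _ in self.errors] + [
            code for code, _, _ in self.warnings
        ]


@dataclass(frozen=True)
class RepresentationSummary:
    """Partition of plasmid-pool counts relative to mean +/- 1 sample sd."""

    n_total: int
    n_within_1sd: int
    n_below_1sd: int
    n_above_1sd: int

    @property
    def pct_within(self) -> float:
        return round(100.0 * self.n_within_1sd / self.n_total, 1)

    @property
    def pct_below(self) -> float:
        return round(100.0 * self.n_below_1sd / self.n_total, 1)

    @property
    def pct_above(self) -> float:
        return round(100.0 * self.n_above_1sd / self.n_total, 1)


def _parse_bool(x) -> bool | None:
    if x is None or (isinstance(x, float) and np.isnan(x)) or x == "":
        return None
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise FormatError(f"unparseable is_control value: {x!r}")


def library_from_frame(df: pd.DataFrame) -> LibraryDesign:
    required = LIBRARY_COLUMNS[:-1]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"library table is missing required column {col!r}")
    constructs = []
    for _, row in df.iterrows():
        is_control = _parse_bool(row["is_control"]) if "is_control" in df.columns else None
        constructs.append(
            PegConstruct(
                construct_id=str(row["construct_id"]),
                spacer=str(row["spacer"]),
                extension=str(row["extension"]),
                scaffold_id=str(row["scaffold_id"]),
                variant_id=str(row["variant_id"]),
                gene=str(row["gene"]),
                variant_label=str(row["variant_label"]),
                mutation_class=str(row["mutation_class"]),
                is_control=is_control,
            )
        )
    return LibraryDesign(constructs)


def load_library(path: str | Path) -> LibraryDesign:
    """Load a library design from a tab-separated table.

    Raises :class:`FormatError` on a missing column and
    :class:`ValidationError` on duplicate construct ids.  Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return library_from_frame(df)


def write_library(lib: LibraryDesign, path: str | Path) -> None:
    """Write a library as TSV in canonical column order (round-trips)."""
    df = lib.to_frame()
    df["is_control"] = df["is_control"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


def validate_library(lib: LibraryDesign) -> ValidationReport:
    """Structural checks on a loaded library; findings go in the report.

    Errors: a spacer mapped to two different extensions, non-ACGT
    sequence characters, no synonymous/control constructs.  Warnings:
    variants with more than four constructs, spacers not 20 nt.
    """
    report = ValidationReport()
    spacer_ext: dict[str, str] = {}
    for c in lib.constructs:
        for name, seq in (("spacer", c.spacer), ("extension", c.extension)):
            if not seq or any(b not in "ACGT" for b in seq.upper()) or seq != seq.upper():
                ok = bool(seq) and all(b in "ACGT" for b in seq.upper())
                if not ok:
                    report.add_error(
                        "NON_ACGT",
                        f"{name} contains characters outside ACGT",
                        c.construct_id,
                    )
                    continue
        if c.mutation_class not in MUTATION_CLASSES:
            report.add_error(
                "BAD_MUTATION_CLASS",
                f"unknown mutation_class {c.mutation_class!r}",
                c.construct_id,
            )
        prev = spacer_ext.get(c.spacer)
        if prev is None:
            spacer_ext[c.spacer] = c.extension
        elif prev != c.extension:
            report.add_error(
                "SPACER_EXTENSION_CONFLICT",
                f"spacer {c.spacer} associated with two extensions",
                c.construct_id,
            )
        if len(c.spacer) != 20 and all(b in "ACGT" for b in c.spacer.upper()):
            report.add_warning(
                "SPACER_LENGTH",
                f"spacer length {len(c.spacer)} != 20",
                c.construct_id,
            )
    if lib.constructs and not lib.control_ids:
        report.add_error("NO_CONTROLS", "library contains no control constructs")
    for variant_id, cids in lib.variant_index.items():
        if len(cids) > 4:
            report.add_warning(
                "TOO_MANY_CONSTRUCTS",
                f"variant {variant_id} has {len(cids)} constructs (> 4)",
                cids[0],
            )
    return report


def representation_stats(counts) -> RepresentationSummary:
    """Classify plasmid-pool counts relative to [mean - sd, mean + sd].

    Bounds are inclusive and sd is the sample standard deviation
    (ddof=1), so an all-equal pool is 100% within band.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise InsufficientDataError("need at least 2 constructs for representation stats")
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    mean = counts.mean()
    sd = counts.std(ddof=1)
    below = int(np.sum(counts < mean - sd))
    above = int(np.sum(counts > mean + sd))
    within = int(counts.size - below - above)
    return RepresentationSummary(
        n_total=int(counts.size),
        n_within_1sd=within,
        n_below_1sd=below,
        n_above_1sd=above,
    )


@dataclass
class SampleSheet:
    """Sample metadata: one row per sequenced sample."""

    frame: pd.DataFrame
    control_arm: str

    def __post_init__(self) -> None:
        df = self.frame
        for col in ["sample_id", "replicate", "arm", "day"]:
            if col not in df.columns:
                raise FormatError(f"sample sheet is missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample_id in sample sheet")
        key = df[["replicate", "arm", "day"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValidationError("duplicate (replicate, arm, day) combination")
        if self.control_arm not in set(df["arm"]):
            raise ValidationError(
                f"control arm {self.control_arm!r} absent from sample sheet"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    @property
    def arms(self) -> list[str]:
        return sorted(set(self.frame["arm"]))

    @property
    def drug_arms(self) -> list[str]:
        return [a for a in self.arms if a != self.control_arm]

    @property
    def days(self) -> list[float]:
        return sorted(set(self.frame["day"].astype(float)))

    @property
    def replicates(self) -> list[int]:
        return sorted(set(self.frame["replicate"].astype(int)))

    def sample_id_for(self, arm: str, day: float, replicate: int) -> str:
        df = self.frame
        mask = (
            (df["arm"] == arm)
            & (df["day"].astype(float) == float(day))
            & (df["replicate"].astype(int) == int(replicate))
        )
        hits = df.loc[mask, "sample_id"]
        if len(hits) != 1:
            raise PairingErrorFor(arm, day, replicate)
        return hits.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        cols = [c for c in SAMPLE_COLUMNS if c in self.frame.columns]
        return self.frame[cols].copy()


def PairingErrorFor(arm, day, replicate):
    from .errors import PairingError

    return PairingError(
        f"no unique sample for arm={arm!r}, day={day}, replicate={replicate}"
    )


def load_sample_sheet(path: str | Path, control_arm: str) -> SampleSheet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["replicate"] = df["replicate"].astype(int)
    df["day"] = df["day"].astype(float)
    return SampleSheet(df, control_arm=control_arm)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.to_frame().to_csv(path, sep="\t", index=False)
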
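"""Screen-level summary statistics.

The printed-statistics layer of the pipeline: log2 counts-per-million
normalization with a pseudocount of 1, log2 fold change of each
construct between a drug arm and its matched vehicle sample, Z-scores
standardized against the synonymous-control distribution, variant-level
aggregation, pooled-variance t-tests with Bonferroni correction, SSMD
window quality, Poisson MOI estimation from marker positivity, and
false-negative-rate accounting against known positives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientDataError, PairingError, ValidationError
from .library import LibraryDesign, SampleSheet
from .quantify import CountMatrix


def normalize_log2(m: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """log2 CPM with pseudocount 1, per sample.

    value = log2( (c + 1) / sum_constructs (c + 1) * 1e6 ).  Defined for
    zero counts; an all-zero sample normalizes to uniform CPM (with a
    warning).
    """
    counts = m.counts if isinstance(m, CountMatrix) else m
    arr = counts.to_numpy(dtype=float) + 1.0
    colsum = arr.sum(axis=0)
    if (counts.to_numpy().sum(axis=0) == 0).any():
        warnings.warn("all-zero sample(s) normalized to uniform CPM", stacklevel=2)
    cpm = arr / colsum * 1e6
    return pd.DataFrame(np.log2(cpm), index=counts.index, columns=counts.columns)


def log2fc(
    nm: pd.DataFrame,
    sheet: SampleSheet,
    arm: str,
    day: float,
    replicate: int,
) -> pd.Series:
    """Per-construct log2 fold change of a treatment sample vs its
    matched vehicle sample (same replicate, same day)."""
    treat = _sample_or_raise(sheet, arm, day, replicate)
    vehicle = _sample_or_raise(sheet, sheet.control_arm, day, replicate)
    return nm[treat] - nm[vehicle]


def _sample_or_raise(sheet: SampleSheet, arm: str, day: float, replicate: int) -> str:
    df = sheet.frame
    mask = (
        (df["arm"] == arm)
        & (df["day"].astype(float) == float(day))
        & (df["replicate"].astype(int) == int(replicate))
    )
    hits = df.loc[mask, "sample_id"]
    if len(hits) != 1:
        raise PairingError(
            f"no unique sample for arm={arm!r}, day={day}, replicate={replicate}"
        )
    return hits.iloc[0]


def z_scores(values: pd.Series, control_ids) -> pd.Series:
    """Standardize log2 fold changes against the control distribution.

    z_i = (x_i - mean(controls)) / sd(controls) with the sample standard
    deviation (ddof=1).  Requires >= 2 controls with nonzero sd.
    """
    control_ids = [c for c in control_ids if c in values.index]
    if len(control_ids) < 2:
        raise InsufficientDataError("need >= 2 control constructs for Z-scores")
    ctrl = values.loc[control_ids].astype(float)
    sd = ctrl.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise InsufficientDataError("control sd is zero; Z undefined")
    return (values - ctrl.mean()) / sd


def aggregate_variants(
    values: pd.Series, lib: LibraryDesign, dropna: bool = True
) -> pd.Series:
    """Variant-level arithmetic mean of per-construct statistics."""
    key = pd.Series(
        {c.construct_id: c.variant_id for c in lib.constructs}, name="variant_id"
    )
    df = pd.DataFrame({"value": values, "variant_id": key.reindex(values.index)})
    if df["variant_id"].isna().any():
        raise ValidationError("values contain constructs absent from the library")
    out = df.groupby("variant_id")["value"].mean()
    if dropna and out.isna().any():
        dropped = list(out.index[out.isna()])
        warnings.warn(f"variants dropped with no scored constructs: {dropped}",
                      stacklevel=2)
        out = out.dropna()
    return out


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    p_bonferroni: float
    degenerate_variance: bool = False


def ttest_vs_reference(variant_values, reference_values, n_tests: int = 1) -> TTestResult:
    """Unpaired two-sided Student's t-test (pooled variance) with
    Bonferroni correction over ``n_tests`` comparisons."""
    a = np.asarray(variant_values, dtype=float)
    b = np.asarray(reference_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return TTestResult(t=0.0, p=1.0, p_bonferroni=1.0, degenerate_variance=True)
        return TTestResult(
            t=np.inf * np.sign(a.mean() - b.mean()),
            p=0.0,
            p_bonferroni=0.0,
            degenerate_variance=True,
        )
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return TTestResult(
        t=float(t), p=float(p), p_bonferroni=float(min(1.0, p * n_tests))
    )


@dataclass(frozen=True)
class SSMDResult:
    ssmd: float
    infinite: bool = False


def ssmd(pos_values, neg_values) -> SSMDResult:
    """Strictly standardized mean difference between two control sets.

    SSMD = (mean_pos - mean_neg) / sqrt(var_pos + var_neg), with sample
    variances.  Both-variances-zero is flagged as infinite.
    """
    a = np.asarray(pos_values, dtype=float)
    b = np.asarray(neg_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    denom = a.var(ddof=1) + b.var(ddof=1)
    diff = a.mean() - b.mean()
    if denom == 0:
        return SSMDResult(ssmd=np.inf * np.sign(diff) if diff else 0.0, infinite=True)
    return SSMDResult(ssmd=float(diff / np.sqrt(denom)))


def moi_from_positive_fraction(f: float) -> float:
    """Poisson MOI implied by a transduction-marker-positive fraction.

    With integrations ~ Poisson(m), the positive fraction is
    1 - exp(-m), so m = -ln(1 - f).  Thirty percent positivity gives
    an MOI of ~0.36.
    """
    if not 0.0 <= f < 1.0:
        raise ValidationError("positive fraction must be in [0, 1)")
    return float(-np.log1p(-f))


def false_negative_rate(hits, known_positives) -> float:
    """Fraction of known positive variants missed by the screen."""
    known = set(known_positives)
    if not known:
        raise ValidationError("known-positive set is empty")
    missed = known - set(hits)
    return len(missed) / len(known)


def hit_rate(n_hits: int, n_tested: int) -> float:
    """Percentage of tested variants called as hits."""
    if n_tested <= 0:
        raise ValidationError("n_tested must be positive")
    return 100.0 * n_hits / n_tested


def replicate_correlation(nm: pd.DataFrame, sheet: SampleSheet) -> pd.DataFrame:
    """Pairwise Pearson r between replicates, per (arm, day).

    Returns a tidy frame with one row per replicate pair; constant
    columns are flagged with NaN r.
    """
    rows = []
    df = sheet.frame
    for (arm, day), group in df.groupby(["arm", "day"]):
        reps = sorted(group["replicate"].astype(int))
        if len(reps) < 2:
            continue
        for i, r1 in enumerate(reps):
            for r2 in reps[i + 1:]:
                s1 = nm[_sample_or_raise(sheet, arm, day, r1)]
                s2 = nm[_sample_or_raise(sheet, arm, day, r2)]
                if s1.std() == 0 or s2.std() == 0:
                    r = np.nan
                else:
                    r = float(sps.pearsonr(s1, s2).statistic)
                rows.append(
                    {"arm": arm, "day": float(day), "rep_a": r1, "rep_b": r2, "r": r}
                )
    return pd.DataFrame(rows, columns=["arm", "day", "rep_a", "rep_b", "r"])


def score_table(
    counts: CountMatrix, lib: LibraryDesign, arms: list[str] | None = None
) -> pd.DataFrame:
    """Tidy construct-level score table across all (arm, day, replicate).

    Columns: construct_id, variant_id, arm, day, replicate, log2fc, z.
    Z-scores are standardized within each (arm, day, replicate) against
    the library's control constructs.
    """
    sheet = counts.samples
    nm = normalize_log2(counts)
    controls = lib.control_ids
    frames = []
    for arm in arms or sheet.drug_arms:
        for day in sheet.days:
            for rep in sheet.replicates:
                try:
                    fc = log2fc(nm, sheet, arm, day, rep)
                except PairingError:
                    continue
                z = z_scores(fc, controls)
                frames.append(
                    pd.DataFrame(
                        {
                            "construct_id": fc.index,
                            "arm": arm,
                            "day": float(day),
                            "replicate": int(rep),
                            "log2fc": fc.to_numpy(),
                            "z": z.to_numpy(),
                        }
                    )
                )
    out = pd.concat(frames, ignore_index=True)
    vmap = {c.construct_id: c.variant_id for c in lib.constructs}
    out.insert(1, "variant_id", out["construct_id"].map(vmap))
    return out
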
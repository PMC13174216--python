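"""Model/Results interface for whole-screen differential-abundance testing.

``ResistanceScreenModel`` is constructed from a count matrix, a sample
sheet and a library design, and tests one drug arm against the vehicle
arm.  ``fit()`` runs the full engine -- size factors, moderated
dispersions, per-unit full/reduced NB GLM fits, the likelihood-ratio
test, a one-sided Wald enrichment test, Benjamini-Hochberg and
synonymous-control empirical FDR, and hit calling -- and returns a
``ScreenLRTResults`` carrying the per-unit table, diagnostics and a
``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import diffabund as da
from .errors import InsufficientDataError, ValidationError
from .library import LibraryDesign, SampleSheet
from .quantify import CountMatrix


class ResistanceScreenModel:
    """NB-GLM time-course model of a drug arm against the vehicle arm.

    Parameters
    ----------
    counts
        Construct-level count matrix with attached sample sheet.
    library
        Library design; synonymous constructs define the control set.
    drug_arm
        Arm to test against the sheet's control arm.
    unit
        "variant" (default): counts are summed over each variant's
        constructs before fitting.  "construct": fit per construct.
    time_as_factor
        Enter harvest day as a factor instead of a continuous covariate.
    size_factor_method
        "total" (default): size factors proportional to column sums, so
        the model tests changes in sequencing *proportions*.  Under
        strong positive selection the non-resistant population can go
        extinct in the drug arm; a median-of-ratios reference then
        anchors on the resistant units themselves and makes weaker
        resistant variants look depleted.  "median_ratio" (the classic
        estimator) and "controls" (median-of-ratios over the control
        units only) are available for gentler selection regimes.
    """

    def __init__(
        self,
        counts: CountMatrix,
        library: LibraryDesign,
        drug_arm: str,
        unit: str = "variant",
        time_as_factor: bool = False,
        size_factor_method: str = "total",
    ):
        if size_factor_method not in ("total", "median_ratio", "controls"):
            raise ValidationError(f"unknown size_factor_method {size_factor_method!r}")
        self.size_factor_method = size_factor_method
        if unit not in ("variant", "construct"):
            raise ValidationError("unit must be 'variant' or 'construct'")
        if drug_arm not in counts.samples.arms:
            raise ValidationError(f"unknown drug arm {drug_arm!r}")
        if drug_arm == counts.samples.control_arm:
            raise ValidationError("drug_arm must differ from the control arm")
        self.counts = counts
        self.library = library
        self.drug_arm = drug_arm
        self.unit = unit
        self.time_as_factor = time_as_factor

        self.design = da.build_design(
            counts.samples.frame,
            drug_arm,
            counts.samples.control_arm,
            time_as_factor=time_as_factor,
        )
        mat = counts.counts[self.design.sample_ids]
        if unit == "variant":
            vmap = {c.construct_id: c.variant_id for c in library.constructs}
            grouped = mat.groupby(mat.index.map(vmap)).sum()
            self.endog = grouped
            self.is_control = pd.Series(
                {v: v in set(library.control_variants) for v in grouped.index}
            )
        else:
            self.endog = mat
            ctrl = set(library.control_ids)
            self.is_control = pd.Series(
                {c: c in ctrl for c in mat.index}
            )

    @classmethod
    def from_tsv(
        cls,
        counts_path,
        samples_path,
        library_path,
        drug_arm: str,
        control_arm: str,
        **kwargs,
    ) -> "ResistanceScreenModel":
        from .library import load_library, load_sample_sheet

        lib = load_library(library_path)
        sheet = load_sample_sheet(samples_path, control_arm=control_arm)
        counts = CountMatrix.from_tsv(counts_path, sheet)
        return cls(counts, lib, drug_arm, **kwargs)

    def fit(
        self,
        fdr_threshold: float = 0.01,
        lfc_threshold: float = 0.0,
        prior_df: float = 60.0,
        fdr_column: str = "efdr",
        min_controls: int = 10,
    ) -> "ScreenLRTResults":
        mat = self.endog
        arr = mat.to_numpy(dtype=float)
        if self.size_factor_method == "total":
            tot = arr.sum(axis=0)
            if (tot <= 0).any():
                raise ValidationError("all-zero sample; cannot normalize")
            log_sf = np.log(tot)
            sf = np.exp(log_sf - log_sf.mean())
        elif self.size_factor_method == "controls":
            sf = da.size_factors(arr[self.is_control.to_numpy()])
        else:
            sf = da.size_factors(arr)
        disp = da.estimate_dispersions(arr, sf, self.design, prior_df=prior_df)

        Xf, Xr = self.design.full, self.design.reduced
        contrast = self.design.drug_contrast()
        ln2 = np.log(2.0)

        rows = []
        for i, unit_id in enumerate(mat.index):
            y = arr[i]
            alpha = disp.alpha_final[i]
            if y.sum() == 0 or not np.isfinite(alpha):
                rows.append(
                    dict(
                        unit=unit_id, base_mean=disp.base_mean[i], alpha=np.nan,
                        lrt_stat=np.nan, df=np.nan, p_lrt=np.nan,
                        wald_stat=np.nan, p_wald_one_sided=np.nan,
                        log2fc_model=np.nan, converged=False,
                    )
                )
                continue
            full = da.fit_nb_glm(y, Xf, sf, alpha)
            reduced = da.fit_nb_glm(y, Xr, sf, alpha)
            stat, df, p = da.lrt(full, reduced)
            wstat, wp = da.wald_one_sided(full, contrast)
            lfc = float(contrast @ full.beta) / ln2
            ok = full.converged and reduced.converged
            rows.append(
                dict(
                    unit=unit_id, base_mean=disp.base_mean[i],
                    alpha=float(alpha), lrt_stat=stat, df=df,
                    p_lrt=p if ok else np.nan,
                    wald_stat=wstat, p_wald_one_sided=wp,
                    log2fc_model=lfc, converged=ok,
                )
            )
        res = pd.DataFrame(rows).set_index("unit")
        res["is_control"] = self.is_control.reindex(res.index).fillna(False)
        res["p_bh"] = da.adjust_bh(res["p_lrt"].to_numpy())
        # Direction-aware evidence for control-based FDR: under positive
        # selection every non-resistant unit (controls included) is
        # strongly depleted in the drug arm, so the two-sided LRT p of
        # the controls is not a useful null for calling *enriched* units.
        # Fold the LRT p to the enrichment side using the Wald sign.
        enrich = np.where(
            res["wald_stat"].to_numpy() >= 0,
            res["p_lrt"].to_numpy() / 2.0,
            1.0 - res["p_lrt"].to_numpy() / 2.0,
        )
        res["p_enrich"] = enrich
        try:
            res["efdr"] = da.empirical_fdr(
                res["p_enrich"].to_numpy(),
                res["is_control"].to_numpy(),
                min_controls=min_controls,
            )
        except InsufficientDataError:
            if fdr_column == "efdr":
                raise
            res["efdr"] = np.nan
        res = da.call_hits(
            res,
            fdr_threshold=fdr_threshold,
            lfc_threshold=lfc_threshold,
            fdr_column=fdr_column,
        )
        return ScreenLRTResults(
            model=self,
            results=res,
            size_factors=pd.Series(sf, index=self.design.sample_ids),
            dispersion=disp,
            fdr_threshold=fdr_threshold,
            lfc_threshold=lfc_threshold,
            fdr_column=fdr_column,
        )


@dataclass
class ScreenLRTResults:
    """Per-unit test results and diagnostics for one drug arm."""

    model: ResistanceScreenModel
    results: pd.DataFrame
    size_factors: pd.Series
    dispersion: da.DispersionModel
    fdr_threshold: float
    lfc_threshold: float
    fdr_column: str

    @property
    def hits(self) -> pd.DataFrame:
        return self.results[self.results["hit"]]

    @property
    def hit_units(self) -> list[str]:
        return list(self.hits.index)

    def hit_counts_per_gene(self) -> pd.Series:
        lib = self.model.library
        if self.model.unit == "variant":
            gmap = {c.variant_id: c.gene for c in lib.constructs}
        else:
            gmap = {c.construct_id: c.gene for c in lib.constructs}
        genes = pd.Series([gmap.get(u, "NA") for u in self.hit_units])
        return genes.value_counts()

    def summary(self) -> str:
        r = self.results
        tested = int(r["p_lrt"].notna().sum())
        lines = [
            "Resistance screen differential abundance (NB GLM LRT)",
            "=" * 56,
            f"Drug arm:           {self.model.drug_arm} vs "
            f"{self.model.counts.samples.control_arm}",
            f"Testing unit:       {self.model.unit}",
            f"Units tested:       {tested} of {len(r)}",
            f"Controls:           {int(r['is_control'].sum())}",
            f"Design:             full={self.model.design.full_names} "
            f"reduced={self.model.design.reduced_names}",
            f"LRT df:             {self.model.design.df_test}",
            f"Dispersion trend:   a0/mu + a1 with (a0, a1) = "
            f"({self.dispersion.trend_params[0]:.4g}, "
            f"{self.dispersion.trend_params[1]:.4g})",
            f"Hit rule:           {self.fdr_column} < {self.fdr_threshold} "
            f"and log2FC > {self.lfc_threshold}",
            f"Hits:               {len(self.hit_units)}",
        ]
        gene_counts = self.hit_counts_per_gene()
        if len(gene_counts):
            lines.append("Hits per gene:      " + ", ".join(
                f"{g}={n}" for g, n in gene_counts.items()
            ))
        top = self.hits.sort_values("p_lrt").head(10)
        if len(top):
            lines.append("")
            lines.append("Top hits (by LRT p):")
            lines.append(
                top[["base_mean", "log2fc_model", "p_lrt", "p_bh", "efdr"]]
                .to_string(float_format=lambda v: f"{v:.3g}")
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.results.copy()
        out.index.name = "unit"
        out.to_csv(path, sep="\t")

    def plot_volcano(self, ax=None):
        """Volcano of model log2FC against -log10 LRT p."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        r = self.results.dropna(subset=["p_lrt", "log2fc_model"])
        logp = -np.log10(np.maximum(r["p_lrt"], 1e-300))
        ax.scatter(r["log2fc_model"], logp, s=8, c="grey", label="tested")
        h = r[r["hit"]]
        ax.scatter(h["log2fc_model"], -np.log10(np.maximum(h["p_lrt"], 1e-300)),
                   s=12, c="crimson", label="hit")
        ax.set_xlabel("model log2 fold change (drug effect at final day)")
        ax.set_ylabel("-log10 LRT p")
        ax.legend(frameon=False)
        return ax

    def plot_qq(self, ax=None):
        """Expected-vs-observed -log10 p, controls highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        r = self.results.dropna(subset=["p_lrt"]).sort_values("p_lrt")
        n = len(r)
        exp = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        obs = -np.log10(np.maximum(r["p_lrt"].to_numpy(), 1e-300))
        colors = np.where(r["is_control"], "steelblue", "grey")
        ax.scatter(exp, obs, s=8, c=colors)
        lim = max(exp.max(), 1)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("expected -log10 p")
        ax.set_ylabel("observed -log10 p")
        return ax


def overlap_sets(results_by_arm: dict[str, "ScreenLRTResults"]) -> dict[str, int]:
    """Venn-style hit overlap counts across drug arms."""
    sets = {arm: set(r.hit_units) for arm, r in results_by_arm.items()}
    arms = sorted(sets)
    out: dict[str, int] = {}
    from itertools import combinations

    for k in range(1, len(arms) + 1):
        for combo in combinations(arms, k):
            inter = set.intersection(*(sets[a] for a in combo))
            outer = set.union(
                *(sets[a] for a in arms if a not in combo), set()
            ) if len(combo) < len(arms) else set()
            out["&".join(combo)] = len(inter - outer)
    return out
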
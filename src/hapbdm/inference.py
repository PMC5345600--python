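"""Two-locus incompatibility inference from adjusted haplotype residuals.

The idea: in a viable-vs-inviable comparison, marginal allele-frequency
differences between the groups propagate linearly into two-locus haplotype
counts, while epistatic (BDM) or heterotic interactions show up as
*deviations* from that linear relation.  The pipeline is:

1. per marker pair, the 2 (group) × 4 (haplotype) count table is reduced to
   its viable-row adjusted residuals — one z-score per haplotype;
2. the *allele indicator* of a haplotype x.y at pair (A, B) is
   d_viable(x at A) + d_viable(y at B), the sum of the two single-locus
   viable-row allele residuals — the linear allele-frequency component;
3. an OLS model regresses haplotype residuals on the indicator plus a
   marker-pair × haplotype-class (parental/recombinant) interaction;
4. a significant interaction is decomposed into per-pair contrasts of
   parental minus recombinant fitted means: positive and significant means
   viable hybrids are enriched for parental haplotypes (a BDM
   incompatibility), negative means enriched for recombinants (heterosis).

A separate scan compares the two viable groups, which differ only in
cytotype, locus by locus: an allele-frequency difference there indicates a
cytonuclear interaction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contingency import (
    HAPLOTYPES,
    adjusted_residuals,
    allele_count_table,
    fisher_exact_two_sided,
    haplotype_class,
    haplotype_count_table,
    sequential_bonferroni,
)
from .genotyping import MarkerPanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidualRecord:
    """One viable-row adjusted haplotype residual with its covariates."""

    pair: tuple[str, str]
    haplotype: str  # one of I.I, I.II, II.I, II.II
    hap_class: str  # parental | recombinant
    residual: float
    indicator: float


def allele_residuals(
    viable: pd.DataFrame, inviable: pd.DataFrame, panel: MarkerPanel
) -> dict[str, dict[str, float]]:
    """Viable-row adjusted allele residuals per locus for one comparison.

    Returns ``{marker: {"I": d, "II": d}}``; in a 2×2 table the two allele
    residuals are exact negatives.  Undefined residuals (zero expected
    counts) are NaN.
    """
    out: dict[str, dict[str, float]] = {}
    for m in panel.markers:
        table = allele_count_table(viable, inviable, m, labels=("viable", "inviable"))
        resid = adjusted_residuals(table)
        out[m] = {"I": float(resid.loc["viable", "I"]), "II": float(resid.loc["viable", "II"])}
    return out


def allele_indicator(
    pair: tuple[str, str], haplotype: str, locus_residuals: dict[str, dict[str, float]]
) -> float:
    """Sum of the two single-locus viable-row allele residuals for a haplotype."""
    m1, m2 = sorted(pair)
    a1, a2 = haplotype.split(".")
    return locus_residuals[m1][a1] + locus_residuals[m2][a2]


def build_residual_dataset(
    viable: pd.DataFrame, inviable: pd.DataFrame, panel: MarkerPanel
) -> list[ResidualRecord]:
    """Assemble the residual/indicator dataset for one viable–inviable comparison.

    Produces up to 4 records per marker pair (one per haplotype).  A record is
    omitted, with a log entry, when its haplotype residual or either of its
    locus allele residuals is undefined because an expected count was zero.
    """
    if len(panel) < 2:
        raise ValueError("need at least two panel markers to form pairs")
    if not len(viable) or not len(inviable):
        raise ValueError("both groups must be nonempty")
    locus_resid = allele_residuals(viable, inviable, panel)
    records: list[ResidualRecord] = []
    for pair in panel.pairs():
        hct = haplotype_count_table(viable, inviable, pair, labels=("viable", "inviable"))
        resid = adjusted_residuals(hct.table)
        for hap in HAPLOTYPES:
            d = float(resid.loc["viable", hap])
            ind = allele_indicator(pair, hap, locus_resid)
            if math.isnan(d) or math.isnan(ind):
                logger.info("pair %s haplotype %s: residual inestimable, omitted", pair, hap)
                continue
            records.append(
                ResidualRecord(
                    pair=pair,
                    haplotype=hap,
                    hap_class=haplotype_class(hap),
                    residual=d,
                    indicator=ind,
                )
            )
    return records


@dataclass
class ModelFit:
    """OLS fit of haplotype residuals on indicator and pair×class cells.

    The design is parameterized as cell means: one column for the indicator
    slope plus one dummy per observed (pair, class) cell, no intercept.  For
    a complete 28-pair design this is 1 + 56 = 57 parameters, so the
    112-record dataset leaves 55 residual degrees of freedom.
    """

    param_names: list
    coef: np.ndarray
    rss: float
    n: int
    rank: int
    xtx_pinv: np.ndarray = field(repr=False)
    records: list = field(repr=False, default_factory=list)

    @property
    def df_resid(self) -> int:
        return self.n - self.rank

    @property
    def sigma2(self) -> float:
        return self.rss / self.df_resid if self.df_resid > 0 else float("nan")

    def cell_index(self, pair: tuple[str, str], hap_class: str) -> int | None:
        key = (pair, hap_class)
        try:
            return self.param_names.index(key)
        except ValueError:
            return None


def _fit_ols(x: np.ndarray, y: np.ndarray, names: list, records: list) -> ModelFit:
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    rss = float(resid @ resid)
    # an exact fit leaves only floating-point dust: snap it to zero
    if rss < 1e-12 * max(1.0, float(y @ y)):
        rss = 0.0
    return ModelFit(
        param_names=names,
        coef=coef,
        rss=rss,
        n=len(y),
        rank=int(rank),
        xtx_pinv=np.linalg.pinv(x.T @ x),
        records=records,
    )


def fit_residual_model(records: list[ResidualRecord]) -> ModelFit:
    """Fit residual ~ indicator + (pair × class) cell means by OLS.

    If a pair contributes no record for one class, that cell's column is
    simply absent (the design drops it), which reduces both the parameter
    count and, through it, the residual degrees of freedom.
    """
    if not records:
        raise ValueError("no records to fit")
    cells = sorted({(r.pair, r.hap_class) for r in records})
    missing = {p for p, _ in cells} - {p for p, c in cells if c == "parental"}
    missing |= {p for p, _ in cells} - {p for p, c in cells if c == "recombinant"}
    if missing:
        logger.warning("pairs with a whole class inestimable: %s", sorted(missing))
    names: list = ["indicator"] + cells
    x = np.zeros((len(records), 1 + len(cells)))
    y = np.empty(len(records))
    cell_pos = {c: i + 1 for i, c in enumerate(cells)}
    for i, r in enumerate(records):
        x[i, 0] = r.indicator
        x[i, cell_pos[(r.pair, r.hap_class)]] = 1.0
        y[i] = r.residual
    return _fit_ols(x, y, names, list(records))


def fit_additive_model(records: list[ResidualRecord]) -> ModelFit:
    """Reduced model: residual ~ indicator + pair + class (no interaction)."""
    if not records:
        raise ValueError("no records to fit")
    pairs = sorted({r.pair for r in records})
    names: list = ["intercept", "indicator"] + [("pair", p) for p in pairs[1:]] + ["recombinant"]
    x = np.zeros((len(records), len(names)))
    y = np.empty(len(records))
    pair_pos = {p: 2 + i for i, p in enumerate(pairs[1:])}
    for i, r in enumerate(records):
        x[i, 0] = 1.0
        x[i, 1] = r.indicator
        if r.pair in pair_pos:
            x[i, pair_pos[r.pair]] = 1.0
        x[i, -1] = 1.0 if r.hap_class == "recombinant" else 0.0
        y[i] = r.residual
    return _fit_ols(x, y, names, list(records))


@dataclass(frozen=True)
class InteractionTest:
    """Omnibus pair×class interaction test (F form and likelihood-ratio form)."""

    f_statistic: float
    df1: int
    df2: int
    p_value: float
    lr_statistic: float
    lr_df: int
    lr_p_value: float


def interaction_test(fit_full: ModelFit, fit_reduced: ModelFit) -> InteractionTest:
    """Compare the full (interaction) model against the additive reduction.

    F = ((RSS_r - RSS_f)/df1) / (RSS_f/df2); the Gaussian likelihood-ratio
    statistic n·log(RSS_r/RSS_f) is reported alongside with the same df.
    A saturated full model (RSS 0 with a worse reduced model) yields an
    infinite statistic, with a warning.
    """
    df1 = fit_full.rank - fit_reduced.rank
    df2 = fit_full.df_resid
    delta = max(fit_reduced.rss - fit_full.rss, 0.0)
    if df2 <= 0:
        raise ValueError("full model leaves no residual degrees of freedom")
    if df1 <= 0:  # nothing removed: the "reduction" is the full model
        return InteractionTest(0.0, df1, df2, 1.0, 0.0, df1, 1.0)
    if fit_full.rss == 0:
        if delta == 0:
            return InteractionTest(0.0, df1, df2, 1.0, 0.0, df1, 1.0)
        logger.warning("full model saturated (RSS=0); F reported as infinite")
        return InteractionTest(float("inf"), df1, df2, 0.0, float("inf"), df1, 0.0)
    f = (delta / df1) / (fit_full.rss / df2)
    p = float(stats.f.sf(f, df1, df2))
    lr = fit_full.n * math.log(fit_reduced.rss / fit_full.rss) if fit_reduced.rss > 0 else 0.0
    lr_p = float(stats.chi2.sf(lr, df1))
    return InteractionTest(float(f), df1, df2, p, float(lr), df1, lr_p)


def omnibus_interaction(records: list[ResidualRecord]) -> InteractionTest:
    """Convenience: fit full and additive models and test the interaction."""
    return interaction_test(fit_residual_model(records), fit_additive_model(records))


@dataclass(frozen=True)
class PairContrast:
    """Parental-minus-recombinant fitted-mean difference for one marker pair."""

    pair: tuple[str, str]
    estimate: float
    se: float
    t: float
    df: int
    p_value: float
    p_adjusted: float | None = None


def pairwise_contrasts(fit: ModelFit, adjust: str = "holm", alpha: float = 0.05) -> list[PairContrast]:
    """Post-hoc contrasts: per pair, parental minus recombinant cell mean.

    Evaluated at indicator 0, so the indicator term cancels and the contrast
    is a difference of two cell-mean coefficients; its standard error comes
    from the model's residual variance and the design's (X'X)⁻ matrix, tested
    against a t distribution on the residual df.  ``adjust`` ∈ {"none",
    "holm"} applies a Holm correction across the pairs.  Pairs with a whole
    class inestimable get a NaN contrast.
    """
    if adjust not in ("none", "holm"):
        raise ValueError("adjust must be 'none' or 'holm'")
    pairs = sorted({r.pair for r in fit.records})
    out: list[PairContrast] = []
    for pair in pairs:
        i_par = fit.cell_index(pair, "parental")
        i_rec = fit.cell_index(pair, "recombinant")
        if i_par is None or i_rec is None:
            out.append(PairContrast(pair, float("nan"), float("nan"), float("nan"), fit.df_resid, float("nan")))
            continue
        c = np.zeros(len(fit.param_names))
        c[i_par], c[i_rec] = 1.0, -1.0
        est = float(c @ fit.coef)
        var = fit.sigma2 * float(c @ fit.xtx_pinv @ c)
        se = math.sqrt(var) if var > 0 else 0.0
        if se == 0.0 or fit.df_resid <= 0:
            # degenerate (noise-free) fit: the contrast is exact
            null = abs(est) <= 1e-10 * max(1.0, float(np.abs(fit.coef).max()))
            if null:
                est = 0.0
            p = 1.0 if null else 0.0
            t = 0.0 if null else math.copysign(float("inf"), est)
        else:
            t = est / se
            p = 2.0 * float(stats.t.sf(abs(t), fit.df_resid))
        out.append(PairContrast(pair, est, se, t, fit.df_resid, p))
    if adjust == "holm":
        defined = [i for i, c in enumerate(out) if not math.isnan(c.p_value)]
        if defined:
            _, p_adj = sequential_bonferroni([out[i].p_value for i in defined], alpha=alpha)
            for i, pa in zip(defined, p_adj):
                c = out[i]
                out[i] = PairContrast(c.pair, c.estimate, c.se, c.t, c.df, c.p_value, float(pa))
    return out


@dataclass(frozen=True)
class PairClassification:
    """Interaction label for one marker pair: BDM, heterosis, or none."""

    pair: tuple[str, str]
    estimate: float
    p_value: float
    label: str  # BDM | none | heterosis


def classify_pairs(contrasts: list[PairContrast], alpha: float = 0.05) -> list[PairClassification]:
    """Label each pair from its contrast sign and significance.

    A significantly positive parental-minus-recombinant contrast (on the
    viable-row residual scale) means viable hybrids carry an excess of
    parental haplotypes — a BDM incompatibility.  A significantly negative
    one means recombinant excess in viables — heterosis.  The adjusted
    p-value is used when the contrasts carry one.
    """
    out = []
    for c in contrasts:
        p = c.p_adjusted if c.p_adjusted is not None else c.p_value
        if math.isnan(c.estimate) or math.isnan(p):
            label = "none"
        elif p < alpha and c.estimate > 0:
            label = "BDM"
        elif p < alpha and c.estimate < 0:
            label = "heterosis"
        else:
            label = "none"
        out.append(PairClassification(pair=c.pair, estimate=c.estimate, p_value=p, label=label))
    return out


def classification_summary(classifications: list[PairClassification]) -> dict[str, int]:
    """Counts of BDM / none / heterosis labels (Table-style summary)."""
    counts = {"BDM": 0, "none": 0, "heterosis": 0}
    for c in classifications:
        counts[c.label] += 1
    return counts


@dataclass(frozen=True)
class CytonuclearScanResult:
    """Per-locus allele-frequency comparison of the two viable groups."""

    table: pd.DataFrame  # one row per locus
    alpha: float


def cytonuclear_scan(
    viable_i: pd.DataFrame,
    viable_ii: pd.DataFrame,
    panel: MarkerPanel,
    alpha: float = 0.05,
) -> CytonuclearScanResult:
    """Scan each locus for allele-frequency differences between viable groups.

    The two viable groups differ only in their maternally inherited cytotype,
    so a locus where allele frequencies differ marks a nuclear allele whose
    viability effect depends on the cytoplasmic background.  Per locus a 2×2
    Fisher exact test is run and p-values are Holm-corrected across the
    panel.  A locus with zero calls in either group has an undefined p,
    reported as NaN and excluded from the correction.
    """
    rows = []
    for m in panel.markers:
        tab = allele_count_table(viable_i, viable_ii, m, labels=("viable_I", "viable_II"))
        n1, n2 = tab.sum(axis=1)
        if n1 == 0 or n2 == 0:
            p = float("nan")
            freq_diff = float("nan")
        else:
            p = fisher_exact_two_sided(tab)
            freq_diff = tab.loc["viable_I", "I"] / n1 - tab.loc["viable_II", "I"] / n2
        rows.append(
            {
                "marker": m,
                "viable_I.I": int(tab.loc["viable_I", "I"]),
                "viable_I.II": int(tab.loc["viable_I", "II"]),
                "viable_II.I": int(tab.loc["viable_II", "I"]),
                "viable_II.II": int(tab.loc["viable_II", "II"]),
                "freq_I_diff": freq_diff,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows).set_index("marker")
    p_holm = np.full(len(table), np.nan)
    sig = np.zeros(len(table), dtype=bool)
    defined = ~table["p_value"].isna().to_numpy()
    if defined.any():
        rej, p_adj = sequential_bonferroni(table.loc[defined, "p_value"], alpha=alpha)
        p_holm[defined] = p_adj
        sig[defined] = rej
    table["p_holm"] = p_holm
    table["significant"] = sig
    table["direction"] = np.where(
        table["significant"],
        np.where(table["freq_I_diff"] > 0, "more I in viable I", "more II in viable I"),
        "",
    )
    return CytonuclearScanResult(table=table, alpha=alpha)
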
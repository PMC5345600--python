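"""End-to-end orchestration: groups → CMH → residual model → labels → report.

The analysis runs up to three comparisons of the four hybrid groups:

* ``viableI-inviableI`` and ``viableII-inviableII`` — within-cytotype
  viable-vs-inviable contrasts: a generalized CMH test of overall haplotype
  differences across the marker-pair strata, then the residual linear model,
  per-pair contrasts and BDM/heterosis labels;
* ``viableI-viableII`` — the cytonuclear scan (the two viable groups differ
  only in cytotype, so per-locus allele-frequency differences implicate
  nuclear × cytoplasm interactions).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .contingency import generalized_cmh, haplotype_count_table, sequential_bonferroni
from .genotyping import assemble_groups, filter_hybrid_samples, panel_from_table
from .inference import (
    build_residual_dataset,
    classification_summary,
    classify_pairs,
    cytonuclear_scan,
    fit_additive_model,
    fit_residual_model,
    interaction_test,
    pairwise_contrasts,
)

logger = logging.getLogger(__name__)

VIABLE_INVIABLE_COMPARISONS = {
    "viableI-inviableI": (("viable", "I"), ("inviable", "I")),
    "viableII-inviableII": (("viable", "II"), ("inviable", "II")),
}
CYTONUCLEAR_COMPARISON = "viableI-viableII"
ALL_COMPARISONS = tuple(VIABLE_INVIABLE_COMPARISONS) + (CYTONUCLEAR_COMPARISON,)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run."""

    comparisons: tuple[str, ...] = ALL_COMPARISONS
    alpha: float = 0.05
    adjust: str = "holm"  # post-hoc contrast adjustment: holm | none
    max_missing: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.comparisons:
            raise ValueError("at least one comparison required")
        unknown = set(self.comparisons) - set(ALL_COMPARISONS)
        if unknown:
            raise ValueError(f"unknown comparisons: {sorted(unknown)}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def _pair_name(pair: tuple[str, str]) -> str:
    return f"{pair[0]}{pair[1]}"


def _viable_inviable_report(viable, inviable, panel, config: RunConfig) -> dict:
    strata = [
        haplotype_count_table(viable, inviable, pair, labels=("viable", "inviable"))
        for pair in panel.pairs()
    ]
    cmh = generalized_cmh(strata)
    records = build_residual_dataset(viable, inviable, panel)
    n_attempted = 4 * len(panel.pairs())
    fit = fit_residual_model(records)
    test = interaction_test(fit, fit_additive_model(records))
    contrasts = pairwise_contrasts(fit, adjust=config.adjust, alpha=config.alpha)
    classes = classify_pairs(contrasts, alpha=config.alpha)
    return {
        "n_viable": int(len(viable)),
        "n_inviable": int(len(inviable)),
        "cmh": {"M2": cmh.statistic, "df": cmh.df, "p": cmh.p_value},
        "residuals": {"attempted": n_attempted, "used": len(records), "omitted": n_attempted - len(records)},
        "model": {
            "F": test.f_statistic,
            "df1": test.df1,
            "df2": test.df2,
            "p": test.p_value,
            "LR": test.lr_statistic,
            "LR_df": test.lr_df,
            "LR_p": test.lr_p_value,
        },
        "pairs": [
            {
                "pair": _pair_name(cl.pair),
                "estimate": cl.estimate,
                "p": cl.p_value,
                "label": cl.label,
            }
            for cl in classes
        ],
        "summary": classification_summary(classes),
        "_records": records,  # stripped before serialization
    }


def run_full_analysis(
    table: pd.DataFrame,
    config: RunConfig = RunConfig(),
    out_dir: str | Path | None = None,
) -> dict:
    """Run the configured comparisons on a lineage-coded genotype table.

    Returns a JSON-serializable report; when ``out_dir`` is given, also
    writes ``report.json``, ``pairs.csv``, ``residuals.csv`` and (if the
    cytonuclear comparison ran) ``cytonuclear.csv``.  A comparison whose
    groups come up empty after filtering is skipped with an explicit report
    entry, and the run continues.
    """
    filtered = filter_hybrid_samples(table, max_missing=config.max_missing)
    groups = assemble_groups(filtered)
    panel = panel_from_table(filtered)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "alpha": config.alpha,
            "adjust": config.adjust,
            "config_hash": hashlib.sha256(
                json.dumps(asdict(config), sort_keys=True, default=str).encode()
            ).hexdigest()[:16],
        },
        "groups": {f"{ph} {cy}": int(len(df)) for (ph, cy), df in groups.items()},
        "comparisons": {},
    }

    cmh_ps: list[tuple[str, float]] = []
    for name in config.comparisons:
        if name == CYTONUCLEAR_COMPARISON:
            v1, v2 = groups[("viable", "I")], groups[("viable", "II")]
            if not len(v1) or not len(v2):
                report["comparisons"][name] = {"skipped": "empty group after filtering"}
                logger.warning("comparison %s skipped: empty group", name)
                continue
            scan = cytonuclear_scan(v1, v2, panel, alpha=config.alpha)
            report["comparisons"][name] = {
                "cytonuclear": scan.table.reset_index().to_dict(orient="records")
            }
        else:
            key_a, key_b = VIABLE_INVIABLE_COMPARISONS[name]
            a, b = groups[key_a], groups[key_b]
            if not len(a) or not len(b):
                report["comparisons"][name] = {"skipped": "empty group after filtering"}
                logger.warning("comparison %s skipped: empty group", name)
                continue
            sub = _viable_inviable_report(a, b, panel, config)
            report["comparisons"][name] = sub
            cmh_ps.append((name, sub["cmh"]["p"]))

    if cmh_ps:  # Holm across the CMH omnibus tests actually run
        _, p_adj = sequential_bonferroni([p for _, p in cmh_ps], alpha=config.alpha)
        for (name, _), pa in zip(cmh_ps, p_adj):
            report["comparisons"][name]["cmh"]["p_holm"] = float(pa)

    if out_dir is not None:
        _write_report(report, Path(out_dir))
    for sub in report["comparisons"].values():
        sub.pop("_records", None)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pair_rows, resid_rows, cyto_rows = [], [], []
    for name, sub in report["comparisons"].items():
        for row in sub.get("pairs", []):
            pair_rows.append({"comparison": name, **row})
        for rec in sub.get("_records", []):
            resid_rows.append(
                {
                    "comparison": name,
                    "pair": _pair_name(rec.pair),
                    "haplotype": rec.haplotype,
                    "class": rec.hap_class,
                    "residual": rec.residual,
                    "indicator": rec.indicator,
                }
            )
        for row in sub.get("cytonuclear", []):
            cyto_rows.append({"comparison": name, **row})
    if pair_rows:
        pd.DataFrame(pair_rows).to_csv(out_dir / "pairs.csv", index=False)
    if resid_rows:
        pd.DataFrame(resid_rows).to_csv(out_dir / "residuals.csv", index=False)
    if cyto_rows:
        pd.DataFrame(cyto_rows).to_csv(out_dir / "cytonuclear.csv", index=False)
    clean = {
        k: (
            {n: {kk: vv for kk, vv in s.items() if kk != "_records"} for n, s in v.items()}
            if k == "comparisons"
            else v
        )
        for k, v in report.items()
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True, default=float)
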
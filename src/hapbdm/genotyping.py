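"""Allele scoring, diagnostic-marker selection and hybrid-group assembly.

The study system is a haplodiploid arthropod: males develop from unfertilized
eggs and are haploid, so each F2 male carries exactly one allele per locus.
Loci in the marker panel are microsatellites fixed for different fragment
sizes in the two parental lineages (lineage I and lineage II), which makes the
lineage of origin of every call unambiguous.

A genotype table is a :class:`pandas.DataFrame` with the metadata columns
``sample_id``, ``phenotype`` (``viable``/``inviable``) and ``cytotype``
(``I``/``II``), followed by one column per panel marker holding lineage codes
``I``/``II`` (or raw fragment sizes before :func:`recode_to_lineage`).
Missing calls are NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PHENOTYPES = ("viable", "inviable")
CYTOTYPES = ("I", "II")
LINEAGES = ("I", "II")

#: metadata columns every genotype table carries before the marker columns
META_COLUMNS = ("sample_id", "phenotype", "cytotype")


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Marker columns of a genotype table, in table order."""
    return [c for c in table.columns if c not in META_COLUMNS]


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered panel of diagnostic biallelic markers.

    Parameters
    ----------
    markers
        Marker names; stored sorted lexicographically.  Marker-pair labels
        downstream (``("A", "B")`` etc.) follow this order.
    diagnostic_alleles
        Mapping ``marker -> (size fixed in lineage I, size fixed in lineage
        II)``.  May be empty when the panel is built from already lineage-coded
        data.
    """

    markers: tuple[str, ...]
    diagnostic_alleles: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker names must be unique")
        object.__setattr__(self, "markers", tuple(sorted(self.markers)))
        for m, (a, b) in self.diagnostic_alleles.items():
            if a == b:
                raise ValueError(f"marker {m!r}: diagnostic alleles must differ")

    def __len__(self) -> int:
        return len(self.markers)

    def pairs(self) -> list[tuple[str, str]]:
        """All unordered marker pairs, alphabetically ordered within and across."""
        ms = self.markers
        return [(ms[i], ms[j]) for i in range(len(ms)) for j in range(i + 1, len(ms))]


def score_allele(
    peaks: Sequence[tuple[float, float]],
    noise_cutoff: float = 400.0,
    dominance_ratio: float = 2.0,
) -> float | None:
    """Score a haploid allele call from a fragment-analysis peak list.

    Stutter and other PCR artefacts can put several peaks at one locus even
    though the template is haploid.  The call is the fragment size of the
    largest-area peak, accepted only if that area is at least
    ``dominance_ratio`` times the area of every other peak and at least
    ``noise_cutoff`` fluorescence units.  Anything else — including a tie for
    the largest peak — is a no-call (``None``).
    """
    if noise_cutoff <= 0:
        raise ValueError("noise_cutoff must be positive")
    if dominance_ratio < 1:
        raise ValueError("dominance_ratio must be >= 1")
    peaks = list(peaks)
    if any(area < 0 for _, area in peaks):
        raise ValueError("peak areas must be non-negative")
    if not peaks:
        return None
    areas = np.asarray([area for _, area in peaks], dtype=float)
    top = int(np.argmax(areas))
    top_area = areas[top]
    if top_area < noise_cutoff:
        return None
    others = np.delete(areas, top)
    # a tie for the maximum fails the dominance rule (ratio >= 1)
    if others.size and top_area < dominance_ratio * others.max():
        return None
    return float(peaks[top][0])


def score_peak_table(
    peaks: Mapping[tuple[str, str], Sequence[tuple[float, float]]],
    noise_cutoff: float = 400.0,
    dominance_ratio: float = 2.0,
) -> pd.DataFrame:
    """Apply :func:`score_allele` to a whole ``(sample, marker) -> peaks`` map.

    Returns a samples × markers table of raw fragment sizes (NaN = no-call),
    ready for :func:`recode_to_lineage` once metadata columns are joined.
    """
    records: dict[str, dict[str, float]] = {}
    for (sample, marker), plist in peaks.items():
        call = score_allele(plist, noise_cutoff=noise_cutoff, dominance_ratio=dominance_ratio)
        records.setdefault(sample, {})[marker] = np.nan if call is None else call
    out = pd.DataFrame.from_dict(records, orient="index").sort_index()
    out.index.name = "sample_id"
    return out.reindex(sorted(out.columns), axis=1)


def select_diagnostic_markers(
    parental_a: pd.DataFrame,
    parental_b: pd.DataFrame,
    min_call_rate: float = 0.8,
) -> MarkerPanel:
    """Select markers fixed for different alleles in the two parental samples.

    A marker is diagnostic when each parental population shows exactly one
    non-missing allele size, the two sizes differ, and the call rate is at
    least ``min_call_rate`` in both populations (amplification reliability).
    The first population is taken as lineage I, the second as lineage II.

    An empty panel is returned with a warning, not an error, when nothing
    passes.
    """
    cols_a = set(marker_columns(parental_a))
    cols_b = set(marker_columns(parental_b))
    if not len(parental_a) or not len(parental_b):
        raise ValueError("parental genotype tables must be nonempty")
    if cols_a != cols_b:
        raise ValueError("parental tables must share the same candidate marker set")

    kept: dict[str, tuple[float, float]] = {}
    for m in sorted(cols_a):
        a_calls = pd.to_numeric(parental_a[m], errors="coerce").dropna()
        b_calls = pd.to_numeric(parental_b[m], errors="coerce").dropna()
        rate_a = len(a_calls) / len(parental_a)
        rate_b = len(b_calls) / len(parental_b)
        if rate_a < min_call_rate or rate_b < min_call_rate:
            continue
        ua, ub = a_calls.unique(), b_calls.unique()
        if len(ua) == 1 and len(ub) == 1 and ua[0] != ub[0]:
            kept[m] = (float(ua[0]), float(ub[0]))
    if not kept:
        logger.warning("no marker passed diagnostic selection; panel is empty")
    return MarkerPanel(markers=tuple(kept), diagnostic_alleles=kept)


def recode_to_lineage(
    raw_calls: pd.DataFrame,
    panel: MarkerPanel,
    size_tol: float = 0.25,
) -> pd.DataFrame:
    """Recode raw fragment sizes to lineage-of-origin codes ``I``/``II``.

    Calls matching neither diagnostic allele (within ``size_tol`` base pairs)
    are non-parental artefacts; they become missing and are counted in a
    logged warning.  Marker columns not in the panel are rejected.
    """
    if not len(panel):
        raise ValueError("panel must be nonempty")
    extra = set(marker_columns(raw_calls)) - set(panel.markers)
    if extra:
        raise ValueError(f"markers absent from panel: {sorted(extra)}")

    out = raw_calls.copy()
    n_nonparental = 0
    for m in (c for c in marker_columns(raw_calls)):
        size_i, size_ii = panel.diagnostic_alleles[m]
        sizes = pd.to_numeric(out[m], errors="coerce").to_numpy(dtype=float)
        coded = np.full(len(sizes), np.nan, dtype=object)
        is_i = np.abs(sizes - size_i) <= size_tol
        is_ii = np.abs(sizes - size_ii) <= size_tol
        coded[is_i] = "I"
        coded[is_ii] = "II"
        nonparental = ~np.isnan(sizes) & ~is_i & ~is_ii
        n_nonparental += int(nonparental.sum())
        out[m] = coded
    if n_nonparental:
        logger.warning("%d non-parental allele call(s) recoded as missing", n_nonparental)
    return out


def filter_hybrid_samples(table: pd.DataFrame, max_missing: int = 2) -> pd.DataFrame:
    """Drop samples with more than ``max_missing`` missing marker calls.

    Samples that fail to amplify at many loci are unreliable templates (the
    panel default tolerates 2 missing of 8).  Retained counts per hybrid
    group are logged.
    """
    markers = marker_columns(table)
    n_missing = table[markers].isna().sum(axis=1)
    kept = table.loc[n_missing <= max_missing].reset_index(drop=True)
    if {"phenotype", "cytotype"}.issubset(table.columns):
        counts = kept.groupby(["phenotype", "cytotype"], observed=True).size()
        logger.info(
            "sample filter (<=%d missing of %d): retained %d/%d; per group: %s",
            max_missing, len(markers), len(kept), len(table), counts.to_dict(),
        )
    return kept


def assemble_groups(table: pd.DataFrame) -> dict[tuple[str, str], pd.DataFrame]:
    """Partition a genotype table into the four phenotype × cytotype groups.

    Returns a dict keyed by ``(phenotype, cytotype)`` with all four keys
    present even when empty.  Unknown phenotype or cytotype values are
    rejected.
    """
    bad_ph = set(table["phenotype"]) - set(PHENOTYPES)
    bad_cy = set(table["cytotype"]) - set(CYTOTYPES)
    if bad_ph or bad_cy:
        raise ValueError(f"unknown labels: phenotype={bad_ph or '{}'} cytotype={bad_cy or '{}'}")
    groups: dict[tuple[str, str], pd.DataFrame] = {}
    for ph in PHENOTYPES:
        for cy in CYTOTYPES:
            mask = (table["phenotype"] == ph) & (table["cytotype"] == cy)
            groups[(ph, cy)] = table.loc[mask].reset_index(drop=True)
    return groups


def panel_from_table(table: pd.DataFrame) -> MarkerPanel:
    """Build a panel from an already lineage-coded genotype table."""
    return MarkerPanel(markers=tuple(marker_columns(table)))
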
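"""Synthetic haplodiploid F2 male genotypes with controllable viability effects.

Design being emulated: two divergent lineages (I and II) are crossed
reciprocally; F1 hybrid females are kept unmated, so all their sons are
haploid recombinant F2 males carrying one gamete of the F1 genome.  Each son
inherits his mother's cytoplasm (cytotype), survives with a genotype-dependent
probability, and is genotyped at a panel of lineage-diagnostic markers with
some missing calls.

Viability is multiplicative: a baseline, times (1 - s) for every configured
two-locus epistatic penalty whose penalized haplotype class the genotype
carries (penalizing recombinants models a BDM incompatibility, penalizing
parentals models heterosis), times (1 - c) for every matching
allele × cytotype penalty (a cytonuclear incompatibility).  Per-marker
transmission bias models segregation distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .genotyping import CYTOTYPES

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = tuple("ABCDEFGH")

#: study-scale sampling quotas per (phenotype, cytotype) group, pre-filtering
STUDY_GROUP_SIZES = {
    ("viable", "I"): 92,
    ("viable", "II"): 94,
    ("inviable", "I"): 134,
    ("inviable", "II"): 134,
}


@dataclass(frozen=True)
class EpistaticEffect:
    """Two-locus viability penalty: class ∈ {recombinant (BDM), parental (heterosis)}."""

    pair: tuple[str, str]
    penalized_class: str
    s: float  # selection coefficient in [0, 1]

    def __post_init__(self) -> None:
        if self.penalized_class not in ("parental", "recombinant"):
            raise ValueError("penalized_class must be 'parental' or 'recombinant'")
        if not 0.0 <= self.s <= 1.0:
            raise ValueError("selection coefficient must lie in [0, 1]")
        object.__setattr__(self, "pair", tuple(sorted(self.pair)))


@dataclass(frozen=True)
class CytonuclearEffect:
    """Viability penalty when a nuclear allele sits on a mismatched cytotype."""

    marker: str
    allele: str  # I | II
    cytotype: str  # I | II
    c: float  # penalty in [0, 1]

    def __post_init__(self) -> None:
        if self.allele not in ("I", "II") or self.cytotype not in CYTOTYPES:
            raise ValueError("allele and cytotype must be 'I' or 'II'")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("penalty must lie in [0, 1]")


@dataclass(frozen=True)
class ViabilityModel:
    """Genotype → survival-probability map for simulated F2 males."""

    baseline: float = 0.5
    epistasis: tuple[EpistaticEffect, ...] = ()
    cytonuclear: tuple[CytonuclearEffect, ...] = ()
    transmission_bias: dict = field(default_factory=dict)  # marker -> P(lineage I)

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline <= 1.0:
            raise ValueError("baseline viability must lie in [0, 1]")
        for b in self.transmission_bias.values():
            if not 0.0 <= b <= 1.0:
                raise ValueError("transmission bias must lie in [0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Configuration for one simulated genotype dataset.

    ``recomb_fractions[j]`` is the recombination fraction between markers j
    and j+1 in panel order; 0.5 means unlinked (the default — the real panel's
    loci behave as independent).  When ``group_sizes`` is set, sampling
    continues until each (phenotype, cytotype) quota is reached, mirroring a
    field design that collects fixed numbers of viable adults and inviable
    eggs; otherwise ``n_f2`` males are drawn per cytotype and phenotypes fall
    where viability puts them.
    """

    markers: tuple[str, ...] = DEFAULT_MARKERS
    recomb_fractions: tuple[float, ...] | None = None
    group_sizes: dict | None = None  # defaults to STUDY_GROUP_SIZES
    n_f2: int | None = None
    viability: ViabilityModel = field(default_factory=ViabilityModel)
    missing_rate: float = 0.09
    missing_rate_inviable: float | None = None  # optional phenotype-dependent rate
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.recomb_fractions is None:
            object.__setattr__(self, "recomb_fractions", (0.5,) * (len(self.markers) - 1))
        if len(self.recomb_fractions) != len(self.markers) - 1:
            raise ValueError("need one recombination fraction per adjacent marker pair")
        if any(not 0.0 <= r <= 0.5 for r in self.recomb_fractions):
            raise ValueError("recombination fractions must lie in [0, 0.5]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.group_sizes is None and self.n_f2 is None:
            object.__setattr__(self, "group_sizes", dict(STUDY_GROUP_SIZES))
        if self.n_f2 is not None and self.n_f2 <= 0:
            raise ValueError("n_f2 must be positive")


def _draw_genomes(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n recombinant gametes as an (n, m) int8 matrix (0 = I, 1 = II).

    The first marker follows its transmission bias.  A marker separated from
    its predecessor by r < 0.5 switches lineage with probability r (its own
    bias field is ignored — linkage dominates); a marker at r = 0.5 is
    independent and follows its own bias.
    """
    markers = config.markers
    bias = config.viability.transmission_bias
    g = np.empty((n, len(markers)), dtype=np.int8)
    g[:, 0] = rng.random(n) >= bias.get(markers[0], 0.5)
    for j in range(1, len(markers)):
        r = config.recomb_fractions[j - 1]
        if r >= 0.5:
            g[:, j] = rng.random(n) >= bias.get(markers[j], 0.5)
        else:
            g[:, j] = g[:, j - 1] ^ (rng.random(n) < r)
    return g


def simulate_f2_male_genome(config: SimConfig, cytotype: str, rng: np.random.Generator) -> dict:
    """One F2 male gamete as ``{marker: "I"|"II"}`` (cytotype is maternal,
    independent of the nuclear draw)."""
    if cytotype not in CYTOTYPES:
        raise ValueError("cytotype must be 'I' or 'II'")
    row = _draw_genomes(config, 1, rng)[0]
    return {m: ("I", "II")[int(v)] for m, v in zip(config.markers, row)}


def _viability_vector(
    genomes: np.ndarray, cytotype: str, model: ViabilityModel, markers: tuple[str, ...]
) -> np.ndarray:
    idx = {m: i for i, m in enumerate(markers)}
    v = np.full(len(genomes), model.baseline)
    for eff in model.epistasis:
        i, j = idx[eff.pair[0]], idx[eff.pair[1]]
        recombinant = genomes[:, i] != genomes[:, j]
        hit = recombinant if eff.penalized_class == "recombinant" else ~recombinant
        v[hit] *= 1.0 - eff.s
    for eff in model.cytonuclear:
        if eff.cytotype != cytotype:
            continue
        code = 0 if eff.allele == "I" else 1
        v[genomes[:, idx[eff.marker]] == code] *= 1.0 - eff.c
    return v


def viability_probability(genotype: dict, cytotype: str, model: ViabilityModel) -> float:
    """Survival probability of one genotype under the viability model."""
    markers = tuple(genotype)
    row = np.array([[0 if genotype[m] == "I" else 1 for m in markers]], dtype=np.int8)
    return float(_viability_vector(row, cytotype, model, markers)[0])


def _as_frame(
    genomes: np.ndarray, phenotypes: np.ndarray, cytotype: str, config: SimConfig, start: int
) -> pd.DataFrame:
    data = {
        "sample_id": [f"{cytotype}-{start + i:04d}" for i in range(len(genomes))],
        "phenotype": np.where(phenotypes, "viable", "inviable"),
        "cytotype": cytotype,
    }
    for j, m in enumerate(config.markers):
        data[m] = np.where(genomes[:, j] == 0, "I", "II").astype(object)
    return pd.DataFrame(data)


def generate_dataset(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate a full lineage-coded genotype table for both reciprocal crosses.

    Each male is drawn as a recombinant gamete, survives with his viability
    probability, and then has calls knocked out at the missing rate.  A fixed
    seed reproduces the table bit for bit.  If a quota cannot be filled (for
    example an absorbing penalty leaves no survivors of a required class),
    the group is returned short with a warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    for cytotype in CYTOTYPES:
        if config.group_sizes is not None:
            need = {
                ph: int(config.group_sizes.get((ph, cytotype), 0))
                for ph in ("viable", "inviable")
            }
            got: dict[str, list[np.ndarray]] = {"viable": [], "inviable": []}
            have = {"viable": 0, "inviable": 0}
            batch = max(256, 2 * sum(need.values()))
            for _ in range(200):  # safety bound on rejection sampling
                if all(have[ph] >= need[ph] for ph in need):
                    break
                g = _draw_genomes(config, batch, rng)
                v = _viability_vector(g, cytotype, config.viability, config.markers)
                alive = rng.random(batch) < v
                for ph, mask in (("viable", alive), ("inviable", ~alive)):
                    short = need[ph] - have[ph]
                    if short > 0:
                        take = g[mask][:short]
                        got[ph].append(take)
                        have[ph] += len(take)
            else:
                logger.warning("cytotype %s: quota not filled after sampling bound", cytotype)
            parts, phenos = [], []
            for ph in ("viable", "inviable"):
                if got[ph]:
                    block = np.concatenate(got[ph])
                    parts.append(block)
                    phenos.append(np.full(len(block), ph == "viable"))
                if have[ph] < need[ph]:
                    logger.warning("group (%s, %s) ended short of quota", ph, cytotype)
            genomes = np.concatenate(parts) if parts else np.empty((0, len(config.markers)), np.int8)
            alive_flags = np.concatenate(phenos) if phenos else np.empty(0, bool)
        else:
            genomes = _draw_genomes(config, config.n_f2, rng)
            v = _viability_vector(genomes, cytotype, config.viability, config.markers)
            alive_flags = rng.random(config.n_f2) < v
        frames.append(_as_frame(genomes, alive_flags, cytotype, config, start=1))
    table = pd.concat(frames, ignore_index=True)

    rate_v = config.missing_rate
    rate_i = config.missing_rate if config.missing_rate_inviable is None else config.missing_rate_inviable
    rates = np.where(table["phenotype"].to_numpy() == "viable", rate_v, rate_i)
    for m in config.markers:
        drop = rng.random(len(table)) < rates
        col = table[m].to_numpy(dtype=object)
        col[drop] = np.nan
        table[m] = col
    empty = [k for k in (config.group_sizes or {}) if not ((table["phenotype"] == k[0]) & (table["cytotype"] == k[1])).any()]
    if empty:
        logger.warning("empty groups after simulation: %s", empty)
    return table


def config_from_dict(raw: dict) -> SimConfig:
    """Build a :class:`SimConfig` from a plain dict (YAML/JSON payload)."""
    raw = dict(raw)
    vm = dict(raw.pop("viability", {}))
    eps = tuple(
        EpistaticEffect(pair=tuple(e["pair"]), penalized_class=e["penalized_class"], s=float(e["s"]))
        for e in vm.pop("epistasis", [])
    )
    cyt = tuple(
        CytonuclearEffect(
            marker=e["marker"], allele=e["allele"], cytotype=e["cytotype"], c=float(e["c"])
        )
        for e in vm.pop("cytonuclear", [])
    )
    model = ViabilityModel(
        baseline=float(vm.pop("baseline", 0.5)),
        epistasis=eps,
        cytonuclear=cyt,
        transmission_bias=dict(vm.pop("transmission_bias", {})),
    )
    if vm:
        raise ValueError(f"unknown viability fields: {sorted(vm)}")
    if "markers" in raw:
        raw["markers"] = tuple(raw["markers"])
    if raw.get("recomb_fractions") is not None:
        raw["recomb_fractions"] = tuple(raw["recomb_fractions"])
    if raw.get("group_sizes") is not None:
        raw["group_sizes"] = {
            (ph, cy): int(n)
            for key, n in raw["group_sizes"].items()
            for ph, cy in [key if isinstance(key, tuple) else tuple(key.split("-"))]
        }
    return SimConfig(viability=model, **raw)


def load_config(path) -> SimConfig:
    """Read a simulation configuration from a YAML (or JSON) file."""
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def null_config(seed: int | None = None, **overrides) -> SimConfig:
    """Study-scale configuration with no genetic effects on viability."""
    return SimConfig(seed=seed, **overrides)


def bdm_config(
    pair: tuple[str, str] = ("C", "F"),
    s: float = 0.9,
    seed: int | None = None,
    **overrides,
) -> SimConfig:
    """Study-scale configuration with one recombinant-penalized (BDM) pair."""
    model = ViabilityModel(epistasis=(EpistaticEffect(pair=pair, penalized_class="recombinant", s=s),))
    return SimConfig(viability=model, seed=seed, **overrides)
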
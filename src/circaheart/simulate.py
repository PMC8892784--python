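"""Synthetic around-the-clock expression studies with known ground truth.

The generator emulates the statistical structure the analysis stages assume:
a 3-group (C / W / WRF) x 6-timepoint (ZT1..ZT21, every 4 h) x 3-replicate
design; per-gene cosinor rhythms with group-specific phase distributions
(uniform across the day in controls, clustered near ZT12.5 in shift workers,
bimodal near ZT8 and ZT20.5 under restricted feeding); amplitude dampening in
WRF; one out-of-phase replicate series in W (replicate desynchrony); and an
animal-level block of differentially expressed genes gated by per-animal
responder flags in WRF.  Noise is multiplicative log-normal — expression is
positive and fpkm variance grows with the mean — with sigma chosen so the
multiplicative coefficient of variation equals ``noise_cv``:
sigma = sqrt(ln(1 + cv^2)).

Every draw flows from the mandatory config seed, so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (ExpressionMatrix, GeneSetPair, ModuleSet, SampleMeta,
                 assign_replicates, format_sample_label)

logger = logging.getLogger("circaheart")

__all__ = [
    "PhaseDistribution",
    "GeneTruth",
    "StudyConfig",
    "GroundTruth",
    "generate_gene_profile",
    "generate_study",
    "generate_module_catalog",
    "generate_disease_gene_sets",
]

GROUPS = ("C", "W", "WRF")
DEFAULT_ZTS = (1.0, 5.0, 9.0, 13.0, 17.0, 21.0)


@dataclass(frozen=True)
class PhaseDistribution:
    """Phase distribution on the 24-h circle: uniform, or a von Mises mixture.

    ``components`` is a tuple of (mean_hour, kappa, weight); an empty tuple
    means uniform on [0, 24).
    """

    components: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self):
        if self.components:
            w = sum(c[2] for c in self.components)
            if not np.isclose(w, 1.0):
                raise ValueError(f"component weights must sum to 1, got {w}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if not self.components:
            return rng.uniform(0.0, 24.0, size)
        weights = np.array([c[2] for c in self.components])
        which = rng.choice(len(self.components), size=size, p=weights)
        out = np.empty(size)
        for i, (mu, kappa, _) in enumerate(self.components):
            mask = which == i
            ang = rng.vonmises(mu * 2 * np.pi / 24.0 - np.pi, kappa, int(mask.sum())) + np.pi
            out[mask] = ang * 24.0 / (2 * np.pi)
        return out % 24.0


@dataclass
class GeneTruth:
    """Planted parameters for one gene: mesor, per-group rhythm and fold."""

    gene_id: str
    baseline: float
    amplitude: Mapping[str, float]
    phase: Mapping[str, float]
    de_multiplier: Mapping[str, float]
    noise_cv: float = 0.0
    module_id: str | None = None

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError("baseline must be positive")
        for g, a in self.amplitude.items():
            if a < 0:
                raise ValueError("amplitude must be non-negative")
            if a > self.baseline:
                raise ValueError(
                    f"amplitude {a} exceeds baseline {self.baseline} for group {g}"
                )
        for g, ph in self.phase.items():
            if not (0 <= ph < 24):
                raise ValueError(f"phase {ph} outside [0, 24)")


def noise_sigma(noise_cv: float) -> float:
    """Log-normal sigma giving a multiplicative CV of ``noise_cv``."""
    return float(np.sqrt(np.log1p(noise_cv ** 2)))


def generate_gene_profile(truth: GeneTruth, samples: Sequence[SampleMeta],
                          rng: np.random.Generator) -> np.ndarray:
    """Expression values for one gene over the given samples.

    value(s) = de_multiplier[group] * (baseline + amplitude[group] *
    cos(2 pi (zt - phase[group]) / 24)) * exp(eps), eps ~ N(0, sigma) with
    sigma = sqrt(ln(1 + noise_cv^2)).  Values are strictly positive because
    amplitude <= baseline.
    """
    zts = np.array([s.zt for s in samples])
    amp = np.array([truth.amplitude.get(s.group, 0.0) for s in samples])
    phase = np.array([truth.phase.get(s.group, 0.0) for s in samples])
    mult = np.array([truth.de_multiplier.get(s.group, 1.0) for s in samples])
    mean = mult * (truth.baseline + amp * np.cos(2 * np.pi * (zts - phase) / 24.0))
    sigma = noise_sigma(truth.noise_cv)
    eps = rng.normal(0.0, sigma, len(samples)) if sigma > 0 else np.zeros(len(samples))
    return mean * np.exp(eps)


@dataclass
class StudyConfig:
    """Study conditions for one synthetic dataset; the seed is mandatory.

    Defaults encode the emulated design: ~2-fold fewer rhythmic genes in W
    and ~2-fold more in WRF than in controls, phase clustering at ZT12.5 (W)
    and ZT8/ZT20.5 (WRF), dampened WRF amplitudes, an 8-h out-of-phase W
    replicate series, and a mostly-upregulated WRF DE block expressed only in
    responder animals.
    """

    seed: int
    n_genes: int = 10_257
    zts: tuple[float, ...] = DEFAULT_ZTS
    n_replicates: int = 3
    frac_rhythmic: Mapping[str, float] = field(
        default_factory=lambda: {"C": 0.10, "W": 0.05, "WRF": 0.20})
    phase_distribution: Mapping[str, PhaseDistribution] = field(
        default_factory=lambda: {
            "C": PhaseDistribution(),
            "W": PhaseDistribution(((12.5, 4.0, 1.0),)),
            "WRF": PhaseDistribution(((8.0, 6.0, 0.5), (20.5, 6.0, 0.5))),
        })
    rel_amplitude: float = 0.5
    amplitude_dampening: float = 0.7      # applied to WRF amplitudes
    replicate_phase_shift: float = 8.0    # hours, applied to W replicate series 2
    shifted_replicate: int = 2
    n_de_genes: int | None = None  # default: scales as 875/10257 of n_genes
    de_up_fraction: float = 808.0 / 875.0
    de_fold: float = 2.0
    responder_fraction: float = 2.0 / 3.0
    noise_cv: float = 0.2
    baseline_range: tuple[float, float] = (2.0, 100.0)

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        for g in GROUPS:
            f = self.frac_rhythmic.get(g, 0.0)
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"frac_rhythmic[{g}]={f} outside [0, 1]")
        for name in ("de_up_fraction", "responder_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not (0.0 <= self.rel_amplitude <= 1.0):
            raise ValueError("rel_amplitude must lie in [0, 1] to keep means positive")
        if self.n_de_genes is None:
            # emulated study: 875 DE genes out of 10,257 expressed
            self.n_de_genes = int(round(self.n_genes * 875.0 / 10_257.0))
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes exceeds n_genes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["phase_distribution"] = {
            g: list(pd_.components) for g, pd_ in self.phase_distribution.items()
        }
        return d


@dataclass
class GroundTruth:
    """Planted per-gene parameters plus the WRF responder animals."""

    genes: pd.DataFrame
    responder_animals: tuple[int, ...]
    config: StudyConfig

    def rhythmic_genes(self, group: str) -> set[str]:
        df = self.genes
        return set(df.loc[df[f"rhythmic_{group}"], "gene_id"])

    def de_genes(self, direction: str | None = None) -> set[str]:
        df = self.genes
        sel = df["de_direction"] != ""
        if direction is not None:
            sel = df["de_direction"] == direction
        return set(df.loc[sel, "gene_id"])


def _build_samples(config: StudyConfig) -> list[SampleMeta]:
    samples = []
    animal = 0
    for group in GROUPS:
        for rep in range(1, config.n_replicates + 1):
            for zt in config.zts:
                animal += 1
                samples.append(SampleMeta(group, animal, zt, 0))
    samples = assign_replicates(samples)
    # deterministic column order: group, then ZT, then replicate
    samples.sort(key=lambda s: (GROUPS.index(s.group), s.zt, s.replicate_index))
    return samples


def generate_study(config: StudyConfig) -> tuple[ExpressionMatrix, GroundTruth]:
    """Generate the full expression matrix and its ground truth.

    54 samples by default (3 groups x 6 ZTs x 3 replicates).  Rhythmic genes
    are drawn independently per group from ``frac_rhythmic``; WRF amplitudes
    are multiplied by ``amplitude_dampening``; the W replicate series
    ``shifted_replicate`` is phase-shifted by ``replicate_phase_shift`` hours;
    DE genes carry ``de_fold`` (up) or 1/``de_fold`` (down) in WRF, applied
    only to responder animals.
    """
    rng = np.random.default_rng(config.seed)
    samples = _build_samples(config)
    g = config.n_genes
    gene_ids = np.array([f"g{i + 1:05d}" for i in range(g)])
    lo, hi = config.baseline_range
    baseline = 10.0 ** rng.uniform(np.log10(lo), np.log10(hi), g)

    rhythmic = {grp: rng.random(g) < config.frac_rhythmic.get(grp, 0.0) for grp in GROUPS}
    phases = {grp: config.phase_distribution[grp].sample(rng, g) for grp in GROUPS}
    amp = {}
    for grp in GROUPS:
        a = np.where(rhythmic[grp], config.rel_amplitude * baseline, 0.0)
        if grp == "WRF":
            a = a * config.amplitude_dampening
        amp[grp] = a

    de_idx = rng.choice(g, size=config.n_de_genes, replace=False)
    n_up = int(round(config.n_de_genes * config.de_up_fraction))
    de_direction = np.full(g, "", dtype=object)
    de_direction[de_idx[:n_up]] = "up"
    de_direction[de_idx[n_up:]] = "down"
    de_mult_wrf = np.ones(g)
    de_mult_wrf[de_direction == "up"] = config.de_fold
    de_mult_wrf[de_direction == "down"] = 1.0 / config.de_fold

    wrf_animals = sorted({s.animal_id for s in samples if s.group == "WRF"})
    responder = {a: bool(rng.random() < config.responder_fraction) for a in wrf_animals}

    sigma = noise_sigma(config.noise_cv)
    values = np.empty((g, len(samples)))
    for j, s in enumerate(samples):
        grp = s.group
        phase_eff = phases[grp].copy()
        if grp == "W" and s.replicate_index == config.shifted_replicate:
            phase_eff = (phase_eff + config.replicate_phase_shift) % 24.0
        mean = baseline + amp[grp] * np.cos(2 * np.pi * (s.zt - phase_eff) / 24.0)
        if grp == "WRF" and responder[s.animal_id]:
            mean = mean * de_mult_wrf
        values[:, j] = mean
    if sigma > 0:
        values *= np.exp(rng.normal(0.0, sigma, values.shape))

    data = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                        columns=[format_sample_label(s) for s in samples])
    matrix = ExpressionMatrix(data, samples)

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "baseline": baseline,
        "noise_cv": config.noise_cv,
        "de_direction": de_direction,
        "de_mult_WRF": de_mult_wrf,
    })
    for grp in GROUPS:
        truth[f"rhythmic_{grp}"] = rhythmic[grp]
        truth[f"amplitude_{grp}"] = amp[grp]
        truth[f"phase_{grp}"] = np.where(rhythmic[grp], phases[grp], np.nan)
    responders = tuple(a for a in wrf_animals if responder[a])
    logger.info("simulated %d genes x %d samples (rhythmic C/W/WRF = %d/%d/%d; "
                "%d DE genes; %d/%d WRF responders)",
                g, len(samples), *(int(rhythmic[x].sum()) for x in GROUPS),
                config.n_de_genes, len(responders), len(wrf_animals))
    return matrix, GroundTruth(truth, responders, config)


def generate_module_catalog(n_modules: int, sizes: Sequence[int] | int,
                            planted_enrichment: Mapping[str, float],
                            up_gene_set: Iterable[str],
                            universe: Sequence[str],
                            rng: np.random.Generator,
                            null_module_id: str = "M0") -> ModuleSet:
    """Partition the gene universe into disjoint modules M1..Mn plus M0.

    Each planted module draws round(fraction * size) members from
    ``up_gene_set`` and the remainder from outside it; unplanted modules draw
    uniformly, so their up-fraction matches the background rate in
    expectation.  All unassigned genes form the null module.
    """
    universe = list(universe)
    if isinstance(sizes, int):
        sizes = [sizes] * n_modules
    if len(sizes) != n_modules:
        raise ValueError("sizes must match n_modules")
    if any(s < 1 for s in sizes):
        raise ValueError("module sizes must be >= 1")
    for mid, f in planted_enrichment.items():
        if not (0.0 <= f <= 1.0):
            raise ValueError(f"planted fraction for {mid} outside [0, 1]")
    up = set(up_gene_set) & set(universe)
    available = set(universe)
    modules: dict[str, frozenset[str]] = {}
    for i, size in enumerate(sizes, start=1):
        mid = f"M{i}"
        frac = planted_enrichment.get(mid)
        if frac is None:
            pool = sorted(available)
            if len(pool) < size:
                raise ValueError(f"not enough unassigned genes for module {mid}")
            chosen = set(rng.choice(pool, size=size, replace=False))
        else:
            n_from_up = int(round(frac * size))
            up_pool = sorted(available & up)
            other_pool = sorted(available - up)
            if len(up_pool) < n_from_up:
                raise ValueError(
                    f"up_gene_set has {len(up_pool)} unassigned members; module "
                    f"{mid} needs {n_from_up}"
                )
            if len(other_pool) < size - n_from_up:
                raise ValueError(f"not enough non-up genes for module {mid}")
            chosen = set(rng.choice(up_pool, size=n_from_up, replace=False))
            chosen |= set(rng.choice(other_pool, size=size - n_from_up, replace=False))
        modules[mid] = frozenset(chosen)
        available -= chosen
    if not available:
        raise ValueError("no genes left for the null module")
    modules[null_module_id] = frozenset(available)
    return ModuleSet(modules, null_module_id=null_module_id)


def generate_disease_gene_sets(n_up: int, n_down: int, shift_log2: float,
                               truth: GroundTruth | pd.DataFrame,
                               rng: np.random.Generator,
                               label: str = "synthetic") -> GeneSetPair:
    """Draw disease up/down gene sets informed by the planted WRF/C fold.

    With ``shift_log2 > 0`` the up set samples genes whose planted log2
    WRF/C multiplier exceeds ``shift_log2`` (symmetrically below
    ``-shift_log2`` for the down set); with ``shift_log2 == 0`` both sets are
    uniform random draws.  The two sets are always disjoint.
    """
    genes = truth.genes if isinstance(truth, GroundTruth) else truth
    ids = genes["gene_id"].to_numpy()
    log2_ratio = np.log2(genes["de_mult_WRF"].to_numpy())
    if n_up + n_down > len(ids):
        raise ValueError("requested sets exceed the number of genes")
    if shift_log2 == 0.0:
        pool = rng.choice(ids, size=n_up + n_down, replace=False)
        up, down = set(pool[:n_up]), set(pool[n_up:])
    else:
        up_pool = ids[log2_ratio > shift_log2]
        down_pool = ids[log2_ratio < -shift_log2]
        if len(up_pool) < n_up:
            raise ValueError(
                f"only {len(up_pool)} genes exceed +{shift_log2} log2; need {n_up}")
        if len(down_pool) < n_down:
            raise ValueError(
                f"only {len(down_pool)} genes fall below -{shift_log2} log2; need {n_down}")
        up = set(rng.choice(up_pool, size=n_up, replace=False))
        down_pool = np.array(sorted(set(down_pool) - up))
        down = set(rng.choice(down_pool, size=n_down, replace=False)) if n_down else set()
    return GeneSetPair(frozenset(up), frozenset(down), label=label)
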
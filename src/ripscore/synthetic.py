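"""Synthetic RIP-seq counts, LFQ tables and annotation universes with planted truth.

Every generator is a pure function of (config, seed): the same configuration
reproduces byte-identical output. Defaults mirror the study geometry the
analysis modules were built for — a ~6000-gene yeast transcriptome assayed
with three IP and three input replicates, an AP-MS design with six bait and
three control runs, and a focal annotation category covering ~3% of the
background but strongly over-represented among planted targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .interactome import ProteinGroupTable
from .riprank import CountMatrix
from .setstats import AnnotationTable, GeneSet

__all__ = [
    "RipSimConfig",
    "ProtSimConfig",
    "SimTruth",
    "simulate_ripseq",
    "simulate_proteome",
    "simulate_annotation",
]


class ValidationError(ValueError):
    pass


@dataclass
class SimTruth:
    """Planted ground truth: which ids carry an effect, and how big."""

    planted_ids: list[str]
    effects: dict[str, float]
    config: dict

    def __post_init__(self) -> None:
        if set(self.planted_ids) - set(self.effects):
            raise ValidationError("every planted id needs an effect")


@dataclass
class RipSimConfig:
    """RIP-seq count simulation: NB counts with a planted IP enrichment.

    Input counts are NB(mu_g * sf_j, alpha); IP counts get the planted
    log2 fold change on the mean. Baseline means mu_g are log-normal;
    library-size factors are drawn uniformly from ``sf_range``.
    """

    n_genes: int = 2000
    n_rep: int = 3
    enriched_frac: float = 0.05
    log2fc_mean: float = 3.0
    log2fc_sd: float = 0.0  # 0 = point mass
    dispersion: float = 0.05
    mean_log: float = np.log(200.0)  # log-normal location of baseline means
    mean_log_sd: float = 1.0
    sf_range: tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.enriched_frac <= 1.0:
            raise ValidationError("enriched_frac must lie in [0, 1]")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.n_rep < 1 or self.n_genes < 1:
            raise ValidationError("n_genes and n_rep must be positive")
        if self.seed is None:
            raise ValidationError("seed is mandatory")


@dataclass
class ProtSimConfig:
    """AP-MS LFQ simulation: Gaussian log2 intensities with MNAR dropout.

    Latent log2 intensities are Normal per protein group; planted interactors
    get ``effect_log2`` added in bait samples. Each value is observed with
    logistic probability ``1/(1+exp(-slope*(x - midpoint)))`` — lower
    intensity, more missing — and unobserved values are stored as LFQ 0.
    A fraction of groups gets razor+unique peptide count exactly 1 to
    exercise the evidence filter.
    """

    n_groups: int = 1000
    n_bait: int = 6
    n_control: int = 3
    interactor_frac: float = 0.05
    effect_log2: float = 3.0
    within_sd: float = 0.5
    base_mean: float = 25.0
    base_sd: float = 2.0
    detect_midpoint: float = 21.0
    detect_slope: float = 1.0
    single_peptide_frac: float = 0.05
    contaminant_frac: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bait < 2 or self.n_control < 2:
            raise ValidationError("group sizes must be >= 2")
        if not 0.0 <= self.interactor_frac <= 1.0:
            raise ValidationError("interactor_frac must lie in [0, 1]")
        if self.within_sd <= 0 or self.base_sd <= 0:
            raise ValidationError("SDs must be > 0")
        if self.detect_slope < 0:
            raise ValidationError("detect_slope must be >= 0")


def simulate_ripseq(cfg: RipSimConfig) -> tuple[CountMatrix, SimTruth]:
    """NB IP/input count matrix with a planted enriched gene fraction."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"GSIM{i:04d}" for i in range(cfg.n_genes)]
    mu = rng.lognormal(cfg.mean_log, cfg.mean_log_sd, size=cfg.n_genes)
    n_planted = int(round(cfg.enriched_frac * cfg.n_genes))
    planted_idx = rng.choice(cfg.n_genes, size=n_planted, replace=False)
    delta = np.zeros(cfg.n_genes)
    if n_planted:
        eff = (
            np.full(n_planted, cfg.log2fc_mean)
            if cfg.log2fc_sd == 0
            else rng.normal(cfg.log2fc_mean, cfg.log2fc_sd, size=n_planted)
        )
        delta[planted_idx] = eff
    n_samp = 2 * cfg.n_rep
    sf = rng.uniform(*cfg.sf_range, size=n_samp)
    cols = []
    condition = []
    samples = []
    replicate = []
    for j in range(n_samp):
        cond = "input" if j < cfg.n_rep else "IP"
        rep = (j % cfg.n_rep) + 1
        mean_j = mu * sf[j] * (2.0 ** delta if cond == "IP" else 1.0)
        cols.append(_nb_draw(rng, mean_j, cfg.dispersion))
        condition.append(cond)
        replicate.append(rep)
        samples.append(f"{cond}_{rep}")
    counts = np.column_stack(cols)
    cm = CountMatrix(genes, counts, samples, condition, replicate)
    truth = SimTruth(
        planted_ids=[genes[i] for i in sorted(planted_idx)],
        effects={genes[i]: float(delta[i]) for i in planted_idx},
        config=vars(cfg).copy(),
    )
    return cm, truth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with variance mu + alpha*mu^2; alpha = 0 is exactly Poisson."""
    if alpha == 0:
        return rng.poisson(mean)
    size_param = 1.0 / alpha
    return rng.negative_binomial(size_param, size_param / (size_param + mean))


def simulate_proteome(cfg: ProtSimConfig) -> tuple[ProteinGroupTable, SimTruth]:
    """LFQ table with planted bait-enriched interactors and MNAR missingness."""
    rng = np.random.default_rng(cfg.seed)
    ids = [f"PSIM{i:04d}" for i in range(cfg.n_groups)]
    base = rng.normal(cfg.base_mean, cfg.base_sd, size=cfg.n_groups)
    n_planted = int(round(cfg.interactor_frac * cfg.n_groups))
    planted_idx = rng.choice(cfg.n_groups, size=n_planted, replace=False)
    shift = np.zeros(cfg.n_groups)
    shift[planted_idx] = cfg.effect_log2
    n_samp = cfg.n_bait + cfg.n_control
    group = ["bait"] * cfg.n_bait + ["control"] * cfg.n_control
    samples = [f"bait_{i + 1}" for i in range(cfg.n_bait)] + [
        f"control_{i + 1}" for i in range(cfg.n_control)
    ]
    means = base[:, None] + shift[:, None] * np.array(
        [g == "bait" for g in group], float
    )[None, :]
    latent = rng.normal(means, cfg.within_sd)
    if np.isinf(cfg.detect_slope):
        p_detect = (latent > cfg.detect_midpoint).astype(float)
    else:
        p_detect = 1.0 / (1.0 + np.exp(-cfg.detect_slope * (latent - cfg.detect_midpoint)))
    observed = rng.random(latent.shape) < p_detect
    lfq = np.where(observed, 2.0**latent, 0.0)
    peptides = rng.integers(2, 20, size=cfg.n_groups)
    single = rng.random(cfg.n_groups) < cfg.single_peptide_frac
    peptides[single] = 1
    contaminant = rng.random(cfg.n_groups) < cfg.contaminant_frac
    table = ProteinGroupTable(
        group_ids=ids,
        values=lfq,
        samples=samples,
        group=group,
        razor_unique_peptides=peptides,
        reverse_flag=np.zeros(cfg.n_groups, bool),
        contaminant_flag=contaminant,
    )
    truth = SimTruth(
        planted_ids=[ids[i] for i in sorted(planted_idx)],
        effects={ids[i]: float(cfg.effect_log2) for i in planted_idx},
        config=vars(cfg).copy(),
    )
    return table, truth


def simulate_annotation(
    n_genes: int = 6000,
    category_specs: dict[str, float] | None = None,
    target_set: list[str] | None = None,
    enrichment_factor: float = 8.0,
    seed: int = 0,
    focal_category: str = "cell_wall",
) -> tuple[AnnotationTable, SimTruth]:
    """Annotation universe with an over-represented focal category in targets.

    Background membership probabilities come from ``category_specs``
    (default: the focal category at 3%); within ``target_set`` the focal
    probability is inflated by ``enrichment_factor`` (default 8x: ~24% of
    targets in a 3% category). Target ids not generated here are added to
    the universe.
    """
    specs = dict(category_specs or {focal_category: 0.03})
    if sum(specs.values()) > 1.0:
        raise ValidationError("category fractions must sum to <= 1")
    if focal_category not in specs:
        raise ValidationError(f"focal category {focal_category!r} missing from specs")
    target_frac = specs[focal_category] * enrichment_factor
    if target_frac > 1.0:
        raise ValidationError(
            f"infeasible inflation: {specs[focal_category]:.3f} x "
            f"{enrichment_factor:g} > 1"
        )
    rng = np.random.default_rng(seed)
    genes = [f"GSIM{i:04d}" for i in range(n_genes)]
    universe = list(dict.fromkeys(genes + list(target_set or [])))
    targets = set(target_set or [])
    cats: dict[str, set[str]] = {name: set() for name in specs}
    for g in universe:
        u = rng.random()
        cum = 0.0
        for name, frac in specs.items():
            pr = frac
            if name == focal_category and g in targets:
                pr = target_frac
            # focal membership is decided independently for targets so the
            # inflated fraction is exact in expectation
            if name == focal_category:
                if rng.random() < pr:
                    cats[name].add(g)
                continue
            cum += frac
            if u < cum and u >= cum - frac:
                cats[name].add(g)
    ann = AnnotationTable(
        universe=GeneSet.from_iterable("universe", universe),
        categories={n: GeneSet.from_iterable(n, s) for n, s in cats.items()},
    )
    truth = SimTruth(
        planted_ids=sorted(targets),
        effects={g: enrichment_factor for g in targets},
        config={
            "n_genes": n_genes,
            "category_specs": specs,
            "enrichment_factor": enrichment_factor,
            "seed": seed,
            "focal_category": focal_category,
        },
    )
    return ann, truth
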
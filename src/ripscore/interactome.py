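"""Label-free AP-MS interactor calling from protein-group LFQ intensities.

The pipeline reproduces the Perseus-style workflow used for volcano-plot
interactor analysis of affinity-enriched bait samples against negative
controls:

    filter -> log2 -> valid-value filter -> down-shifted imputation -> test

Stages are order-enforced on the table object. Missing values (LFQ 0, the
MaxQuant convention, or NaN) are assumed missing-not-at-random — below the
detection limit — and imputed per sample from a Gaussian down-shifted by
1.8 observed-SD units with width 0.3 SD units. Significance comes from an
s0-moderated two-sample t statistic against a permutation-derived cutoff at
a stated FDR (default 0.01), reported one-sided for the enrichment side.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProteinGroupTable",
    "ImputationParams",
    "PipelineOrderError",
    "filter_protein_groups",
    "log2_lfq",
    "valid_value_filter",
    "impute_downshift",
    "two_sample_t",
    "s0_statistic",
    "permutation_fdr_volcano",
    "enrichment_report",
    "identification_bookkeeping",
    "run_interactome",
]

BAIT, CONTROL = "bait", "control"

# pipeline stage ordering; each operation checks its predecessor
_STAGES = ["raw", "filtered", "log2", "valid", "imputed"]


class ValidationError(ValueError):
    pass


class PipelineOrderError(RuntimeError):
    """Raised when a pipeline stage is applied out of order."""


@dataclass
class ImputationParams:
    """Down-shifted Gaussian imputation parameters, in per-sample SD units."""

    width: float = 0.3
    downshift: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("width must be > 0")
        if self.downshift < 0:
            raise ValidationError("downshift must be >= 0")


@dataclass
class ProteinGroupTable:
    """Protein-group x sample LFQ intensities with evidence counts and design.

    ``values`` holds raw LFQ intensities at stage "raw"/"filtered" (0 = not
    quantified) and log2 intensities with NaN for missing from stage "log2" on.
    """

    group_ids: list[str]
    values: np.ndarray
    samples: list[str]
    group: list[str]  # per-sample: "bait" or "control"
    razor_unique_peptides: np.ndarray
    reverse_flag: np.ndarray
    contaminant_flag: np.ndarray
    member_proteins: list[str] | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.razor_unique_peptides = np.asarray(self.razor_unique_peptides, int)
        self.reverse_flag = np.asarray(self.reverse_flag, bool)
        self.contaminant_flag = np.asarray(self.contaminant_flag, bool)
        n_g, n_s = len(self.group_ids), len(self.samples)
        if self.values.shape != (n_g, n_s):
            raise ValidationError(
                f"values shape {self.values.shape} != ({n_g}, {n_s})"
            )
        bad = sorted(set(self.group) - {BAIT, CONTROL})
        if bad:
            raise ValidationError(f"unknown sample groups: {bad}")
        if len(self.group) != n_s:
            raise ValidationError("design length does not match sample count")
        if self.stage in ("raw", "filtered") and np.any(
            np.nan_to_num(self.values) < 0
        ):
            raise ValidationError("LFQ intensities must be >= 0")

    @property
    def n_groups(self) -> int:
        return len(self.group_ids)

    def mask(self, which: str) -> np.ndarray:
        return np.array([g == which for g in self.group])

    def _require_stage(self, expected: str, op: str) -> None:
        if self.stage != expected:
            raise PipelineOrderError(
                f"{op} expects a table at stage {expected!r}, got {self.stage!r}; "
                f"the order is {' -> '.join(_STAGES)}"
            )


def filter_protein_groups(
    table: ProteinGroupTable, min_razor_unique: int = 2
) -> tuple[ProteinGroupTable, dict[str, int]]:
    """Drop single-peptide, reverse-hit and contaminant protein groups.

    Groups identified by a single razor-and-unique peptide (count below
    ``min_razor_unique``) and groups flagged as reverse or potential
    contaminant are removed. Returns the filtered table and a filter log of
    removed counts.
    """
    table._require_stage("raw", "filter_protein_groups")
    low_evidence = table.razor_unique_peptides < min_razor_unique
    flagged = table.reverse_flag | table.contaminant_flag
    keep = ~(low_evidence | flagged)
    log = {
        "input_groups": table.n_groups,
        "removed_single_peptide": int(np.sum(low_evidence)),
        "removed_reverse": int(np.sum(table.reverse_flag & ~low_evidence)),
        "removed_contaminant": int(
            np.sum(table.contaminant_flag & ~table.reverse_flag & ~low_evidence)
        ),
        "kept_groups": int(np.sum(keep)),
    }
    out = _subset_groups(table, keep)
    out.stage = "filtered"
    return out, log


def _subset_groups(table: ProteinGroupTable, keep: np.ndarray) -> ProteinGroupTable:
    idx = np.flatnonzero(keep)
    return replace(
        table,
        group_ids=[table.group_ids[i] for i in idx],
        values=table.values[idx],
        razor_unique_peptides=table.razor_unique_peptides[idx],
        reverse_flag=table.reverse_flag[idx],
        contaminant_flag=table.contaminant_flag[idx],
        member_proteins=(
            [table.member_proteins[i] for i in idx] if table.member_proteins else None
        ),
    )


def log2_lfq(table: ProteinGroupTable) -> ProteinGroupTable:
    """log2-transform intensities; zeros (and NaN) become explicit missing.

    An intensity of exactly 1 maps to log2 value 0 and stays valid — only
    zero/NaN mark "not quantified".
    """
    table._require_stage("filtered", "log2_lfq")
    v = table.values
    if np.any(np.nan_to_num(v) < 0):
        raise ValidationError("negative LFQ intensity")
    missing = ~(v > 0)  # 0 and NaN
    out = np.full_like(v, np.nan)
    out[~missing] = np.log2(v[~missing])
    res = replace(table, values=out)
    res.stage = "log2"
    return res


def valid_value_filter(
    table: ProteinGroupTable, min_frac: float = 0.6
) -> tuple[ProteinGroupTable, dict[str, int]]:
    """Keep groups quantified in >= ``min_frac`` of samples in bait OR control.

    The comparison is ``>=`` on the exact fraction, so 4 of 6 (0.667) passes
    at 0.6 while 3 of 6 does not.
    """
    table._require_stage("log2", "valid_value_filter")
    bait = table.mask(BAIT)
    ctrl = table.mask(CONTROL)
    if bait.sum() == 0 or ctrl.sum() == 0:
        raise ValidationError("both bait and control groups must be non-empty")
    valid = ~np.isnan(table.values)
    frac_bait = valid[:, bait].sum(axis=1) / bait.sum()
    frac_ctrl = valid[:, ctrl].sum(axis=1) / ctrl.sum()
    keep = (frac_bait >= min_frac) | (frac_ctrl >= min_frac)
    out = _subset_groups(table, keep)
    out.stage = "valid"
    log = {"input_groups": table.n_groups, "kept_groups": int(np.sum(keep))}
    return out, log


def impute_downshift(
    table: ProteinGroupTable, params: ImputationParams
) -> tuple[ProteinGroupTable, np.ndarray]:
    """Impute missing log2 values per sample from a down-shifted Gaussian.

    For sample *j* with observed mean ``m_j`` and SD ``s_j`` each missing
    entry is drawn from ``Normal(m_j - downshift*s_j, (width*s_j)^2)``.
    Deterministic under ``params.seed``. Returns the completed table and the
    boolean imputation mask.
    """
    table._require_stage("valid", "impute_downshift")
    rng = np.random.default_rng(params.seed)
    v = table.values.copy()
    mask = np.isnan(v)
    for j, name in enumerate(table.samples):
        obs = v[~mask[:, j], j]
        if obs.size < 2:
            raise ValidationError(
                f"sample {name!r} has {obs.size} observed values; need >= 2 to impute"
            )
        m, s = obs.mean(), obs.std(ddof=1)
        n_miss = int(mask[:, j].sum())
        if n_miss:
            v[mask[:, j], j] = rng.normal(
                m - params.downshift * s, params.width * s, size=n_miss
            )
    out = replace(table, values=v)
    out.stage = "imputed"
    return out, mask


def two_sample_t(
    bait_values: np.ndarray,
    control_values: np.ndarray,
    kind: str = "student",
) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance Student by default.

    Degenerate zero-variance input: equal means give (0, 1); unequal means
    give an infinite statistic with p = 0 (the caller sees the degeneracy in
    the infinite t).
    """
    a = np.asarray(bait_values, float)
    b = np.asarray(control_values, float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need >= 2 values per side")
    if kind not in ("student", "welch"):
        raise ValidationError(f"unknown test kind {kind!r}")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=(kind == "student"))
    return float(t), float(p)


def s0_statistic(
    mean_diff: float | np.ndarray, se: float | np.ndarray, s0: float
) -> float | np.ndarray:
    """Moderated statistic ``d = mean_diff / (se + s0)``.

    ``s0`` damps the significance of small fold changes with tiny variance;
    s0 = 0 recovers the plain t statistic.
    """
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValidationError("standard error must be > 0")
    if s0 < 0:
        raise ValidationError("s0 must be >= 0")
    d = np.asarray(mean_diff, float) / (se + s0)
    return float(d) if d.ndim == 0 else d


def _row_t_parts(
    values: np.ndarray, bait: np.ndarray, ctrl: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Row-wise pooled-variance mean difference, SE and df."""
    a, b = values[:, bait], values[:, ctrl]
    n1, n2 = a.shape[1], b.shape[1]
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (
        n1 + n2 - 2
    )
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    df = np.full(len(values), n1 + n2 - 2)
    return diff, se, df


def _distinct_permutations(
    n_samples: int, n_bait: int, n_perm: int, rng: np.random.Generator,
    observed: tuple[int, ...] | None = None,
) -> list[np.ndarray]:
    """Distinct null bait-label assignments as boolean masks.

    The observed assignment is excluded (its statistics are the observed
    ones, not null draws); for equal group sizes a split and its complement
    give identical |d| and count once.
    """
    from math import comb

    equal_sizes = 2 * n_bait == n_samples

    def canonical(combo: tuple[int, ...]) -> tuple[int, ...]:
        if equal_sizes and 0 not in combo:
            return tuple(sorted(set(range(n_samples)) - set(combo)))
        return combo

    excluded = {canonical(observed)} if observed is not None else set()
    total = comb(n_samples, n_bait)
    if equal_sizes:
        total //= 2
    total -= len(excluded)
    if total < 2:
        raise ValidationError("fewer than 2 distinct label permutations exist")

    def to_mask(combo: tuple[int, ...]) -> np.ndarray:
        m = np.zeros(n_samples, bool)
        m[list(combo)] = True
        return m

    if total <= n_perm:
        out = []
        for combo in itertools.combinations(range(n_samples), n_bait):
            c = canonical(combo)
            if c != combo or c in excluded:
                continue
            out.append(to_mask(c))
        return out
    chosen: set[tuple[int, ...]] = set()
    while len(chosen) < n_perm:
        pick = canonical(tuple(sorted(rng.choice(n_samples, n_bait, replace=False))))
        if pick not in excluded:
            chosen.add(pick)
    return [to_mask(c) for c in sorted(chosen)]


def permutation_fdr_volcano(
    table: ProteinGroupTable,
    s0: float = 0.1,
    fdr: float = 0.01,
    n_perm: int = 250,
    seed: int = 0,
    perm_aggregate: str = "mean",
) -> tuple[pd.DataFrame, float]:
    """Volcano-style significance calling with a permutation-estimated FDR.

    The observed ``|d|`` (s0-moderated t) per group is compared with its null
    distribution over distinct bait/control label assignments (all enumerated
    when fewer than ``n_perm`` exist). The cutoff is the smallest c with

        FDR(c) = aggregate_perm #{|d_perm| >= c} / #{|d_obs| >= c} <= fdr

    after enforcing monotonicity of FDR(c) in c. Groups on the enrichment
    side (mean_diff > 0) at or above the cutoff are ``significant``;
    depleted-side hits are classed separately.

    Returns the record table and the |d| cutoff (inf when no c attains the
    target FDR).
    """
    table._require_stage("imputed", "permutation_fdr_volcano")
    bait = table.mask(BAIT)
    ctrl = table.mask(CONTROL)
    if bait.sum() < 2 or ctrl.sum() < 2:
        raise ValidationError("need >= 2 samples per group")
    if perm_aggregate not in ("mean", "median"):
        raise ValidationError(f"unknown perm_aggregate {perm_aggregate!r}")
    v = table.values
    diff, se, df = _row_t_parts(v, bait, ctrl)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, diff / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_stat), df)
    d_obs = diff / (se + s0)

    rng = np.random.default_rng(seed)
    perms = _distinct_permutations(
        len(table.samples), int(bait.sum()), n_perm, rng,
        observed=tuple(np.flatnonzero(bait)),
    )
    abs_obs = np.abs(d_obs)
    null_counts = []
    for m in perms:
        pd_diff, pd_se, _ = _row_t_parts(v, m, ~m)
        d_perm = np.abs(pd_diff / (pd_se + s0))
        null_counts.append(d_perm)
    null_abs = np.concatenate(null_counts)
    n_eff_perm = len(perms)

    # candidate cutoffs: the observed |d| values, scanned from large to small
    cand = np.unique(abs_obs)[::-1]
    sorted_obs = np.sort(abs_obs)
    sorted_null = np.sort(null_abs)
    obs_ge = (len(sorted_obs) - np.searchsorted(sorted_obs, cand, side="left")).astype(float)
    perm_ge = (len(sorted_null) - np.searchsorted(sorted_null, cand, side="left")).astype(float)
    if perm_aggregate == "mean":
        perm_per = perm_ge / n_eff_perm
    else:
        per_perm = np.stack([
            len(nc) - np.searchsorted(np.sort(nc), cand, side="left")
            for nc in null_counts
        ])
        perm_per = np.median(per_perm, axis=0).astype(float)
    est = np.minimum(perm_per / np.maximum(obs_ge, 1.0), 1.0)
    est = np.maximum.accumulate(est)  # FDR(c) non-increasing as c grows
    passing = np.flatnonzero(est <= fdr)
    cutoff = float(cand[passing[-1]]) if passing.size else np.inf

    n_valid_bait = np.sum(~np.isnan(v[:, bait]), axis=1)
    n_valid_ctrl = np.sum(~np.isnan(v[:, ctrl]), axis=1)
    enriched = (abs_obs >= cutoff) & (diff > 0)
    depleted = (abs_obs >= cutoff) & (diff < 0)
    sig_class = np.where(enriched, "enriched", np.where(depleted, "depleted", "ns"))
    records = pd.DataFrame(
        {
            "group_id": table.group_ids,
            "log2_enrichment": diff,
            "t_stat": t_stat,
            "p": p,
            "d_stat": d_obs,
            "significant": enriched,
            "significance_class": sig_class,
            "n_valid_bait": n_valid_bait,
            "n_valid_control": n_valid_ctrl,
        }
    )
    return records, cutoff


def enrichment_report(
    records: pd.DataFrame, annotations: dict[str, set[str]] | None = None
) -> pd.DataFrame:
    """Volcano table: log2 enrichment, -log10 p, d, class, annotation tags."""
    out = records.copy()
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out["p"].to_numpy(float))
    for name, members in (annotations or {}).items():
        out[name] = out["group_id"].isin(members)
    cols = [
        "group_id",
        "log2_enrichment",
        "neg_log10_p",
        "d_stat",
        "significance_class",
    ]
    extra = [c for c in out.columns if c not in cols]
    return out[cols + extra]


def identification_bookkeeping(table: ProteinGroupTable) -> dict[str, int]:
    """Counts of protein groups identified in either sample set vs quantified in both.

    A group is "identified" in a sample set (bait or control) if it has at
    least one quantified (nonzero, non-NaN) intensity there; "quantified in
    both" requires at least one in each. Works on raw or log2 tables.
    """
    v = table.values
    valid = ~np.isnan(v) & (np.nan_to_num(v) != 0) if table.stage in (
        "raw", "filtered") else ~np.isnan(v)
    in_bait = valid[:, table.mask(BAIT)].any(axis=1)
    in_ctrl = valid[:, table.mask(CONTROL)].any(axis=1)
    return {
        "identified_either": int(np.sum(in_bait | in_ctrl)),
        "quantified_both": int(np.sum(in_bait & in_ctrl)),
    }


def run_interactome(
    table: ProteinGroupTable,
    s0: float = 0.1,
    fdr: float = 0.01,
    width: float = 0.3,
    downshift: float = 1.8,
    min_valid_frac: float = 0.6,
    n_perm: int = 250,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, dict[str, int]]:
    """Full interactor pipeline in the enforced stage order."""
    filtered, flog = filter_protein_groups(table)
    logged = log2_lfq(filtered)
    valid, vlog = valid_value_filter(logged, min_valid_frac)
    imputed, _ = impute_downshift(
        valid, ImputationParams(width=width, downshift=downshift, seed=seed)
    )
    records, cutoff = permutation_fdr_volcano(
        imputed, s0=s0, fdr=fdr, n_perm=n_perm, seed=seed
    )
    log = {**{f"filter_{k}": v for k, v in flog.items()},
           **{f"valid_{k}": v for k, v in vlog.items()}}
    return records, cutoff, log
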
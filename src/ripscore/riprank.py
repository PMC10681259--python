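"""Per-gene IP/input enrichment from raw RIP-seq counts and Vfactor target selection.

The workflow mirrors a standard bulk RNA-seq differential pipeline specialised
to the two-group IP-versus-input contrast:

1. median-of-ratios size factors (the DESeq normalisation scheme),
2. per-gene method-of-moments negative-binomial dispersion,
3. a two-group NB Wald test fitted by Fisher scoring with log link and
   size-factor offsets,
4. Benjamini-Hochberg adjustment,
5. the composite selection score ``vfactor = log2fc * (-log10 p)`` with a
   strict ``> threshold`` cut (default 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CountMatrix",
    "TargetSet",
    "median_of_ratios_size_factors",
    "estimate_dispersions",
    "nb_wald_test",
    "bh_adjust",
    "vfactor",
    "select_targets",
    "run_enrichment",
    "DEFAULT_VFACTOR_THRESHOLD",
    "P_FLOOR",
    "ALPHA_FLOOR",
]

DEFAULT_VFACTOR_THRESHOLD = 50.0
#: p-values are floored here before -log10 so Vfactors stay finite.
P_FLOOR = 1e-300
#: lower bound for the per-gene NB dispersion estimate.
ALPHA_FLOOR = 1e-8

IP, INPUT = "IP", "input"


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


@dataclass
class CountMatrix:
    """Gene x sample integer counts with an IP/input design.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (systematic ORF names canonical).
    counts
        Non-negative integer array, shape (n_genes, n_samples).
    samples
        Sample names, one per column.
    condition
        Per-sample condition, each ``"IP"`` or ``"input"``.
    replicate
        Per-sample positive integer replicate id.
    """

    gene_ids: list[str]
    counts: np.ndarray
    samples: list[str]
    condition: list[str]
    replicate: list[int]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            seen: set[str] = set()
            dups = sorted({g for g in self.gene_ids if g in seen or seen.add(g)})
            raise ValidationError(f"duplicate gene ids: {', '.join(dups)}")
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.gene_ids),
            len(self.samples),
        ):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.samples)} samples"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise ValidationError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        bad = sorted(set(self.condition) - {IP, INPUT})
        if bad:
            raise ValidationError(f"unknown conditions: {bad}; expected IP/input")
        for cond in (IP, INPUT):
            if cond not in self.condition:
                raise ValidationError(f"no samples with condition {cond!r}")
        if len(self.condition) != len(self.samples) or len(self.replicate) != len(
            self.samples
        ):
            raise ValidationError("design length does not match sample count")
        if any(int(r) <= 0 for r in self.replicate):
            raise ValidationError("replicate ids must be positive integers")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def condition_mask(self, cond: str) -> np.ndarray:
        return np.array([c == cond for c in self.condition])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.samples)


@dataclass
class TargetSet:
    """A named set of gene identifiers with free-text provenance."""

    name: str
    gene_ids: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError(f"duplicate gene ids in target set {self.name!r}")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def as_set(self) -> set[str]:
        return set(self.gene_ids)


def median_of_ratios_size_factors(counts: CountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    Only genes with strictly positive counts in every sample enter the
    pseudo-reference (the per-gene geometric mean); the factor of sample *j*
    is the median ratio of its counts to that reference.

    Raises
    ------
    ValidationError
        If no gene has all-positive counts (the reference is undefined).
    """
    mat = counts.counts if isinstance(counts, CountMatrix) else np.asarray(counts)
    mat = mat.astype(float)
    all_pos = np.all(mat > 0, axis=1)
    if not np.any(all_pos):
        raise ValidationError(
            "size factors undefined: no gene has all-positive counts across samples"
        )
    ref = mat[all_pos]
    geomean = np.exp(np.mean(np.log(ref), axis=1))
    factors = np.median(ref / geomean[:, None], axis=0)
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean -> 1
    return factors


def estimate_dispersions(
    counts: CountMatrix, size_factors: np.ndarray, alpha_floor: float = ALPHA_FLOOR
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene method-of-moments NB dispersion on normalised counts.

    Within each condition with >= 2 samples, ``alpha = (s^2 - mean)/mean^2``
    on size-factor-normalised counts; estimates are averaged across
    conditions and floored at ``alpha_floor``. Under the NB parameterisation
    used throughout (variance = mu + alpha mu^2) a Poisson gene has alpha 0.

    Returns
    -------
    alpha : ndarray
        Floored dispersion per gene.
    all_zero : ndarray of bool
        Flags genes whose counts are zero everywhere (alpha is the floor
        by convention, not by estimation).
    """
    if counts.n_samples < 2:
        raise ValidationError("dispersion estimation needs >= 2 samples")
    norm = counts.counts / np.asarray(size_factors)[None, :]
    all_zero = np.all(counts.counts == 0, axis=1)
    per_cond = []
    for cond in (IP, INPUT):
        sub = norm[:, counts.condition_mask(cond)]
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / mu**2
        a[~np.isfinite(a)] = 0.0
        per_cond.append(a)
    if not per_cond:
        # single replicate per condition: no within-group variance available
        alpha = np.full(counts.n_genes, alpha_floor)
    else:
        alpha = np.maximum(np.mean(per_cond, axis=0), alpha_floor)
    alpha[all_zero] = alpha_floor
    return alpha, all_zero


def _fit_group_log_mean(
    y: np.ndarray, sf: np.ndarray, alpha: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MLE of beta in mu_ij = sf_j * exp(beta_i) for NB rows, by Fisher scoring.

    Vectorised over genes (rows of ``y``). Returns (beta, se_beta, converged);
    rows whose counts are all zero get beta = -inf and se = inf.
    """
    y = np.asarray(y, float)
    sf = np.asarray(sf, float)
    zero_rows = np.all(y == 0, axis=1)
    with np.errstate(divide="ignore"):
        beta = np.log(np.mean(y / sf[None, :], axis=1))
    beta[zero_rows] = 0.0  # placeholder; overwritten below
    converged = np.zeros(len(y), bool)
    active = ~zero_rows
    a = alpha[:, None]
    for _ in range(max_iter):
        if not np.any(active):
            break
        mu = sf[None, :] * np.exp(beta[:, None])
        w = mu / (1.0 + a * mu)
        score = np.sum((y - mu) / (1.0 + a * mu), axis=1)
        info = np.sum(w, axis=1)
        step = np.where(active, score / np.maximum(info, 1e-300), 0.0)
        step = np.clip(step, -10.0, 10.0)
        beta = beta + step
        done = np.abs(step) < tol
        converged |= done & active
        active &= ~done
    mu = sf[None, :] * np.exp(beta[:, None])
    info = np.sum(mu / (1.0 + a * mu), axis=1)
    with np.errstate(divide="ignore"):
        se = 1.0 / np.sqrt(info)
    beta[zero_rows] = -np.inf
    se[zero_rows] = np.inf
    converged[zero_rows] = True  # degenerate, handled by the caller
    return beta, se, converged


def nb_wald_test(
    counts: CountMatrix,
    size_factors: np.ndarray,
    dispersion: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Two-group NB Wald test of IP versus input, vectorised over genes.

    Fits ``mu = sf * exp(beta_cond)`` per condition by Fisher scoring (the
    two groups decouple, so each is a one-parameter NB GLM with log link and
    size-factor offsets; zeros are handled by the likelihood, no pseudocounts).
    ``log2fc = (beta_IP - beta_input)/ln 2``; the Wald p is the two-sided
    normal tail of log2fc/se.

    Genes with an all-zero condition are degenerate: the reported log2fc
    falls back to normalised means with a half-count added, p is NA, and
    ``degenerate`` is set. Non-convergence is flagged with NA p, never silent.
    """
    sf = np.asarray(size_factors, float)
    dispersion = np.asarray(dispersion, float)
    ip_mask = counts.condition_mask(IP)
    in_mask = counts.condition_mask(INPUT)
    y = counts.counts.astype(float)
    b_ip, se_ip, conv_ip = _fit_group_log_mean(
        y[:, ip_mask], sf[ip_mask], dispersion, max_iter, tol
    )
    b_in, se_in, conv_in = _fit_group_log_mean(
        y[:, in_mask], sf[in_mask], dispersion, max_iter, tol
    )
    ln2 = np.log(2.0)
    log2fc = (b_ip - b_in) / ln2
    se = np.sqrt(se_ip**2 + se_in**2) / ln2
    degenerate = np.isinf(b_ip) | np.isinf(b_in)
    converged = conv_ip & conv_in
    with np.errstate(invalid="ignore", divide="ignore"):
        z = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[degenerate | ~converged] = np.nan

    # half-count fallback keeps the reported fold change finite for all-zero groups
    norm = y / sf[None, :]
    mean_ip = norm[:, ip_mask].mean(axis=1)
    mean_in = norm[:, in_mask].mean(axis=1)
    fallback = np.log2(mean_ip + 0.5) - np.log2(mean_in + 0.5)
    log2fc = np.where(degenerate, fallback, log2fc)
    se = np.where(degenerate, np.nan, se)

    base_mean = norm.mean(axis=1)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "p": p,
            "dispersion": dispersion,
            "converged": converged,
            "degenerate": degenerate,
        }
    )


def bh_adjust(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NA entries are propagated and excluded from the effective test count m.
    """
    p = np.asarray(p_values, float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def vfactor(
    log2fc: float | np.ndarray,
    p: float | np.ndarray,
    floor: float | None = P_FLOOR,
) -> float | np.ndarray:
    """Composite selection score: ``log2fc * (-log10 p)``.

    The sign follows the fold change, so depleted genes score negative.
    With ``floor`` set (default 1e-300), p is clipped from below so an
    underflowed p of exactly 0 still yields a finite score; pass
    ``floor=None`` to forbid p <= 0 outright.
    """
    p = np.asarray(p, float)
    if floor is None:
        if np.any(p <= 0):
            raise ValidationError("p <= 0 with flooring disabled")
        pf = p
    else:
        pf = np.maximum(p, floor)
    if np.any(pf > 1):
        raise ValidationError("p-values must be <= 1")
    result = np.asarray(log2fc, float) * (-np.log10(pf))
    return float(result) if result.ndim == 0 else result


def select_targets(
    records: pd.DataFrame,
    threshold: float = DEFAULT_VFACTOR_THRESHOLD,
    name: str = "vfactor_targets",
) -> TargetSet:
    """Genes with ``vfactor`` strictly above ``threshold``, in input order.

    The inequality is strict: a score exactly at the threshold is excluded.
    """
    if "vfactor" not in records.columns:
        raise ValidationError("records lack a 'vfactor' column")
    vf = records["vfactor"].to_numpy(float)
    keep = np.nan_to_num(vf, nan=-np.inf) > threshold
    genes = records.loc[keep, "gene_id"].tolist()
    return TargetSet(
        name=name,
        gene_ids=genes,
        provenance=f"vfactor > {threshold:g} on {len(records)} tested genes",
    )


def run_enrichment(
    counts: CountMatrix,
    vfactor_threshold: float = DEFAULT_VFACTOR_THRESHOLD,
    use_adjusted_p: bool = False,
    p_floor: float = P_FLOOR,
) -> pd.DataFrame:
    """Full enrichment table: size factors through Vfactor selection.

    ``use_adjusted_p`` switches the Vfactor to BH-adjusted p; the default is
    the raw test p.
    """
    sf = median_of_ratios_size_factors(counts)
    alpha, _ = estimate_dispersions(counts, sf)
    table = nb_wald_test(counts, sf, alpha)
    table["padj"] = bh_adjust(table["p"].to_numpy())
    p_for_v = table["padj"] if use_adjusted_p else table["p"]
    table["vfactor"] = vfactor(
        table["log2fc"].to_numpy(), np.nan_to_num(p_for_v.to_numpy(), nan=1.0), p_floor
    )
    table["selected"] = np.nan_to_num(
        table["vfactor"].to_numpy(), nan=-np.inf
    ) > vfactor_threshold
    return table
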
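"""Normalization and negative-binomial differential expression.

Counts are normalized with median-of-ratios size factors; per-feature NB
dispersions come from a pooled method-of-moments estimate shrunk toward a
fitted mean-dispersion trend; the test is a Wald test on the log ratio of
pseudocounted group means with a delta-method standard error, followed by
Benjamini-Hochberg correction per contrast. Features with zero counts in
every sample of a contrast are excluded from testing and from the BH
denominator and flagged instead of carrying silent zeros.

A separate counts-per-million matrix (library-size normalization to one
million per sample, no transcript-length correction) feeds the
reinstatement fold changes downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix
from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

#: Pseudocount added to group means before the log fold-change ratio.
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class Contrast:
    """A two-level comparison with the other design factor held fixed.

    ``log2fc`` downstream is alternative over reference, e.g.
    ``Contrast("TG_vs_WT@3", ("age", 3), ("genotype", "WT", "TG"))`` tests
    TG against WT among 3-month samples.
    """

    name: str
    fixed: tuple[str, object] | None  # (factor, level) held constant
    tested: tuple[str, object, object]  # (factor, reference, alternative)

    def __post_init__(self) -> None:
        if self.fixed is not None and self.fixed[0] == self.tested[0]:
            raise ValueError("tested and fixed factors must differ")

    def masks(self, design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        """(reference, alternative) boolean sample masks."""
        base = np.ones(len(design), dtype=bool)
        if self.fixed is not None:
            factor, level = self.fixed
            base &= design[factor].astype(str).to_numpy() == str(level)
        factor, ref, alt = self.tested
        col = design[factor].astype(str).to_numpy()
        ref_mask = base & (col == str(ref))
        alt_mask = base & (col == str(alt))
        for level, mask in ((ref, ref_mask), (alt, alt_mask)):
            if not mask.any():
                raise ValueError(f"contrast {self.name}: no samples with "
                                 f"{factor}={level}")
        return ref_mask, alt_mask

    def swapped(self) -> "Contrast":
        factor, ref, alt = self.tested
        return Contrast(self.name + "_swapped", self.fixed, (factor, alt, ref))


@dataclass(frozen=True)
class DEThresholds:
    """Significance and effect-size cutoffs for calling DEGs.

    All comparisons are strict: FDR < ``fdr_max`` and |log2FC| strictly
    above the chosen cutoff.
    """

    fdr_max: float = 0.05
    lfc_min_loose: float = 0.1
    lfc_min_strict: float = 0.26

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max < 1:
            raise ValueError("fdr_max must be in (0, 1)")
        if not 0 <= self.lfc_min_loose <= self.lfc_min_strict:
            raise ValueError("need 0 <= lfc_min_loose <= lfc_min_strict")


@dataclass
class DEResult:
    """Per-feature Wald-test results for one named contrast.

    ``table`` columns: base_mean (normalized mean over the contrast's
    samples), log2fc, se_log2fc, wald_p, fdr, tested. Untested features
    (all-zero within the contrast) carry NaN statistics and tested=False.
    """

    contrast: str
    table: pd.DataFrame

    def tested_features(self) -> set[str]:
        return set(self.table.index[self.table["tested"]])


def size_factors(counts: CountMatrix) -> np.ndarray:
    """Median-of-ratios per-sample size factors, geometric mean 1.

    Each sample's factor is the median, over features expressed in every
    sample, of that sample's count divided by the feature's geometric mean
    across samples. If no feature is expressed in all samples the estimator
    falls back to total-count scaling with a warning.
    """
    x = counts.values.astype(float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        logger.warning("no feature expressed in every sample; "
                       "falling back to total-count size factors")
        totals = x.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        sf = totals
    else:
        logx = np.log(x[all_pos])
        log_gm = logx.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logx - log_gm, axis=0))
    sf = sf / np.exp(np.mean(np.log(sf)))
    return sf


def tpm_normalize(counts: CountMatrix) -> pd.DataFrame:
    """Library-size normalization: every sample column scaled to 1e6.

    Gene-level counts carry no transcript-length table here, so this is
    counts-per-million; the classic length division is omitted.
    """
    x = counts.values.astype(float)
    totals = x.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"zero library size for samples: {[counts.sample_ids[j] for j in zero]}"
        )
    return pd.DataFrame(x / totals * 1e6, index=counts.feature_ids,
                        columns=counts.sample_ids)


def _groups(design: pd.DataFrame) -> list[np.ndarray]:
    masks = []
    for (gt, age), sub in design.groupby(["genotype", "age"], sort=True):
        m = ((design["genotype"] == gt) & (design["age"] == age)).to_numpy()
        if m.sum() >= 2:
            masks.append(m)
    return masks


def nb_dispersion(
    counts: CountMatrix,
    shrink_weight: float = 0.5,
) -> np.ndarray:
    """Per-feature NB dispersion alpha, method of moments with trend shrinkage.

    For each design cell with >= 2 samples the gene-wise estimate is
    ``(s^2 - m) / m^2`` on size-factor-normalized counts; cells are pooled
    with degrees-of-freedom weights and clamped at zero. The gene-wise
    values are then shrunk toward a fitted mean-dispersion trend
    ``alpha(mu) = a1 + a0/mu`` (weighted average with ``shrink_weight`` on
    the trend). Deterministic; degenerate features get alpha = 0.
    """
    if not 0 <= shrink_weight <= 1:
        raise ValueError("shrink_weight must be in [0, 1]")
    sf = size_factors(counts)
    norm = counts.values / sf
    masks = _groups(counts.design)
    if not masks:
        raise ValueError("need at least one design cell with >= 2 samples")
    num = np.zeros(counts.n_features)
    den = np.zeros(counts.n_features)
    base = np.zeros(counts.n_features)
    wsum = 0.0
    for m in masks:
        sub = norm[:, m]
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        w = m.sum() - 1
        ok = mean > 0
        num[ok] += w * (var[ok] - mean[ok]) / mean[ok] ** 2
        den[ok] += w
        base += w * mean
        wsum += w
    genewise = np.zeros(counts.n_features)
    tested = den > 0
    genewise[tested] = np.maximum(0.0, num[tested] / den[tested])
    base_mean = base / wsum

    if shrink_weight == 0:
        return genewise
    # parametric trend alpha(mu) = a1 + a0/mu fit on informative genes
    fit_mask = tested & (genewise > 0) & (base_mean > 0)
    if fit_mask.sum() >= 10:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / base_mean[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, genewise[fit_mask], rcond=None)
        a1, a0 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        a1, a0 = (float(np.median(genewise[tested])) if tested.any() else 0.0), 0.0
    trend = np.zeros(counts.n_features)
    pos = base_mean > 0
    trend[pos] = a1 + a0 / base_mean[pos]
    out = np.where(tested, (1 - shrink_weight) * genewise + shrink_weight * trend, 0.0)
    return np.maximum(out, 0.0)


def nb_wald(
    counts: CountMatrix,
    contrast: Contrast,
    dispersion: np.ndarray | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> DEResult:
    """Wald test of the NB group-mean log ratio for one contrast.

    Group means are computed on size-factor-normalized counts;
    ``log2fc = log2((mu_alt + c) / (mu_ref + c))`` with pseudocount ``c``.
    The standard error comes from the delta method under
    ``Var(count) = mu*s + alpha*(mu*s)^2`` for a sample with size factor
    ``s``; the two-sided p is normal. BH correction runs across tested
    features only.
    """
    ref_mask, alt_mask = contrast.masks(counts.design)
    if ref_mask.sum() < 2 or alt_mask.sum() < 2:
        raise ValueError(f"contrast {contrast.name}: both levels need >= 2 samples")
    sf = size_factors(counts)
    norm = counts.values / sf
    if dispersion is None:
        dispersion = nb_dispersion(counts)
    alpha = np.asarray(dispersion, dtype=float)

    in_contrast = ref_mask | alt_mask
    tested = counts.values[:, in_contrast].sum(axis=1) > 0

    mu_ref = norm[:, ref_mask].mean(axis=1)
    mu_alt = norm[:, alt_mask].mean(axis=1)
    base_mean = norm[:, in_contrast].mean(axis=1)

    # Var(mean of normalized counts) = (1/n^2) sum_i (mu/s_i + alpha*mu^2)
    inv_s_ref = (1.0 / sf[ref_mask]).sum()
    inv_s_alt = (1.0 / sf[alt_mask]).sum()
    n_ref, n_alt = ref_mask.sum(), alt_mask.sum()
    var_ref = (mu_ref * inv_s_ref + alpha * mu_ref**2 * n_ref) / n_ref**2
    var_alt = (mu_alt * inv_s_alt + alpha * mu_alt**2 * n_alt) / n_alt**2

    c = pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        # difference of logs, not log of ratio: swapping levels then negates
        # the estimate exactly, not merely to rounding
        log2fc = np.log2(mu_alt + c) - np.log2(mu_ref + c)
        var_ln = var_alt / (mu_alt + c) ** 2 + var_ref / (mu_ref + c) ** 2
        se_log2fc = np.sqrt(var_ln) / np.log(2)
        z = np.where(se_log2fc > 0, log2fc / se_log2fc, np.where(log2fc == 0, 0.0, np.inf))
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se_log2fc": se_log2fc,
            "wald_p": wald_p,
            "fdr": np.nan,
            "tested": tested,
        },
        index=pd.Index(counts.feature_ids, name="feature_id"),
    )
    table.loc[~tested, ["base_mean", "log2fc", "se_log2fc", "wald_p"]] = np.nan
    if tested.any():
        table.loc[tested, "fdr"] = bh_adjust(table.loc[tested, "wald_p"].to_numpy())
    return DEResult(contrast=contrast.name, table=table)


def classify_deg(
    res: DEResult,
    thresholds: DEThresholds = DEThresholds(),
    which_lfc: str = "loose",
) -> tuple[set[str], set[str]]:
    """(up, down) gene sets at FDR < fdr_max and |log2FC| strictly above cutoff."""
    if which_lfc not in ("loose", "strict"):
        raise ValueError("which_lfc must be 'loose' or 'strict'")
    lfc_min = (thresholds.lfc_min_loose if which_lfc == "loose"
               else thresholds.lfc_min_strict)
    t = res.table[res.table["tested"]]
    sig = t["fdr"] < thresholds.fdr_max
    up = set(t.index[sig & (t["log2fc"] > lfc_min)])
    down = set(t.index[sig & (t["log2fc"] < -lfc_min)])
    return up, down


def standard_contrasts() -> list[Contrast]:
    """The four study contrasts: genotype at each age, age within each genotype."""
    return [
        Contrast("TG_vs_WT@3", ("age", 3), ("genotype", "WT", "TG")),
        Contrast("TG_vs_WT@6", ("age", 6), ("genotype", "WT", "TG")),
        Contrast("6_vs_3@WT", ("genotype", "WT"), ("age", 3, 6)),
        Contrast("6_vs_3@TG", ("genotype", "TG"), ("age", 3, 6)),
    ]
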
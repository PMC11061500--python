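"""Summary statistics shared by the observed dataset and the reference table.

The fixed-order vector comprises, for a given group list: per group the
proportion of polymorphic loci and the mean and variance across loci of
unbiased expected heterozygosity; per group pair the Hudson FST
(ratio-of-averages across loci) and Nei's standard genetic distance; and,
when the canonical five demes are present, the admixture-sensitive
statistics f3(HYB_g; PAM_g, HIM) for each geographic group g and
f4(PAM_N, PAM_S; HYB_pooled, HIM).  Loci with no data in a group are
dropped pairwise, per statistic.

Identical statistic names and ordering between observed and simulated
vectors are required by the downstream random-forest steps; the registry
version string is recorded in reference-table provenance.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .genotypes import MISSING, SnpDataset

__all__ = [
    "STAT_REGISTRY_VERSION",
    "allele_freq",
    "expected_heterozygosity",
    "proportion_polymorphic",
    "hudson_fst",
    "hudson_fst_per_locus",
    "nei_distance",
    "f3",
    "f4",
    "compute_summaries",
    "summary_names",
]

STAT_REGISTRY_VERSION = "v1"

#: canonical deme order used when the study's five groups are present
CANONICAL_GROUPS = ("PAM_N", "PAM_S", "HYB_N", "HYB_S", "HIM")

#: Nei distance cap substituted for -ln(0) when groups share no alleles
NEI_CAP = 10.0


def _freq_and_copies(ds: SnpDataset, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = ds.dosages[rows]
    called = d != MISSING
    n_copies = 2.0 * called.sum(axis=0)
    alt = np.where(called, d, 0).sum(axis=0, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_copies > 0, alt / n_copies, np.nan)
    return p, n_copies


def _rows(ds: SnpDataset, group) -> np.ndarray:
    """Row indices for a group label or an explicit list of labels (pooled)."""
    labels = ds.individuals["group_label"].to_numpy()
    if isinstance(group, (list, tuple, set, frozenset)):
        mask = np.isin(labels, list(group))
    else:
        mask = labels == group
    rows = np.flatnonzero(mask)
    if rows.size == 0:
        raise ValueError(f"group {group!r} has no individuals")
    return rows


def allele_freq(ds: SnpDataset, group) -> np.ndarray:
    """Per-locus alternate-allele frequency within a group (NaN if no calls)."""
    p, _ = _freq_and_copies(ds, _rows(ds, group))
    return p


def _het_per_locus(p: np.ndarray, n_copies: np.ndarray) -> np.ndarray:
    """Unbiased expected heterozygosity 2p(1-p) n/(n-1) per locus."""
    with np.errstate(invalid="ignore", divide="ignore"):
        h = 2.0 * p * (1.0 - p) * n_copies / (n_copies - 1.0)
    return np.where(n_copies >= 2, h, np.nan)


def expected_heterozygosity(ds: SnpDataset, group) -> tuple[float, float]:
    """Mean and variance (across loci) of unbiased expected heterozygosity."""
    p, n = _freq_and_copies(ds, _rows(ds, group))
    h = _het_per_locus(p, n)
    h = h[~np.isnan(h)]
    if h.size == 0:
        return np.nan, np.nan
    return float(h.mean()), float(h.var())


def proportion_polymorphic(ds: SnpDataset, group) -> float:
    """Fraction of loci segregating within the group (among loci with data)."""
    p = allele_freq(ds, group)
    valid = ~np.isnan(p)
    if not valid.any():
        return np.nan
    with np.errstate(invalid="ignore"):
        poly = (p > 0) & (p < 1)
    return float(poly[valid].mean())


def _fst_components(ds: SnpDataset, group_a, group_b):
    pa, na = _freq_and_copies(ds, _rows(ds, group_a))
    pb, nb = _freq_and_copies(ds, _rows(ds, group_b))
    hw = 0.5 * (_het_per_locus(pa, na) + _het_per_locus(pb, nb))
    hb = pa * (1.0 - pb) + pb * (1.0 - pa)
    valid = ~(np.isnan(hw) | np.isnan(hb))
    return hw[valid], hb[valid]


def hudson_fst(ds: SnpDataset, group_a, group_b) -> float:
    """Hudson-style FST, ratio of averages: 1 - mean(Hw) / mean(Hb).

    Hw averages the two sample-size-corrected within-group heterozygosities;
    Hb is the between-group heterozygosity pA(1-pB) + pB(1-pA).  The raw
    value is returned (it may be slightly negative under panmixia).
    """
    hw, hb = _fst_components(ds, group_a, group_b)
    mb = hb.mean() if hb.size else np.nan
    if not mb or np.isnan(mb):
        return np.nan
    return float(1.0 - hw.mean() / mb)


def hudson_fst_per_locus(ds: SnpDataset, group_a, group_b) -> np.ndarray:
    """Single-locus Hudson FST values 1 - Hw/Hb (loci with Hb > 0)."""
    hw, hb = _fst_components(ds, group_a, group_b)
    ok = hb > 0
    return 1.0 - hw[ok] / hb[ok]


def nei_distance(ds: SnpDataset, group_a, group_b, cap: float = NEI_CAP) -> float:
    """Nei's standard genetic distance over biallelic frequencies.

    D = -ln( sum_l sum_alleles pA pB / sqrt(sum_l sum pA^2 * sum_l sum pB^2) ).
    A zero genetic identity (fixed opposite alleles everywhere) would give
    +inf and is guarded to ``cap``.
    """
    pa = allele_freq(ds, group_a)
    pb = allele_freq(ds, group_b)
    valid = ~(np.isnan(pa) | np.isnan(pb))
    pa, pb = pa[valid], pb[valid]
    if pa.size == 0:
        return np.nan
    jxy = (pa * pb + (1 - pa) * (1 - pb)).sum()
    jx = (pa**2 + (1 - pa) ** 2).sum()
    jy = (pb**2 + (1 - pb) ** 2).sum()
    identity = jxy / np.sqrt(jx * jy)
    if identity <= np.exp(-cap):
        return float(cap)
    return float(-np.log(identity))


def f3(ds: SnpDataset, target, source_a, source_b, corrected: bool = True) -> float:
    """f3(target; A, B) with the small-sample correction for the target.

    Mean over loci of (pT - pA)(pT - pB) - hT / nT, where hT is the target's
    unbiased heterozygosity estimate pT(1-pT) nT/(nT-1) and nT its number of
    called gene copies.  Significantly negative values indicate that the
    target is admixed between proxies of A and B.  ``corrected=False`` drops
    the sampling-noise term (the raw product is then identically zero when
    the target equals one source).
    """
    pt, nt = _freq_and_copies(ds, _rows(ds, target))
    pa = allele_freq(ds, source_a)
    pb = allele_freq(ds, source_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = pt * (1.0 - pt) / (nt - 1.0) if corrected else 0.0
        vals = (pt - pa) * (pt - pb) - corr
    vals = vals[~np.isnan(vals) & (nt >= 2)]
    return float(vals.mean()) if vals.size else np.nan


def f4(ds: SnpDataset, a, b, c, d) -> float:
    """f4(A, B; C, D) = mean over loci of (pA - pB)(pC - pD)."""
    pa, pb = allele_freq(ds, a), allele_freq(ds, b)
    pc, pd_ = allele_freq(ds, c), allele_freq(ds, d)
    vals = (pa - pb) * (pc - pd_)
    vals = vals[~np.isnan(vals)]
    return float(vals.mean()) if vals.size else np.nan


def _resolve_groups(ds: SnpDataset, groups) -> list[str]:
    if groups is not None:
        return list(groups)
    present = list(pd.unique(ds.individuals["group_label"]))
    if set(CANONICAL_GROUPS) <= set(present):
        extra = [g for g in present if g not in CANONICAL_GROUPS]
        return list(CANONICAL_GROUPS) + extra
    return present


def summary_names(groups) -> list[str]:
    """Statistic names, in vector order, for a group list."""
    groups = list(groups)
    names = []
    for g in groups:
        names += [f"prop_poly_{g}", f"he_mean_{g}", f"he_var_{g}"]
    for a, b in itertools.combinations(groups, 2):
        names += [f"fst_{a}_{b}", f"neiD_{a}_{b}"]
    if set(CANONICAL_GROUPS) <= set(groups):
        names += ["f3_HYB_N", "f3_HYB_S", "f4_PAM_HYB_HIM"]
    return names


def _stats_from_freqs(p, n):
    """(prop polymorphic, He mean, He variance) from cached (p, n) arrays."""
    h = _het_per_locus(p, n)
    h = h[~np.isnan(h)]
    valid = ~np.isnan(p)
    with np.errstate(invalid="ignore"):
        poly = (p > 0) & (p < 1)
    prop = float(poly[valid].mean()) if valid.any() else np.nan
    if h.size == 0:
        return prop, np.nan, np.nan
    return prop, float(h.mean()), float(h.var())


def _fst_from_freqs(pa, na, pb, nb) -> float:
    hw = 0.5 * (_het_per_locus(pa, na) + _het_per_locus(pb, nb))
    hb = pa * (1.0 - pb) + pb * (1.0 - pa)
    valid = ~(np.isnan(hw) | np.isnan(hb))
    mb = hb[valid].mean() if valid.any() else np.nan
    if not mb or np.isnan(mb):
        return np.nan
    return float(1.0 - hw[valid].mean() / mb)


def _nei_from_freqs(pa, pb, cap: float = NEI_CAP) -> float:
    valid = ~(np.isnan(pa) | np.isnan(pb))
    pa, pb = pa[valid], pb[valid]
    if pa.size == 0:
        return np.nan
    jxy = (pa * pb + (1 - pa) * (1 - pb)).sum()
    jx = (pa**2 + (1 - pa) ** 2).sum()
    jy = (pb**2 + (1 - pb) ** 2).sum()
    identity = jxy / np.sqrt(jx * jy)
    if identity <= np.exp(-cap):
        return float(cap)
    return float(-np.log(identity))


def _f3_from_freqs(pt, nt, pa, pb) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = pt * (1.0 - pt) / (nt - 1.0)
        vals = (pt - pa) * (pt - pb) - corr
    vals = vals[~np.isnan(vals) & (nt >= 2)]
    return float(vals.mean()) if vals.size else np.nan


def compute_summaries(ds: SnpDataset, groups=None) -> pd.Series:
    """Compute the fixed-order summary vector for a dataset.

    ``groups`` defaults to the labels present in the dataset (canonical deme
    order when the five study demes are all present).  The admixture block
    (f3 per geographic group, f4 with pooled hybrids) is included exactly
    when the five canonical demes are in the group list.  Pure function:
    the dataset is not modified and reruns are bit-identical.  Per-group
    allele frequencies are computed once and shared by every statistic.
    """
    groups = _resolve_groups(ds, groups)
    freqs = {g: _freq_and_copies(ds, _rows(ds, g)) for g in groups}
    values: dict[str, float] = {}
    for g in groups:
        p, n = freqs[g]
        prop, hm, hv = _stats_from_freqs(p, n)
        values[f"prop_poly_{g}"] = prop
        values[f"he_mean_{g}"] = hm
        values[f"he_var_{g}"] = hv
    for a, b in itertools.combinations(groups, 2):
        (pa, na), (pb, nb) = freqs[a], freqs[b]
        values[f"fst_{a}_{b}"] = _fst_from_freqs(pa, na, pb, nb)
        values[f"neiD_{a}_{b}"] = _nei_from_freqs(pa, pb)
    if set(CANONICAL_GROUPS) <= set(groups):
        values["f3_HYB_N"] = _f3_from_freqs(*freqs["HYB_N"], freqs["PAM_N"][0], freqs["HIM"][0])
        values["f3_HYB_S"] = _f3_from_freqs(*freqs["HYB_S"], freqs["PAM_S"][0], freqs["HIM"][0])
        p_hyb, _ = _freq_and_copies(ds, _rows(ds, ["HYB_N", "HYB_S"]))
        vals = (freqs["PAM_N"][0] - freqs["PAM_S"][0]) * (p_hyb - freqs["HIM"][0])
        vals = vals[~np.isnan(vals)]
        values["f4_PAM_HYB_HIM"] = float(vals.mean()) if vals.size else np.nan
    return pd.Series(values, index=summary_names(groups), dtype=float)
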
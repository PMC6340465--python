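"""Windowed male-female contrasts that localize the SDR.

Statistics per window: Hudson-estimator F_ST between male and female
haplotypes, the percentage of sex-limited SNPs (minor-allele frequency
above a threshold in one sex, strictly absent in the other), nucleotide
diversity per sex, their log2 ratio, and optionally the normalized
male:female read-depth log2 ratio. On an XY system, the SDR stands out
through elevated male-female F_ST, an excess of sex-limited (Y-limited)
SNPs and male-biased heterozygosity, while autosomes and the PAR stay
flat.

The Hudson ratio-of-sums estimator is used for F_ST: per site
``num = (pA - pB)^2 - pA(1-pA)/(nA-1) - pB(1-pB)/(nB-1)`` and
``den = pA(1-pB) + pB(1-pA)``, with the window value Sum(num)/Sum(den).
Negative values are reported as-is so simulation nulls stay unbiased.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import HaplotypeMatrix, MetadataTable, Sex, Window

DEFAULT_MAX_MISSING = 0.2


@dataclass
class SexDiffRow:
    window: Window
    n_snps: int
    fst_mf: float
    sex_limited_pct: float
    pi_m: float
    pi_f: float
    log2_pi_ratio: float
    log2_cov_ratio: float = math.nan


def _freqs(alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site alternate-allele frequency and genotyped count."""
    ok = alleles >= 0
    n = ok.sum(axis=1)
    with np.errstate(invalid="ignore"):
        p = np.where(ok, alleles, 0).sum(axis=1) / np.where(n > 0, n, 1)
    return p, n


def window_fst(hap: HaplotypeMatrix, group_a: Sequence[str],
               group_b: Sequence[str], window: Window,
               min_haps: int = 4) -> float:
    """Hudson ratio-of-sums F_ST between two haplotype groups.

    Sites contribute only with >= min_haps genotyped haplotypes per group.
    Returns NaN when no site contributes or the denominator sum is 0.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    sub = hap.alleles[hap.site_slice(window)]
    pa, na = _freqs(sub[:, hap.hap_indices(group_a)])
    pb, nb = _freqs(sub[:, hap.hap_indices(group_b)])
    use = (na >= min_haps) & (nb >= min_haps)
    if not use.any():
        return math.nan
    pa, na, pb, nb = pa[use], na[use], pb[use], nb[use]
    num = ((pa - pb) ** 2
           - pa * (1 - pa) / (na - 1)
           - pb * (1 - pb) / (nb - 1))
    den = pa * (1 - pb) + pb * (1 - pa)
    s_den = den.sum()
    if s_den == 0:
        return math.nan
    return float(num.sum() / s_den)


def sex_limited_fraction(hap: HaplotypeMatrix, males: Sequence[str],
                         females: Sequence[str], window: Window,
                         maf_threshold: float = 0.1,
                         min_genotyped_frac: float = 0.8) -> float:
    """Percent of SNPs with MAF > threshold in one sex and frequency
    exactly 0 in the other (the Y-limited-allele signature).

    A site contributes only when fully genotyped in at least
    ``min_genotyped_frac`` of each sex's haplotypes.
    """
    if not (0 <= maf_threshold < 0.5):
        raise ValueError("maf_threshold must be in [0, 0.5)")
    sub = hap.alleles[hap.site_slice(window)]
    pm, nm = _freqs(sub[:, hap.hap_indices(males)])
    pf, nf = _freqs(sub[:, hap.hap_indices(females)])
    use = (nm >= min_genotyped_frac * len(males)) & \
          (nf >= min_genotyped_frac * len(females)) & (nm > 0) & (nf > 0)
    if not use.any():
        return math.nan
    pm, pf = pm[use], pf[use]

    def limited(p_this: np.ndarray, p_other: np.ndarray) -> np.ndarray:
        # an allele qualifies when it is a minor allele of this sex
        # (freq <= 0.5, ties allowed), exceeds the MAF threshold here,
        # and is strictly absent in the other sex
        alt = (p_this <= 0.5) & (p_this > maf_threshold) & (p_other == 0)
        ref = ((1 - p_this) <= 0.5) & ((1 - p_this) > maf_threshold) \
            & (p_other == 1)
        return alt | ref

    qualifies = limited(pm, pf) | limited(pf, pm)
    return float(100.0 * qualifies.sum() / use.sum())


def window_pi(hap: HaplotypeMatrix, group: Sequence[str], window: Window,
              denominator_mode: str = "window_bp") -> float:
    """Nucleotide diversity: Sum over sites of (n/(n-1)) 2p(1-p), divided
    by window length (mode ``window_bp``) or by the number of contributing
    SNPs (mode ``snp_only``)."""
    if denominator_mode not in ("window_bp", "snp_only"):
        raise ValueError(f"unknown denominator mode {denominator_mode!r}")
    sub = hap.alleles[hap.site_slice(window)]
    p, n = _freqs(sub[:, hap.hap_indices(group)])
    use = n >= 2
    if not use.any():
        return math.nan if denominator_mode == "snp_only" else 0.0
    p, n = p[use], n[use]
    total = float((n / (n - 1) * 2 * p * (1 - p)).sum())
    denom = window.length if denominator_mode == "window_bp" else int(use.sum())
    return total / denom


def log2_ratio(x_m: float, x_f: float) -> float:
    """log2(male/female); NaN when either side is 0 or missing."""
    if x_m < 0 or x_f < 0:
        raise ValueError("inputs must be non-negative")
    if x_m == 0 or x_f == 0 or math.isnan(x_m) or math.isnan(x_f):
        return math.nan
    return math.log2(x_m / x_f)


def coverage_log2_ratio(depth_table: pd.DataFrame, metadata: MetadataTable,
                        window: Window) -> float:
    """log2 of male over female mean depth in a window, each sample first
    normalized by its own genome-wide mean depth."""
    means = depth_table.groupby("sample_id")["depth"].mean()
    if (means == 0).any():
        bad = means.index[means == 0].tolist()
        raise ValueError(f"samples with zero genome-wide mean depth: {bad}")
    rows = depth_table[(depth_table["chrom"] == window.chromosome)
                       & (depth_table["start"] == window.start)
                       & (depth_table["end"] == window.end)]
    norm = rows["depth"].to_numpy() / means.loc[rows["sample_id"]].to_numpy()
    sex = np.array([metadata[s].sex.value for s in rows["sample_id"]])
    m = norm[sex == Sex.male.value]
    f = norm[sex == Sex.female.value]
    if len(m) == 0 or len(f) == 0:
        return math.nan
    return log2_ratio(float(m.mean()), float(f.mean()))


def scan_sexdiff(hap: HaplotypeMatrix, metadata: MetadataTable,
                 windows: Sequence[Window], species: str,
                 min_snps: int = 5,
                 depth_table: pd.DataFrame | None = None,
                 max_missing: float = DEFAULT_MAX_MISSING,
                 pi_mode: str = "window_bp") -> pd.DataFrame:
    """One SexDiffRow per window for one focal species' males vs females."""
    hap = hap.filter_missingness(max_missing)
    males = [f"{s}_{ab}" for s in metadata.select(species=species, sex=Sex.male)
             for ab in "AB"]
    females = [f"{s}_{ab}" for s in metadata.select(species=species, sex=Sex.female)
               for ab in "AB"]
    if not males or not females:
        raise ValueError(f"species {species!r} needs both sexes")
    rows = []
    for w in windows:
        if w.chromosome != hap.chromosome:
            continue
        sub = hap.alleles[hap.site_slice(w)]
        seg = ((sub == 1).any(axis=1) & (sub == 0).any(axis=1)).sum()
        if seg < min_snps:
            row = SexDiffRow(w, int(seg), math.nan, math.nan, math.nan,
                             math.nan, math.nan)
        else:
            pi_m = window_pi(hap, males, w, pi_mode)
            pi_f = window_pi(hap, females, w, pi_mode)
            row = SexDiffRow(
                w, int(seg),
                window_fst(hap, males, females, w),
                sex_limited_fraction(hap, males, females, w),
                pi_m, pi_f, log2_ratio(pi_m, pi_f))
        if depth_table is not None:
            row.log2_cov_ratio = coverage_log2_ratio(depth_table, metadata, w)
        rows.append(row)
    return pd.DataFrame({
        "chrom": [r.window.chromosome for r in rows],
        "start": [r.window.start for r in rows],
        "end": [r.window.end for r in rows],
        "label": [r.window.label.value for r in rows],
        "n_snps": [r.n_snps for r in rows],
        "fst_mf": [r.fst_mf for r in rows],
        "sex_limited_pct": [r.sex_limited_pct for r in rows],
        "pi_m": [r.pi_m for r in rows],
        "pi_f": [r.pi_f for r in rows],
        "log2_pi_ratio": [r.log2_pi_ratio for r in rows],
        "log2_cov_ratio": [r.log2_cov_ratio for r in rows],
    })
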
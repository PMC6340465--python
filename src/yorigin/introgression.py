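"""Polarized site-pattern statistics: D and the windowed admixture
estimator f_d.

For populations (P1, P2, P3, O) with derived-allele frequencies
(p1, p2, p3, p4), each site contributes

    ABBA = (1 - p1) p2 p3 (1 - p4)
    BABA = p1 (1 - p2) p3 (1 - p4)

and a window's D = Sum(ABBA - BABA) / Sum(ABBA + BABA). The f_d
estimator replaces the donor frequency with the site-wise larger of
(p2, p3) in the denominator:

    f_d = Sum(ABBA - BABA) / Sum(ABBA_d - BABA_d),

where ABBA_d / BABA_d substitute p_d = max(p2, p3) for both p2 and p3.
f_d is reported only for windows with D >= 0 (its domain: an excess of
shared derived alleles between P2 and P3); negative-D windows carry a
reason code instead.

Two standard configurations: a species test (P1 = sister species,
P2 = donor candidate, P3 = focal species) and a sexed test
(P1 = focal females, P2 = focal males, P3 = donor candidate) that
isolates male-limited, i.e. Y-linked, sharing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (HaplotypeMatrix, MetadataTable, Sex, Species,
                        Window, resolve_group)

REASON_OK = "ok"
REASON_TOO_FEW_SITES = "too_few_sites"
REASON_ZERO_DENOM = "zero_denominator"
REASON_NEGATIVE_D = "negative_D"

CONFIGURATIONS = ("species", "sexed")


@dataclass(frozen=True)
class SitePattern:
    p1: float
    p2: float
    p3: float
    p4: float

    @property
    def abba(self) -> float:
        return (1 - self.p1) * self.p2 * self.p3 * (1 - self.p4)

    @property
    def baba(self) -> float:
        return self.p1 * (1 - self.p2) * self.p3 * (1 - self.p4)

    @property
    def p_d(self) -> float:
        return max(self.p2, self.p3)

    @property
    def abba_d(self) -> float:
        return (1 - self.p1) * self.p_d * self.p_d * (1 - self.p4)

    @property
    def baba_d(self) -> float:
        return self.p1 * (1 - self.p_d) * self.p_d * (1 - self.p4)


@dataclass
class FdRow:
    window: Window
    n_sites: int
    d: float
    fd: float
    configuration: str
    reason: str = REASON_OK


def _group_freqs(derived: np.ndarray, idx: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    sub = derived[:, idx]
    ok = sub >= 0
    n = ok.sum(axis=1)
    p = np.where(ok, sub, 0).sum(axis=1) / np.where(n > 0, n, 1)
    return p, n


def _usable_freqs(hap: HaplotypeMatrix, groups: Sequence[Sequence[str]],
                  rows: slice, min_group: int = 2):
    """Derived-allele frequencies (p1..p4) at usable sites of a window.

    Polarization is strictly by the outgroup group O: its observed allele
    is the ancestral state, so sites where the raw coding disagrees with
    the outgroup are re-polarized rather than dropped. Sites with a
    polymorphic or missing outgroup are skipped, as are sites with fewer
    than ``min_group`` genotyped haplotypes in P1-P3.
    """
    if len(groups) != 4:
        raise ValueError("need exactly 4 groups (P1, P2, P3, O)")
    seen: set[str] = set()
    for g in groups:
        if seen & set(g):
            raise ValueError(f"overlapping groups: {sorted(seen & set(g))}")
        seen |= set(g)
    idx = [hap.hap_indices(list(g)) for g in groups]
    A = hap.alleles[rows]
    out = A[:, idx[3]]
    out_ok = out >= 0
    n_out = out_ok.sum(axis=1)
    out_sum = np.where(out_ok, out, 0).sum(axis=1)
    mono0 = out_sum == 0
    mono1 = out_sum == n_out
    usable = (n_out > 0) & (mono0 | mono1)
    anc = np.where(mono1, 1, 0).astype(np.int8)  # outgroup allele = ancestral

    ps, ns = [], []
    for k in range(3):
        p, n = _group_freqs(A, idx[k])
        usable &= n >= min_group
        ps.append(p)
        ns.append(n)
    # re-polarize: derived = allele different from the outgroup state
    ps = [np.where(anc == 1, 1 - p, p) for p in ps]
    p4 = np.zeros(A.shape[0])  # by construction after polarization
    return [p[usable] for p in ps] + [p4[usable]], usable


def site_pattern(hap: HaplotypeMatrix, groups: Sequence[Sequence[str]],
                 site: int) -> SitePattern | None:
    """SitePattern at one site index, or None when the site is unusable."""
    (p1, p2, p3, p4), usable = _usable_freqs(hap, groups,
                                             slice(site, site + 1))
    if not usable.any():
        return None
    return SitePattern(float(p1[0]), float(p2[0]), float(p3[0]), float(p4[0]))


def window_d_fd(hap: HaplotypeMatrix, groups: Sequence[Sequence[str]],
                window: Window, min_sites: int = 20,
                configuration: str = "custom") -> FdRow:
    """D and f_d for one window by ratio-of-sums over usable sites."""
    (p1, p2, p3, p4), _ = _usable_freqs(hap, groups, hap.site_slice(window))
    seg = (p1 > 0) | (p2 > 0) | (p3 > 0)
    p1, p2, p3, p4 = p1[seg], p2[seg], p3[seg], p4[seg]
    n_sites = int(len(p1))
    if n_sites < min_sites:
        return FdRow(window, n_sites, math.nan, math.nan, configuration,
                     REASON_TOO_FEW_SITES)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    pd_ = np.maximum(p2, p3)
    abba_d = (1 - p1) * pd_ * pd_ * (1 - p4)
    baba_d = p1 * (1 - pd_) * pd_ * (1 - p4)
    num = float((abba - baba).sum())
    den_d = float((abba + baba).sum())
    den_fd = float((abba_d - baba_d).sum())
    # D needs informative (ABBA or BABA) sites; f_d's denominator exists
    # whenever the donor carries derived alleles, and stays defined (= 0,
    # no excess) on windows with no sharing at all. f_d is withheld only
    # for a demonstrated deficit (D < 0), outside its domain.
    d = num / den_d if den_d != 0 else math.nan
    if not math.isnan(d) and d < 0:
        return FdRow(window, n_sites, d, math.nan, configuration,
                     REASON_NEGATIVE_D)
    if den_fd == 0:
        return FdRow(window, n_sites, d, math.nan, configuration,
                     REASON_ZERO_DENOM)
    return FdRow(window, n_sites, d, num / den_fd, configuration, REASON_OK)


def configuration_groups(metadata: MetadataTable, configuration: str,
                         hap_ids: Sequence[str],
                         focal: str = "pungitius",
                         donor: str = "sinensis",
                         sister: str = "tymensis") -> list[list[str]]:
    """Resolve the two standard (P1, P2, P3, O) layouts."""
    if configuration == "species":
        specs = [sister, donor, focal, "outgroup"]
    elif configuration == "sexed":
        specs = [f"{focal}&female", f"{focal}&male", donor, "outgroup"]
    else:
        raise ValueError(f"unknown configuration {configuration!r}; "
                         f"choose from {CONFIGURATIONS}")
    return [resolve_group(metadata, s, hap_ids) for s in specs]


def genome_scan_fd(hap: HaplotypeMatrix, metadata: MetadataTable,
                   configuration: str, windows: Sequence[Window],
                   min_sites: int = 20) -> pd.DataFrame:
    """One FdRow per window under a named configuration."""
    groups = configuration_groups(metadata, configuration, hap.hap_ids)
    rows = []
    for w in windows:
        if w.chromosome != hap.chromosome:
            continue
        r = window_d_fd(hap, groups, w, min_sites=min_sites,
                        configuration=configuration)
        rows.append(r)
    return pd.DataFrame({
        "chrom": [r.window.chromosome for r in rows],
        "start": [r.window.start for r in rows],
        "end": [r.window.end for r in rows],
        "label": [r.window.label.value for r in rows],
        "n_sites": [r.n_sites for r in rows],
        "D": [r.d for r in rows],
        "fd": [r.fd for r in rows],
        "config": [r.configuration for r in rows],
        "reason": [r.reason for r in rows],
    })


def summarize_fd(table: pd.DataFrame) -> dict[str, float]:
    """Mean f_d by window label (NaN-aware)."""
    out: dict[str, float] = {}
    for label, sub in table.groupby("label"):
        out[f"fd_mean_{label}"] = float(np.nanmean(sub["fd"].to_numpy())) \
            if sub["fd"].notna().any() else math.nan
        out[f"d_mean_{label}"] = float(np.nanmean(sub["D"].to_numpy())) \
            if sub["D"].notna().any() else math.nan
    return out
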
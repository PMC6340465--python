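"""Divergence statistics: windowed d_xy, the ILS-vs-introgression
contrast, Nei-Gojobori (1986) pairwise dN/dS, and private-substitution
partitioning.

The ILS discriminator: if the male-limited (Y) haplotype group and the
candidate donor species shared an ancestor *before* the deepest species
split (incomplete lineage sorting), their divergence should exceed the
genomic average; if the Y arrived by introgression *after* the species
split, it should fall below it. A one-sided rank test on window d_xy
values decides between the two.

NG86 counts synonymous/nonsynonymous sites per codon (averaged over the
two sequences), resolves multi-hit codons by averaging over all minimal
mutational pathways with equal weight (pathways through stop codons are
excluded), and applies the Jukes-Cantor correction to the proportions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import HaplotypeMatrix, Window

ILS_CONSISTENT = "ils_consistent"
INTROGRESSION_CONSISTENT = "introgression_consistent"

_BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _c in itertools.product(_BASES, repeat=3):
    _CODON_TABLE["".join(_c)] = ""
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, _c in enumerate(itertools.product(_BASES, repeat=3)):
    _CODON_TABLE["".join(_c)] = _AA[_i]

STOP = "*"


# ---------------------------------------------------------------------------
# windowed d_xy and the ILS test
# ---------------------------------------------------------------------------

def window_dxy(hap: HaplotypeMatrix, group_a: Sequence[str],
               group_b: Sequence[str], window: Window) -> float:
    """Mean between-group pairwise difference per bp of the window:
    Sum over sites of pA(1-pB) + pB(1-pA), divided by window length."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    sub = hap.alleles[hap.site_slice(window)]

    def freq(idx):
        g = sub[:, idx]
        ok = g >= 0
        n = ok.sum(axis=1)
        p = np.where(ok, g, 0).sum(axis=1) / np.where(n > 0, n, 1)
        return p, n

    pa, na = freq(hap.hap_indices(group_a))
    pb, nb = freq(hap.hap_indices(group_b))
    use = (na > 0) & (nb > 0)
    pa, pb = pa[use], pb[use]
    return float((pa * (1 - pb) + pb * (1 - pa)).sum() / window.length)


@dataclass(frozen=True)
class IlsTestResult:
    classification: str
    p_value: float
    mean_difference: float  # mean(dxy_sdr) - mean(dxy_auto)
    n_sdr: int
    n_auto: int


def ils_vs_introgression_test(dxy_sdr: Sequence[float],
                              dxy_auto: Sequence[float],
                              alpha: float = 0.05) -> IlsTestResult:
    """One-sided Mann-Whitney test of SDR divergence exceeding the
    autosomal background. Significant excess -> ILS-consistent; anything
    else (including clearly reduced divergence) -> introgression-
    consistent."""
    sdr = np.asarray([x for x in dxy_sdr if not math.isnan(x)])
    auto = np.asarray([x for x in dxy_auto if not math.isnan(x)])
    if len(sdr) < 5 or len(auto) < 5:
        raise ValueError("need >= 5 windows per class")
    res = stats.mannwhitneyu(sdr, auto, alternative="greater")
    cls = ILS_CONSISTENT if res.pvalue < alpha else INTROGRESSION_CONSISTENT
    return IlsTestResult(cls, float(res.pvalue),
                         float(sdr.mean() - auto.mean()),
                         len(sdr), len(auto))


# ---------------------------------------------------------------------------
# NG86 pairwise dN/dS
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _codon_site_counts(codon: str) -> tuple[float, float]:
    """(N_sites, S_sites) for one codon: at each position, the fraction
    of the three possible point mutations that are synonymous counts
    toward S; mutations creating stops count as nonsynonymous."""
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _CODON_TABLE[alt] == aa and _CODON_TABLE[alt] != STOP:
                s += 1.0 / 3.0
    return 3.0 - s, s


@lru_cache(maxsize=None)
def _codon_path_counts(c1: str, c2: str) -> tuple[float, float]:
    """(Nd, Sd) between two codons, averaged over all minimal mutational
    pathways with equal weight; pathways through stop codons are skipped
    (unless every pathway hits one, in which case all are used)."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0

    def walk(allow_stops: bool):
        totals = []
        for order in itertools.permutations(diff):
            cur = c1
            nd = sd = 0.0
            ok = True
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
                if _CODON_TABLE[nxt] == STOP and nxt != c2 and not allow_stops:
                    ok = False
                    break
                if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if ok:
                totals.append((nd, sd))
        return totals

    totals = walk(allow_stops=False)
    if not totals:
        totals = walk(allow_stops=True)
    nd = sum(t[0] for t in totals) / len(totals)
    sd = sum(t[1] for t in totals) / len(totals)
    return nd, sd


def _jc(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class NG86Result:
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    dn: float
    ds: float

    @property
    def ratio(self) -> float:
        if math.isnan(self.dn) or math.isnan(self.ds) or self.ds == 0:
            return math.nan
        return self.dn / self.ds


def ng86_pairwise(cds_a: str, cds_b: str) -> NG86Result:
    """Nei-Gojobori 1986 pairwise dN/dS on in-frame aligned CDS.

    Codons containing gaps or ambiguity codes are skipped pairwise;
    internal stop codons raise; a shared terminal stop codon is ignored.
    Saturated proportions (p >= 0.75) yield NaN rates.
    """
    a, b = cds_a.upper().replace("U", "T"), cds_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) % 3:
        raise ValueError("length must be a multiple of 3")
    n_codons = len(a) // 3
    n_sites = s_sites = nd = sd = 0.0
    for k in range(n_codons):
        ca, cb = a[3 * k:3 * k + 3], b[3 * k:3 * k + 3]
        if any(ch not in _BASES for ch in ca + cb):
            continue
        stop_a = _CODON_TABLE[ca] == STOP
        stop_b = _CODON_TABLE[cb] == STOP
        if stop_a or stop_b:
            if k == n_codons - 1:
                continue  # terminal stop
            raise ValueError(f"internal stop codon at codon {k + 1}")
        na_, sa_ = _codon_site_counts(ca)
        nb_, sb_ = _codon_site_counts(cb)
        n_sites += (na_ + nb_) / 2.0
        s_sites += (sa_ + sb_) / 2.0
        d_n, d_s = _codon_path_counts(ca, cb)
        nd += d_n
        sd += d_s
    pn = nd / n_sites if n_sites > 0 else math.nan
    ps = sd / s_sites if s_sites > 0 else math.nan
    return NG86Result(n_sites, s_sites, nd, sd, _jc(pn), _jc(ps))


# ---------------------------------------------------------------------------
# private substitutions
# ---------------------------------------------------------------------------

def group_derived_freqs(hap: HaplotypeMatrix,
                        groups: Mapping[str, Sequence[str]]) -> dict[str, np.ndarray]:
    der = hap.derived()
    out = {}
    for name, ids in groups.items():
        sub = der[:, hap.hap_indices(list(ids))]
        ok = sub >= 0
        n = ok.sum(axis=1)
        out[name] = np.where(ok, sub, 0).sum(axis=1) / np.where(n > 0, n, 1)
    return out


def private_substitutions(hap: HaplotypeMatrix,
                          groups: Mapping[str, Sequence[str]],
                          subst_threshold: float = 0.5
                          ) -> dict[str, np.ndarray]:
    """Positions of substitutions private to each group.

    A site is a substitution for group g when its derived-allele
    frequency in g is >= ``subst_threshold``; it is private to g when it
    additionally has derived frequency exactly 0 in every other group.
    """
    freqs = group_derived_freqs(hap, groups)
    names = list(groups)
    out: dict[str, np.ndarray] = {}
    for g in names:
        mask = freqs[g] >= subst_threshold
        for other in names:
            if other != g:
                mask &= freqs[other] == 0
        out[g] = hap.positions[mask]
    return out


def classify_sites(hap: HaplotypeMatrix,
                   groups: Mapping[str, Sequence[str]]) -> np.ndarray:
    """Presence-based partition of every site: 'absent' (derived allele
    seen in no group), 'private:<g>' (seen in exactly one group) or
    'shared' (seen in two or more groups)."""
    freqs = group_derived_freqs(hap, groups)
    names = list(groups)
    present = np.stack([freqs[g] > 0 for g in names])
    n_present = present.sum(axis=0)
    out = np.full(hap.n_sites, "shared", dtype=object)
    out[n_present == 0] = "absent"
    only = np.where(n_present == 1)[0]
    which = present[:, only].argmax(axis=0)
    for i, w in zip(only, which):
        out[i] = f"private:{names[w]}"
    return out
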
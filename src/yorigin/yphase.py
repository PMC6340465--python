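"""Assigning male heterozygous alleles to X or Y by gene-tree voting.

Inside a non-recombining SDR, one haplotype per male belongs to the Y
clade of each window tree. Phasing software does not know which, and
switch errors can swap the label mid-chromosome. The fix exploited here:
build trees in *overlapping* sliding windows; in each tree, score a
male's haplotype as Y-linked when it falls in an exclusively male clade;
then, per heterozygous site, take a majority vote over all windows that
covered the site. The voted allele is recorded as Y-linked; the
complementary allele as X-linked. Homozygous sites carry the shared
allele on both.

Votes are per-window and unweighted. Ties and uncovered sites stay
missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datamodel import (MISSING, HaplotypeMatrix, MetadataTable, Sex,
                        Species, Window, make_windows)
from .genetrees import GeneTree, build_window_tree, xy_consistent

logger = logging.getLogger(__name__)


@dataclass
class YAssignment:
    """Per (male, site) vote tally and final Y-allele call.

    Arrays are (n_sites, n_males); ``y_allele`` is 0/1/-1 and covers
    heterozygous decisions only at het sites (homozygous sites carry the
    shared allele). ``n_windows_covering`` counts qualifying windows per
    site.
    """

    chromosome: str
    positions: np.ndarray
    males: list[str]
    y_allele: np.ndarray
    votes_y_allele: np.ndarray
    votes_other: np.ndarray
    n_windows_covering: np.ndarray

    def decided_het_mask(self, hap: HaplotypeMatrix) -> np.ndarray:
        """(site, male) mask: heterozygous in the input and decided."""
        het = np.zeros(self.y_allele.shape, dtype=bool)
        for j, m in enumerate(self.males):
            ia, ib = hap.hap_indices([f"{m}_A", f"{m}_B"])
            a, b = hap.alleles[:, ia], hap.alleles[:, ib]
            het[:, j] = (a >= 0) & (b >= 0) & (a != b)
        return het & (self.y_allele >= 0)

    def to_frame(self, hap: HaplotypeMatrix):
        import pandas as pd
        rows = []
        for j, m in enumerate(self.males):
            dec = self.y_allele[:, j] >= 0
            for i in np.flatnonzero(dec):
                rows.append((m, int(self.positions[i]),
                             int(self.y_allele[i, j]),
                             int(self.votes_y_allele[i, j]),
                             int(self.votes_y_allele[i, j]
                                 + self.votes_other[i, j])))
        return pd.DataFrame(rows, columns=["sample_id", "position",
                                           "y_allele", "votes_y",
                                           "votes_total"])


def score_window_y_haplotypes(tree: GeneTree, metadata: MetadataTable,
                              focal_species: Species | str = Species.pungitius,
                              q_min: float = 0.5) -> set[tuple[str, str]]:
    """Haplotypes scored Y-linked by one window tree.

    Returns {(male sample id, "A"/"B"), ...}: the members of the largest
    exclusively-male clade covering at least ``q_min`` of the males. Two
    equally large disjoint clades -> the window is skipped (empty set).
    """
    focal_species = Species(focal_species)
    try:
        res = xy_consistent(tree, metadata, focal_species, q=q_min)
    except ValueError:
        return set()
    if not res.is_consistent:
        return set()
    # detect a disjoint equally-sized competitor: rerun the clade search
    # excluding the winner's tips
    male_samples = set(metadata.select(species=focal_species, sex=Sex.male))
    winner = set(res.clade_tips)
    competitor_sizes = []
    for node in tree.tree.postorder(include_self=False):
        if node.is_tip():
            continue
        tipset = [t.name for t in node.tips()]
        if set(tipset) & winner:
            continue
        samples = [t.rsplit("_", 1)[0] for t in tipset]
        if any(s not in male_samples for s in samples):
            continue
        if len(set(samples)) != len(samples):
            continue
        if len(set(samples)) >= q_min * res.n_males_total and len(tipset) >= 2:
            competitor_sizes.append(len(set(samples)))
    if competitor_sizes and max(competitor_sizes) >= res.n_males_covered:
        logger.info("window skipped: two equally supported male clades")
        return set()
    out = set()
    for t in res.clade_tips:
        sample, hap = t.rsplit("_", 1)
        out.add((sample, hap))
    return out


def vote_assign(hap: HaplotypeMatrix, metadata: MetadataTable,
                window_size: int = 100_000, step: int | None = None,
                q_min: float = 0.5,
                outgroup_hap: str | None = None,
                focal_species: Species | str = Species.pungitius,
                region: Window | None = None,
                min_snps: int = 5) -> YAssignment:
    """Majority-vote X/Y assignment over overlapping sliding windows.

    ``region`` restricts voting windows (e.g. to an inferred SDR); trees
    are built from focal-species + outgroup haplotypes.
    """
    step = window_size // 5 if step is None else step
    if step >= window_size:
        raise ValueError("step must be smaller than window_size: "
                         "windows must genuinely overlap")
    focal_species = Species(focal_species)
    males = metadata.select(species=focal_species, sex=Sex.male)
    if outgroup_hap is None:
        outs = metadata.select(species=Species.outgroup)
        outgroup_hap = f"{outs[0]}_A" if outs else None
    tip_set = [f"{s}_{ab}" for s in metadata.select(species=focal_species)
               for ab in "AB"]
    if outgroup_hap is not None:
        tip_set.append(outgroup_hap)

    lo = region.start if region is not None else 0
    hi = region.end if region is not None else int(hap.positions[-1]) + 1
    windows = [Window(hap.chromosome, w.start + lo, w.end + lo)
               for w in make_windows(hi - lo, window_size, step)]

    n_sites = hap.n_sites
    col = {m: j for j, m in enumerate(males)}
    votes = np.zeros((n_sites, len(males), 2), dtype=np.int32)
    covering = np.zeros(n_sites, dtype=np.int32)

    hap_cols = {(m, ab): hap.hap_indices([f"{m}_{ab}"])[0]
                for m in males for ab in "AB"}

    for w in windows:
        rows = hap.site_slice(w)
        sub = hap.alleles[rows]
        seg = ((sub == 1).any(axis=1) & (sub == 0).any(axis=1)).sum()
        if seg < min_snps:
            continue
        tree = build_window_tree(hap, w, tip_set, outgroup=outgroup_hap)
        scored = score_window_y_haplotypes(tree, metadata, focal_species,
                                           q_min)
        if not scored:
            continue
        covering[rows] += 1
        site_idx = np.arange(n_sites)[rows]
        for sample, ab in scored:
            j = col[sample]
            ia = hap_cols[(sample, "A")]
            ib = hap_cols[(sample, "B")]
            a_all = hap.alleles[rows, ia]
            b_all = hap.alleles[rows, ib]
            het = (a_all >= 0) & (b_all >= 0) & (a_all != b_all)
            y_al = a_all if ab == "A" else b_all
            for allele in (0, 1):
                sel = site_idx[het & (y_al == allele)]
                votes[sel, j, allele] += 1

    v0, v1 = votes[:, :, 0], votes[:, :, 1]
    y_allele = np.full((n_sites, len(males)), MISSING, dtype=np.int8)
    y_allele[v1 > v0] = 1
    y_allele[v0 > v1] = 0
    votes_win = np.where(y_allele == 1, v1, np.where(y_allele == 0, v0, 0))
    votes_other = np.where(y_allele == 1, v0, np.where(y_allele == 0, v1, 0))
    return YAssignment(hap.chromosome, hap.positions.copy(), males,
                       y_allele, votes_win.astype(np.int32),
                       votes_other.astype(np.int32), covering)


def build_xy_groups(hap: HaplotypeMatrix, assignment: YAssignment
                    ) -> tuple[HaplotypeMatrix, dict[str, str]]:
    """Rebuild per-male X and Y haplotypes from the vote.

    Returns a new matrix in which each focal male contributes synthetic
    ``<id>_Y`` and ``<id>_X`` columns (voted Y allele; complementary X
    allele at decided het sites; shared allele at homozygous sites;
    missing where undecided), everything else passing through unchanged,
    plus a haplotype->"X"/"Y" label map (females' haplotypes are
    X-eligible).
    """
    males = assignment.males
    male_set = set(males)
    keep_cols = [i for i, h in enumerate(hap.hap_ids)
                 if h.rsplit("_", 1)[0] not in male_set]
    new_ids = [hap.hap_ids[i] for i in keep_cols]
    cols = [hap.alleles[:, i] for i in keep_cols]
    xy_labels: dict[str, str] = {}
    for h in new_ids:
        xy_labels[h] = "X"
    for j, m in enumerate(males):
        ia, ib = hap.hap_indices([f"{m}_A", f"{m}_B"])
        a, b = hap.alleles[:, ia], hap.alleles[:, ib]
        hom = (a == b)  # includes double-missing
        het = (a >= 0) & (b >= 0) & (a != b)
        y = np.full(hap.n_sites, MISSING, dtype=np.int8)
        x = np.full(hap.n_sites, MISSING, dtype=np.int8)
        y[hom] = a[hom]
        x[hom] = a[hom]
        dec = het & (assignment.y_allele[:, j] >= 0)
        y[dec] = assignment.y_allele[dec, j]
        x[dec] = 1 - assignment.y_allele[dec, j]
        new_ids.extend([f"{m}_X", f"{m}_Y"])
        cols.extend([x, y])
        xy_labels[f"{m}_X"] = "X"
        xy_labels[f"{m}_Y"] = "Y"
    alleles = np.stack(cols, axis=1)
    out = HaplotypeMatrix(hap.chromosome, hap.positions, alleles, new_ids,
                          hap.ancestral_state, ref=hap.ref, alt=hap.alt)
    return out, xy_labels
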
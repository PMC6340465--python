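"""Window gene trees and the topology classifiers built on them.

Trees are neighbor-joining on Jukes-Cantor distances between haplotypes,
rooted on the outgroup haplotype when present (midpoint otherwise). Three
classifiers read them:

* ``xy_consistent`` - does one haplotype from (almost) every male of the
  focal species form an exclusively-male clade? That is the signature of
  a non-recombining Y in an XY system.
* ``topology_weights`` - quartet weighting over four designated groups
  (focal-species X, focal-species Y, donor-candidate species, its sister
  species), sampling one haplotype per group.
* ``classify_direction`` - which lineage nests inside which, deciding
  whether the male-limited haplotype group was donated by the candidate
  species or vice versa.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .datamodel import HaplotypeMatrix, MetadataTable, Sex, Species, Window

logger = logging.getLogger(__name__)

JC_SATURATION_CAP = 5.0


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

def jc_distance_matrix(hap: HaplotypeMatrix, window: Window | None,
                       tip_set: Sequence[str]) -> DistanceMatrix:
    """Jukes-Cantor-corrected pairwise distances over shared non-missing
    sites. Saturated pairs (p >= 0.75) are capped at JC_SATURATION_CAP.

    Tip order is canonicalized (sorted) so downstream tree construction
    does not depend on caller ordering.
    """
    tips = sorted(set(tip_set))
    if not tips:
        raise ValueError("empty tip set")
    rows = hap.site_slice(window) if window is not None else slice(None)
    sub = hap.alleles[rows][:, hap.hap_indices(tips)]
    ok = (sub >= 0)
    x = np.where(ok, sub, 0).astype(np.float64)
    m = ok.astype(np.float64)
    shared = m.T @ m
    half = x.T @ (m - x)
    diffs = half + half.T
    if (shared == 0).any() and len(tips) > 1:
        off = shared + np.eye(len(tips)) * 1
        if (off == 0).any():
            raise ValueError("some haplotype pairs share no comparable site")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(shared > 0, diffs / np.where(shared > 0, shared, 1), 0.0)
    sat = p >= 0.75
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(sat, JC_SATURATION_CAP, -0.75 * np.log1p(-4.0 * p / 3.0))
    np.fill_diagonal(d, 0.0)
    n_sat = int(np.triu(sat, 1).sum())
    if n_sat:
        logger.info("%d saturated pairs capped at %.1f", n_sat,
                    JC_SATURATION_CAP)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, tips)


@dataclass
class GeneTree:
    """A rooted window tree over haplotype tips."""

    tree: TreeNode
    window: Window | None = None
    rooted_by: str = "outgroup"
    _lca_cache: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def tip_names(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    def newick(self) -> str:
        return str(self.tree).strip()

    def is_rooted(self) -> bool:
        return len(self.tree.children) == 2

    # -- pairwise LCA depths (one postorder pass) -----------------------
    def lca_depths(self) -> tuple[np.ndarray, dict[str, int]]:
        """Matrix L with L[i, j] = depth (edges from root) of lca(tip i,
        tip j); tips indexed by the returned name map."""
        if self._lca_cache is not None:
            return self._lca_cache
        names = self.tip_names
        col = {nm: i for i, nm in enumerate(names)}
        n = len(names)
        L = np.zeros((n, n), dtype=np.int32)
        depth: dict[int, int] = {id(self.tree): 0}
        for node in self.tree.preorder(include_self=False):
            depth[id(node)] = depth[id(node.parent)] + 1
        tipsets: dict[int, np.ndarray] = {}
        for node in self.tree.postorder(include_self=True):
            if node.is_tip():
                tipsets[id(node)] = np.array([col[node.name]], dtype=np.intp)
                continue
            kid_sets = [tipsets.pop(id(k)) for k in node.children]
            d = depth[id(node)]
            for a, b in itertools.combinations(kid_sets, 2):
                L[np.ix_(a, b)] = d
                L[np.ix_(b, a)] = d
            tipsets[id(node)] = np.concatenate(kid_sets)
        self._lca_cache = (L, col)
        return self._lca_cache


def nj_tree(dm: DistanceMatrix, outgroup: str | None = None,
            window: Window | None = None) -> GeneTree:
    """Neighbor joining, then rooting on the outgroup tip when present
    (midpoint otherwise, logged). Deterministic for a given matrix."""
    if dm.shape[0] < 3:
        raise ValueError("need at least 3 tips")
    if not np.isfinite(dm.data).all():
        raise ValueError("non-finite distances")
    unrooted = nj(dm)
    if outgroup is not None and outgroup in dm.ids:
        rooted = unrooted.root_by_outgroup([outgroup])
        rooted_by = "outgroup"
    else:
        rooted = unrooted.root_at_midpoint()
        rooted_by = "midpoint"
        logger.info("no outgroup tip; rooted at midpoint")
    return GeneTree(rooted, window=window, rooted_by=rooted_by)


def build_window_tree(hap: HaplotypeMatrix, window: Window | None,
                      tip_set: Sequence[str],
                      outgroup: str | None = None) -> GeneTree:
    return nj_tree(jc_distance_matrix(hap, window, tip_set),
                   outgroup=outgroup, window=window)


# ---------------------------------------------------------------------------
# XY-consistency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class XYConsistency:
    is_consistent: bool
    clade_tips: tuple[str, ...]
    n_males_covered: int
    n_males_total: int


def _sample_of(tip_name: str) -> str:
    return tip_name.rsplit("_", 1)[0]


def xy_consistent(tree: GeneTree, metadata: MetadataTable,
                  focal_species: Species | str,
                  q: float = 1.0) -> XYConsistency:
    """Search for an exclusively focal-male clade with at most one
    haplotype per male, covering at least a fraction ``q`` of the males
    present in the tree. Returns the maximal qualifying clade."""
    if not tree.is_rooted():
        raise ValueError("tree must be rooted (binary root)")
    focal_species = Species(focal_species)
    male_samples = set(metadata.select(species=focal_species, sex=Sex.male))
    tips_in_tree = tree.tip_names
    males_in_tree = {_sample_of(t) for t in tips_in_tree} & male_samples
    n_males = len(males_in_tree)
    if n_males < 2:
        raise ValueError("need >= 2 focal males in the tree")

    best: tuple[int, int, tuple[str, ...]] | None = None
    for node in tree.tree.postorder(include_self=False):
        if node.is_tip():
            continue
        tipset = sorted(t.name for t in node.tips())
        if len(tipset) < 2:
            continue
        samples = [_sample_of(t) for t in tipset]
        if any(s not in male_samples for s in samples):
            continue
        if len(set(samples)) != len(samples):  # both haplotypes of a male
            continue
        covered = len(set(samples))
        if covered < q * n_males:
            continue
        cand = (covered, len(tipset), tuple(tipset))
        if best is None or (cand[0], cand[1], cand[2]) > \
                (best[0], best[1], best[2]):
            best = cand
    if best is None:
        return XYConsistency(False, (), 0, n_males)
    return XYConsistency(True, best[2], best[0], n_males)


# ---------------------------------------------------------------------------
# topology weighting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyWeights:
    """Weights of the three unrooted quartet topologies for ordered
    groups (g1, g2, g3, g4): T1 = g1g2|g3g4, T2 = g1g3|g2g4,
    T3 = g1g4|g2g3."""

    t1: float
    t2: float
    t3: float
    n_quartets: int
    exhaustive: bool

    def as_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3])


def _check_groups(groups: Sequence[Sequence[str]], tree_tips: set[str],
                  n: int) -> list[list[str]]:
    if len(groups) != n:
        raise ValueError(f"need exactly {n} groups")
    cleaned = []
    seen: set[str] = set()
    for g in groups:
        g = list(g)
        if not g:
            raise ValueError("empty group")
        if seen & set(g):
            raise ValueError(f"overlapping groups: {sorted(seen & set(g))}")
        missing = set(g) - tree_tips
        if missing:
            raise ValueError(f"group tips not in tree: {sorted(missing)}")
        seen |= set(g)
        cleaned.append(g)
    return cleaned


def topology_weights(tree: GeneTree, groups: Sequence[Sequence[str]],
                     max_exhaustive: int = 10_000, n_mc: int = 1000,
                     seed: int | np.random.Generator = 0) -> TopologyWeights:
    """Quartet topology weights: one tip sampled per group, topology read
    off the tree, frequencies over all (or ``n_mc`` sampled) quartets.

    For a quartet (a, b, c, d) on a binary tree the realized pairing is
    the one whose two LCAs are jointly deepest.
    """
    groups = _check_groups(groups, set(tree.tip_names), 4)
    L, col = tree.lca_depths()
    idx = [np.array([col[t] for t in g], dtype=np.intp) for g in groups]
    sizes = [len(g) for g in groups]
    n_total = int(np.prod(sizes))
    exhaustive = n_total <= max_exhaustive

    if exhaustive:
        a, b, c, d = idx
        s1 = (L[np.ix_(a, b)][:, :, None, None]
              + L[np.ix_(c, d)][None, None, :, :])
        s2 = (L[np.ix_(a, c)][:, None, :, None]
              + L[np.ix_(b, d)][None, :, None, :])
        s3 = (L[np.ix_(a, d)][:, None, None, :]
              + L[np.ix_(b, c)][None, :, :, None])
        n_quartets = n_total
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        draws = [g[rng.integers(len(g), size=n_mc)] for g in idx]
        a, b, c, d = draws
        s1 = L[a, b] + L[c, d]
        s2 = L[a, c] + L[b, d]
        s3 = L[a, d] + L[b, c]
        n_quartets = n_mc

    stacked = np.stack([s1, s2, s3])
    winner = np.argmax(stacked, axis=0)  # first max wins on ties
    counts = np.bincount(winner.ravel(), minlength=3)
    w = counts / counts.sum()
    return TopologyWeights(float(w[0]), float(w[1]), float(w[2]),
                           n_quartets, exhaustive)


# ---------------------------------------------------------------------------
# direction of introgression
# ---------------------------------------------------------------------------

DONOR_SINENSIS = "donor_sinensis"
DONOR_PUNGITIUS = "donor_pungitius"
AMBIGUOUS = "ambiguous"


def classify_direction(tree: GeneTree,
                       groups: Mapping[str, Sequence[str]]) -> str:
    """Decide the direction of the transfer from nesting structure.

    ``groups`` maps punX / punY / sin / tym to tip-name lists. The donor
    is the candidate species when the male-limited (Y) clade nests inside
    it (the species is paraphyletic with respect to the Y); the reverse
    nesting pattern supports the focal species as donor.
    """
    for key in ("punX", "punY", "sin", "tym"):
        if key not in groups or not list(groups[key]):
            raise ValueError(f"missing group {key!r}")
    if not tree.is_rooted():
        raise ValueError("tree must be rooted on the outgroup")
    punX = list(groups["punX"])
    punY = list(groups["punY"])
    sin = list(groups["sin"])
    tym = list(groups["tym"])
    t = tree.tree

    def clade(tips: list[str]) -> tuple[TreeNode, set[str]]:
        node = t.lca(tips) if len(tips) > 1 else t.find(tips[0])
        return node, {x.name for x in node.tips()}

    node_ysin, set_ysin = clade(punY + sin)
    node_sin, _ = clade(sin)
    if (not set_ysin & set(punX) and not set_ysin & set(tym)
            and node_ysin is node_sin):
        return DONOR_SINENSIS

    node_pun, set_pun = clade(punX + punY)
    node_punsin, _ = clade(punX + punY + sin)
    if (set(sin) <= set_pun and not set_pun & set(tym)
            and node_pun is node_punsin):
        return DONOR_PUNGITIUS
    return AMBIGUOUS
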
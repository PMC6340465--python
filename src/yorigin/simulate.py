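"""Synthetic phased-genotype generator with known truth.

Each window gets one genealogy from a structured coalescent over the
three-species tree ((sinensis, tymensis), pungitius) plus a single
outgroup haplotype; mutations are dropped on branches under an
infinite-sites model within the window. There is no recombination inside
a window and free recombination between windows, which matches the
windowed statistics every downstream stage computes and keeps per-window
expectations in closed form.

Scenarios control the genealogy of SDR windows:

``introgression``
    one haplotype per focal-species male (the Y) descends from a single
    lineage that attaches inside the sinensis clade at ``t_intro``;
``ils`` / ``xy_ancestral``
    the Y lineage stays distinct until ``t_ydeep`` (above the deepest
    species split), producing elevated Y divergence;
``donor_pungitius``
    the reverse transfer: the sinensis lineage nests inside the male
    clade, which rejoins pungitius at ``t_xy``;
``no_sdr``
    every window follows the species tree (null model).

Times are in coalescent units; ``mu`` is the per-site mutation rate per
coalescent unit, calibrated together with the split times so autosomal
divergences sit at the d_S scale of closely related stickleback species
(sinensis-tymensis ~ 0.018, sinensis-pungitius ~ 0.025 per site).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .datamodel import (HaplotypeMatrix, MetadataTable, SampleMetadata,
                        Sex, Species, Window, WindowLabel, make_windows)
from .vcfio import (_hap_ids_for, write_metadata, write_truth_table,
                    write_vcf_multi)

# SDR placement is scaled from the inversion breakpoints (3.5-18.9 Mb) on
# a 20.6-Mb nominal sex chromosome.
_SDR_REF = (3_500_000, 18_900_000)
_CHROM_REF_LENGTH = 20_600_000

_SCENARIOS = ("introgression", "ils", "no_sdr", "xy_ancestral",
              "donor_pungitius")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ScenarioConfig:
    """Study conditions for one simulated dataset."""

    scenario: str = "introgression"
    n_pungitius_males: int = 15
    n_pungitius_females: int = 15
    n_sinensis_males: int = 11
    n_sinensis_females: int = 9
    n_tymensis_males: int = 13
    n_tymensis_females: int = 10
    chrom_length: int = 2_000_000
    autosome_length: int | None = None
    window_size: int = 100_000
    sdr_start: int | None = None
    sdr_end: int | None = None
    # split times (coalescent units)
    t_intro: float = 0.1
    t_resolve: float = 0.05
    t_st: float = 0.54
    t_pun: float = 0.77
    t_ydeep: float = 1.0
    t_xy: float = 0.35
    t_out: float = 1.3
    coal_rate: float = 20.0
    jitter: float = 1.0
    mu: float = 0.0152
    phase_switch_rate: float = 0.0
    seed: int = 0
    sex_chrom: str = "chr12"
    autosome: str = "chr1"

    def __post_init__(self) -> None:
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {_SCENARIOS}")
        if self.autosome_length is None:
            self.autosome_length = self.chrom_length
        scale = self.chrom_length / _CHROM_REF_LENGTH
        if self.sdr_start is None:
            self.sdr_start = int(_SDR_REF[0] * scale)
        if self.sdr_end is None:
            self.sdr_end = int(_SDR_REF[1] * scale)
        if not (0 <= self.sdr_start < self.sdr_end <= self.chrom_length):
            raise ValueError("SDR interval must lie inside [0, chrom_length)")
        if not (0 < self.t_intro < self.t_st < self.t_pun):
            raise ValueError("need 0 < t_intro < t_st < t_pun")
        if self.t_resolve < 0 or self.t_intro + self.t_resolve >= \
                min(self.t_xy, self.t_st):
            raise ValueError("t_resolve must fit between t_intro and the "
                             "next split")
        if self.t_ydeep <= self.t_pun:
            raise ValueError("t_ydeep must exceed t_pun")
        if not (self.t_intro < self.t_xy < self.t_st):
            raise ValueError("need t_intro < t_xy < t_st")
        if self.t_out <= self.t_ydeep:
            raise ValueError("t_out must exceed t_ydeep (and every split)")
        if min(self.coal_rate, self.mu) < 0 or self.jitter < 0:
            raise ValueError("rates must be non-negative")
        if not (0 <= self.phase_switch_rate <= 1):
            raise ValueError("phase_switch_rate must be in [0, 1]")

    # -- derived layout -------------------------------------------------
    def metadata(self) -> MetadataTable:
        recs = []
        for i in range(self.n_pungitius_males):
            recs.append(SampleMetadata(f"pun_m{i + 1:02d}", Species.pungitius, Sex.male))
        for i in range(self.n_pungitius_females):
            recs.append(SampleMetadata(f"pun_f{i + 1:02d}", Species.pungitius, Sex.female))
        for i in range(self.n_sinensis_males):
            recs.append(SampleMetadata(f"sin_m{i + 1:02d}", Species.sinensis, Sex.male))
        for i in range(self.n_sinensis_females):
            recs.append(SampleMetadata(f"sin_f{i + 1:02d}", Species.sinensis, Sex.female))
        for i in range(self.n_tymensis_males):
            recs.append(SampleMetadata(f"tym_m{i + 1:02d}", Species.tymensis, Sex.male))
        for i in range(self.n_tymensis_females):
            recs.append(SampleMetadata(f"tym_f{i + 1:02d}", Species.tymensis, Sex.female))
        recs.append(SampleMetadata("out_1", Species.outgroup, Sex.unknown))
        return MetadataTable(recs)

    def windows(self) -> list[Window]:
        """Labeled window plan: autosome first, then the sex chromosome."""
        out = [w.relabel(WindowLabel.autosome)
               for w in make_windows(self.autosome_length, self.window_size,
                                     chromosome=self.autosome)]
        for w in make_windows(self.chrom_length, self.window_size,
                              chromosome=self.sex_chrom):
            mid = (w.start + w.end) // 2
            if self.scenario != "no_sdr" and self.sdr_start <= mid < self.sdr_end:
                out.append(w.relabel(WindowLabel.SDR))
            else:
                out.append(w.relabel(WindowLabel.PAR))
        return out

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class TruthTable:
    """Ground truth of one simulated dataset."""

    scenario: str
    window_classes: list[tuple[int, str]]
    y_hap: dict[str, str]  # male sample id -> "A"/"B" (true Y haplotype)

    def y_hap_ids(self) -> list[str]:
        return [f"{s}_{h}" for s, h in sorted(self.y_hap.items())]


class Genealogy:
    """Rooted binary genealogy over haplotype tips, built by merges."""

    def __init__(self, tip_ids: Sequence[str]):
        self.tip_ids = list(tip_ids)
        n = len(self.tip_ids)
        self._times: list[float] = [0.0] * n
        self._parent: list[int] = [-1] * n
        self._children: list[tuple[int, int] | None] = [None] * n

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    @property
    def n_nodes(self) -> int:
        return len(self._times)

    @property
    def times(self) -> np.ndarray:
        return np.asarray(self._times)

    @property
    def parent(self) -> np.ndarray:
        return np.asarray(self._parent)

    def merge(self, a: int, b: int, t: float) -> int:
        if t < max(self._times[a], self._times[b]) - 1e-12:
            raise ValueError("merge time precedes child times")
        node = len(self._times)
        self._times.append(float(t))
        self._parent.append(-1)
        self._children.append((a, b))
        self._parent[a] = node
        self._parent[b] = node
        return node

    @property
    def root(self) -> int:
        return len(self._times) - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        t = self.times
        p = self.parent
        out = np.zeros(self.n_nodes)
        nz = p >= 0
        out[nz] = t[p[nz]] - t[nz]
        return out

    def descendant_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips): tip j descends from (or is) node i."""
        n, nt = self.n_nodes, self.n_tips
        desc = np.zeros((n, nt), dtype=bool)
        desc[np.arange(nt), np.arange(nt)] = True
        for node in range(nt, n):
            a, b = self._children[node]
            desc[node] = desc[a] | desc[b]
        return desc

    def mrca(self, tip_indices: Sequence[int]) -> int:
        desc = self.descendant_matrix()
        covering = np.flatnonzero(desc[:, list(tip_indices)].all(axis=1))
        return int(covering[np.argmin(self.times[covering])])

    def tmrca(self, tip_indices: Sequence[int]) -> float:
        return float(self.times[self.mrca(tip_indices)])

    def tip_index(self, tip_id: str) -> int:
        return self.tip_ids.index(tip_id)


# ---------------------------------------------------------------------------
# coalescent machinery
# ---------------------------------------------------------------------------

def _coalesce(rng: np.random.Generator, gen: Genealogy, lineages: list[int],
              t_start: float, t_end: float | None, rate: float, jitter: float,
              floor: int = 1) -> tuple[list[int], float]:
    """Pairwise coalescence at per-pair ``rate`` from t_start until t_end
    (or until ``floor`` lineages remain). Waiting times are scaled by
    ``jitter``; jitter 0 collapses the population instantly."""
    t = t_start
    while len(lineages) > floor:
        k = len(lineages)
        total = rate * k * (k - 1) / 2.0
        if jitter == 0.0 or not np.isfinite(1.0 / total):
            dt = 0.0
        else:
            dt = jitter * rng.exponential(1.0 / total)
        if t_end is not None and t + dt > t_end:
            return lineages, t_end
        t += dt
        i, j = sorted(rng.choice(k, size=2, replace=False))
        node = gen.merge(lineages[i], lineages[j], t)
        lineages = [x for n, x in enumerate(lineages) if n not in (i, j)]
        lineages.append(node)
    return lineages, (t_end if t_end is not None else t)


def _force_merge(rng: np.random.Generator, gen: Genealogy,
                 lineages: list[int], t: float) -> int:
    """Collapse all remaining lineages into one at exactly time t."""
    lineages = list(lineages)
    while len(lineages) > 1:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        node = gen.merge(lineages[i], lineages[j], t)
        lineages = [x for n, x in enumerate(lineages) if n not in (i, j)]
        lineages.append(node)
    return lineages[0]


def _tip_layout(config: ScenarioConfig, metadata: MetadataTable
                ) -> tuple[list[str], dict[str, list[int]]]:
    hap_ids = _hap_ids_for(metadata, metadata.sample_ids)
    by_species: dict[str, list[int]] = {s.value: [] for s in Species}
    for i, h in enumerate(hap_ids):
        sid = h.rsplit("_", 1)[0]
        by_species[metadata[sid].species.value].append(i)
    return hap_ids, by_species


def simulate_window_genealogy(config: ScenarioConfig, window: Window, seed,
                              y_hap: dict[str, str] | None = None) -> Genealogy:
    """One genealogy over all haplotype tips for one labeled window.

    ``y_hap`` names the true Y haplotype ("A"/"B") of every focal-species
    male; it only matters for SDR windows. Raises on unlabeled windows.
    """
    if window.label is WindowLabel.unknown:
        raise ValueError("window must carry a class label")
    rng = _rng(seed)
    metadata = config.metadata()
    hap_ids, by_species = _tip_layout(config, metadata)
    gen = Genealogy(hap_ids)
    jit, rate = config.jitter, config.coal_rate

    males = metadata.select(species=Species.pungitius, sex=Sex.male)
    if y_hap is None:
        y_hap = {m: "A" for m in males}

    sdr_like = (window.label is WindowLabel.SDR
                and config.scenario != "no_sdr")
    out_tip = by_species["outgroup"][0]

    if not sdr_like:
        pun = list(by_species["pungitius"])
        sin = list(by_species["sinensis"])
        tym = list(by_species["tymensis"])
        pun, _ = _coalesce(rng, gen, pun, 0.0, config.t_st, rate, jit)
        sin, _ = _coalesce(rng, gen, sin, 0.0, config.t_st, rate, jit)
        tym, _ = _coalesce(rng, gen, tym, 0.0, config.t_st, rate, jit)
        st, _ = _coalesce(rng, gen, sin + tym, config.t_st, config.t_pun, rate, jit)
        pun, _ = _coalesce(rng, gen, pun, config.t_st, config.t_pun, rate, jit)
        anc, _ = _coalesce(rng, gen, st + pun, config.t_pun, config.t_out, rate, jit)
        root = _force_merge(rng, gen, anc, config.t_out)
        gen.merge(root, out_tip, config.t_out)
        return gen

    y_tips = [gen.tip_index(f"{m}_{y_hap[m]}") for m in males]
    y_set = set(y_tips)
    pun = [i for i in by_species["pungitius"] if i not in y_set]
    sin = list(by_species["sinensis"])
    tym = list(by_species["tymensis"])
    t_y = config.t_intro / 2.0

    if config.scenario in ("introgression", "ils", "xy_ancestral"):
        ys, _ = _coalesce(rng, gen, y_tips, 0.0, t_y, rate, jit)
        y_anc = _force_merge(rng, gen, ys, t_y)
        if config.scenario == "introgression":
            # hold sinensis at >= 2 lineages so the Y attaches strictly
            # inside the sinensis clade at t_intro
            sin, _ = _coalesce(rng, gen, sin, 0.0, config.t_intro, rate, jit,
                               floor=2)
            host = int(rng.integers(len(sin)))
            joined = gen.merge(sin[host], y_anc, config.t_intro)
            sin = [x for n, x in enumerate(sin) if n != host] + [joined]
            pun, _ = _coalesce(rng, gen, pun, 0.0, config.t_st, rate, jit)
            tym, _ = _coalesce(rng, gen, tym, 0.0, config.t_st, rate, jit)
            # guard interval: the nesting branch above the attachment gets
            # at least t_resolve of length so it is resolvable from data
            sin, _ = _coalesce(rng, gen, sin,
                               config.t_intro + config.t_resolve,
                               config.t_st, rate, jit)
            st, _ = _coalesce(rng, gen, sin + tym, config.t_st, config.t_pun, rate, jit)
            pun, _ = _coalesce(rng, gen, pun, config.t_st, config.t_pun, rate, jit)
            anc, _ = _coalesce(rng, gen, st + pun, config.t_pun, config.t_out, rate, jit)
        else:  # ils / xy_ancestral: Y lineage attaches above t_pun
            pun, _ = _coalesce(rng, gen, pun, 0.0, config.t_st, rate, jit)
            sin, _ = _coalesce(rng, gen, sin, 0.0, config.t_st, rate, jit)
            tym, _ = _coalesce(rng, gen, tym, 0.0, config.t_st, rate, jit)
            st, _ = _coalesce(rng, gen, sin + tym, config.t_st, config.t_pun, rate, jit)
            pun, _ = _coalesce(rng, gen, pun, config.t_st, config.t_pun, rate, jit)
            anc, _ = _coalesce(rng, gen, st + pun, config.t_pun, config.t_ydeep,
                               rate, jit)
            anc, _ = _coalesce(rng, gen, anc + [y_anc], config.t_ydeep,
                               config.t_out, rate, jit)
    elif config.scenario == "donor_pungitius":
        # sinensis chromosome descends from the male-limited lineage
        sins, _ = _coalesce(rng, gen, sin, 0.0, t_y, rate, jit)
        sin_anc = _force_merge(rng, gen, sins, t_y)
        ys, _ = _coalesce(rng, gen, y_tips, 0.0, config.t_intro, rate, jit,
                          floor=2)
        host = int(rng.integers(len(ys)))
        joined = gen.merge(ys[host], sin_anc, config.t_intro)
        ys = [x for n, x in enumerate(ys) if n != host] + [joined]
        ys, _ = _coalesce(rng, gen, ys, config.t_intro + config.t_resolve,
                          config.t_xy, rate, jit)
        pun, _ = _coalesce(rng, gen, pun, 0.0, config.t_xy, rate, jit)
        pun, _ = _coalesce(rng, gen, pun + ys, config.t_xy, config.t_pun, rate, jit)
        tym, _ = _coalesce(rng, gen, tym, 0.0, config.t_pun, rate, jit)
        anc, _ = _coalesce(rng, gen, pun + tym, config.t_pun, config.t_out, rate, jit)
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(f"scenario {config.scenario!r} has no SDR genealogy")

    root = _force_merge(rng, gen, anc, config.t_out)
    gen.merge(root, out_tip, config.t_out)
    return gen


# ---------------------------------------------------------------------------
# mutations and phase errors
# ---------------------------------------------------------------------------

def drop_mutations(gen: Genealogy, mu: float, length: int, seed,
                   window: Window | None = None) -> HaplotypeMatrix:
    """Poisson mutation dropping under infinite sites within the window.

    Each branch receives Poisson(mu * length * branch_length) mutations;
    every mutation gets a unique position. The returned matrix is coded
    with ancestral state 0 everywhere.
    """
    rng = _rng(seed)
    bl = gen.branch_lengths()
    total = float(bl.sum())
    if not np.isfinite(total):
        raise ValueError("non-finite total branch length")
    expected = mu * length * total
    if expected > length / 2:
        raise ValueError(
            f"expected {expected:.0f} mutations on {length} bp violates "
            "the infinite-sites assumption; lower mu or shorten branches")
    n_mut = int(rng.poisson(expected))
    n_mut = min(n_mut, length)
    positions = np.sort(rng.choice(length, size=n_mut, replace=False))
    branches = rng.choice(gen.n_nodes, size=n_mut,
                          p=bl / total if total > 0 else None)
    desc = gen.descendant_matrix()
    alleles = desc[branches].astype(np.int8)
    offset = window.start if window is not None else 0
    chrom = window.chromosome if window is not None else "chr_sim"
    return HaplotypeMatrix(chrom, positions + offset, alleles, gen.tip_ids,
                           np.zeros(n_mut, dtype=np.int8))


def inject_phase_errors(hap: HaplotypeMatrix, rate: float, seed,
                        metadata: MetadataTable) -> HaplotypeMatrix:
    """Markov switch process along sites for each male sample.

    A switch at site s exchanges the two haplotype columns from s onward;
    ground truth (which chromosome is which) is defined by the original
    columns and is NOT updated here.
    """
    if not (0 <= rate <= 1):
        raise ValueError("switch rate must be in [0, 1]")
    alleles = hap.alleles.copy()
    rng = _rng(seed)
    if rate > 0:
        hap_set = set(hap.hap_ids)
        for sid in metadata.select(sex=Sex.male):
            a_id, b_id = f"{sid}_A", f"{sid}_B"
            if a_id not in hap_set or b_id not in hap_set:
                continue
            ia, ib = hap.hap_indices([a_id, b_id])
            switches = rng.random(hap.n_sites) < rate
            swapped = np.cumsum(switches) % 2 == 1
            tmp = alleles[swapped, ia].copy()
            alleles[swapped, ia] = alleles[swapped, ib]
            alleles[swapped, ib] = tmp
    return HaplotypeMatrix(hap.chromosome, hap.positions, alleles,
                           hap.hap_ids, hap.ancestral_state,
                           ref=hap.ref, alt=hap.alt)


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

@dataclass
class SimulatedDataset:
    config: ScenarioConfig
    metadata: MetadataTable
    haplotypes: dict[str, HaplotypeMatrix]  # chromosome -> matrix
    windows: list[Window]
    truth: TruthTable

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "simulated.vcf",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.tsv",
            "scenario": outdir / "scenario.yaml",
        }
        chroms = [self.config.autosome, self.config.sex_chrom]
        write_vcf_multi([self.haplotypes[c] for c in chroms
                         if c in self.haplotypes],
                        self.metadata, paths["vcf"])
        write_metadata(self.metadata, paths["metadata"])
        write_truth_table(paths["truth"], self.truth.window_classes,
                          self.truth.y_hap)
        self.config.to_yaml(paths["scenario"])
        return paths


def simulate_dataset(config: ScenarioConfig) -> SimulatedDataset:
    """Simulate every window of the autosome + sex chromosome."""
    metadata = config.metadata()
    windows = config.windows()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(len(windows) + 2)
    rng_global = np.random.default_rng(seeds[0])

    males = metadata.select(species=Species.pungitius, sex=Sex.male)
    if config.scenario == "no_sdr":
        y_hap: dict[str, str] = {}
    else:
        y_hap = {m: ("A" if rng_global.random() < 0.5 else "B")
                 for m in males}

    per_chrom: dict[str, list[HaplotypeMatrix]] = {}
    window_classes: list[tuple[int, str]] = []
    for i, w in enumerate(windows):
        rng_w = np.random.default_rng(seeds[2 + i])
        gen = simulate_window_genealogy(config, w, rng_w, y_hap=y_hap)
        hm = drop_mutations(gen, config.mu, w.length, rng_w, window=w)
        per_chrom.setdefault(w.chromosome, []).append(hm)
        window_classes.append((i, w.label.value))

    haplotypes: dict[str, HaplotypeMatrix] = {}
    for chrom, parts in per_chrom.items():
        positions = np.concatenate([p.positions for p in parts])
        alleles = np.concatenate([p.alleles for p in parts], axis=0)
        anc = np.concatenate([p.ancestral_state for p in parts])
        hm = HaplotypeMatrix(chrom, positions, alleles, parts[0].hap_ids, anc)
        if config.phase_switch_rate > 0:
            hm = inject_phase_errors(hm, config.phase_switch_rate,
                                     np.random.default_rng(seeds[1]), metadata)
        haplotypes[chrom] = hm

    truth = TruthTable(config.scenario, window_classes, y_hap)
    return SimulatedDataset(config, metadata, haplotypes, windows, truth)
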
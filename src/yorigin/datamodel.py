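"""Core data types shared by every pipeline stage.

Coordinates are 0-based half-open internally; VCF I/O converts to/from
1-based positions at the boundary. Alleles are coded 0 (reference state),
1 (alternate) and -1 (missing) in int8 arrays of shape (sites, haplotypes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)


class Species(str, Enum):
    pungitius = "pungitius"
    sinensis = "sinensis"
    tymensis = "tymensis"
    outgroup = "outgroup"


class Sex(str, Enum):
    male = "male"
    female = "female"
    unknown = "unknown"


class WindowLabel(str, Enum):
    autosome = "autosome"
    PAR = "PAR"
    SDR = "SDR"
    unknown = "unknown"


@dataclass(frozen=True)
class SampleMetadata:
    """One sequenced diploid (or the haploid outgroup reference sample)."""

    sample_id: str
    species: Species
    sex: Sex = Sex.unknown

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species(self.species))
        object.__setattr__(self, "sex", Sex(self.sex))


class MetadataTable:
    """Collection of SampleMetadata with unique sample ids and lookups."""

    def __init__(self, records: Iterable[SampleMetadata]):
        self.records: list[SampleMetadata] = list(records)
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample ids: {dupes}")
        self._by_id = {r.sample_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleMetadata:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def select(self, species: Species | str | None = None,
               sex: Sex | str | None = None) -> list[str]:
        out = []
        for r in self.records:
            if species is not None and r.species != Species(species):
                continue
            if sex is not None and r.sex != Sex(sex):
                continue
            out.append(r.sample_id)
        return out


@dataclass(frozen=True)
class Window:
    """Half-open genomic interval [start, end)."""

    chromosome: str
    start: int
    end: int
    label: WindowLabel = WindowLabel.unknown

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end {self.end} <= start {self.start}")
        object.__setattr__(self, "label", WindowLabel(self.label))

    @property
    def length(self) -> int:
        return self.end - self.start

    def relabel(self, label: WindowLabel | str) -> "Window":
        return Window(self.chromosome, self.start, self.end, WindowLabel(label))

    def overlaps(self, other: "Window") -> bool:
        return (self.chromosome == other.chromosome
                and self.start < other.end and other.start < self.end)


@dataclass(frozen=True)
class RegionAnnotation:
    """Recombination-suppressed interval on the focal chromosome."""

    chromosome: str
    sdr_start: int
    sdr_end: int

    def __post_init__(self) -> None:
        if self.sdr_start >= self.sdr_end:
            raise ValueError("sdr_start must be < sdr_end")

    def label_window(self, w: Window, par_as: WindowLabel = WindowLabel.PAR) -> Window:
        """Label a focal-chromosome window by its midpoint; elsewhere autosome."""
        if w.chromosome != self.chromosome:
            return w.relabel(WindowLabel.autosome)
        mid = (w.start + w.end) // 2
        if self.sdr_start <= mid < self.sdr_end:
            return w.relabel(WindowLabel.SDR)
        return w.relabel(par_as)


class HaplotypeMatrix:
    """Phased biallelic alleles over (site, haplotype).

    ``alleles[s, h]`` is 0/1/-1. Haplotype ids are ``<sample_id>_A`` /
    ``<sample_id>_B`` (the outgroup sample may be haploid: a single
    ``<id>_A`` column). ``ancestral_state`` holds the outgroup/reference
    allele per site, used to polarize derived-allele statistics.
    """

    def __init__(self, chromosome: str, positions: np.ndarray,
                 alleles: np.ndarray, hap_ids: Sequence[str],
                 ancestral_state: np.ndarray | None = None,
                 ref: Sequence[str] | None = None,
                 alt: Sequence[str] | None = None):
        self.chromosome = chromosome
        self.positions = np.asarray(positions, dtype=np.int64)
        self.alleles = np.asarray(alleles, dtype=np.int8)
        self.hap_ids = list(hap_ids)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be 2-D (sites, haplotypes)")
        if self.alleles.shape != (len(self.positions), len(self.hap_ids)):
            raise ValueError(
                f"alleles shape {self.alleles.shape} inconsistent with "
                f"{len(self.positions)} positions x {len(self.hap_ids)} haplotypes")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        if ancestral_state is None:
            ancestral_state = np.zeros(len(self.positions), dtype=np.int8)
        self.ancestral_state = np.asarray(ancestral_state, dtype=np.int8)
        if self.ancestral_state.shape != (len(self.positions),):
            raise ValueError("ancestral_state length mismatch")
        self.ref = list(ref) if ref is not None else ["A"] * len(self.positions)
        self.alt = list(alt) if alt is not None else ["T"] * len(self.positions)
        self._hap_index = {h: i for i, h in enumerate(self.hap_ids)}

    # -- basic views ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.hap_ids:
            seen.setdefault(h.rsplit("_", 1)[0], None)
        return list(seen)

    def hap_indices(self, hap_ids: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self._hap_index[h] for h in hap_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown haplotype id {e.args[0]!r}") from None

    def site_slice(self, window: Window) -> slice:
        """Index slice of sites falling inside a half-open window."""
        lo = int(np.searchsorted(self.positions, window.start, side="left"))
        hi = int(np.searchsorted(self.positions, window.end, side="left"))
        return slice(lo, hi)

    def subset(self, window: Window | None = None,
               hap_ids: Sequence[str] | None = None) -> "HaplotypeMatrix":
        rows = self.site_slice(window) if window is not None else slice(None)
        cols = (self.hap_indices(hap_ids) if hap_ids is not None
                else np.arange(self.n_haplotypes))
        return HaplotypeMatrix(
            self.chromosome, self.positions[rows],
            self.alleles[rows][:, cols],
            [self.hap_ids[i] for i in cols],
            self.ancestral_state[rows],
            ref=self.ref[rows] if isinstance(rows, slice) else self.ref,
            alt=self.alt[rows] if isinstance(rows, slice) else self.alt,
        )

    def derived(self) -> np.ndarray:
        """Alleles recoded so 1 = derived relative to ancestral_state.

        Sites with missing ancestral state keep their 0/1 coding.
        Missing alleles stay -1.
        """
        out = self.alleles.copy()
        flip = self.ancestral_state == 1
        sub = out[flip]
        swap = sub >= 0
        sub[swap] = 1 - sub[swap]
        out[flip] = sub
        return out

    def missing_fraction(self) -> np.ndarray:
        return (self.alleles == MISSING).mean(axis=1)

    def filter_missingness(self, max_missing: float = 0.2) -> "HaplotypeMatrix":
        """Drop sites with more than ``max_missing`` missing haplotypes."""
        keep = self.missing_fraction() <= max_missing
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("missingness filter dropped %d/%d sites", n_drop, self.n_sites)
        idx = np.flatnonzero(keep)
        return HaplotypeMatrix(
            self.chromosome, self.positions[idx], self.alleles[idx],
            self.hap_ids, self.ancestral_state[idx],
            ref=[self.ref[i] for i in idx], alt=[self.alt[i] for i in idx])


def make_windows(chrom_length: int, size: int, step: int | None = None,
                 chromosome: str = "chr1") -> list[Window]:
    """Tile [0, chrom_length) with half-open windows.

    A final partial window is kept when it is at least half the nominal
    size, otherwise dropped (logged). ``step > size`` is an error: sliding
    plans must not create gaps.
    """
    if size <= 0:
        raise ValueError("window size must be positive")
    step = size if step is None else step
    if step <= 0 or step > size:
        raise ValueError("step must satisfy 0 < step <= size")
    out: list[Window] = []
    start = 0
    while start < chrom_length:
        end = min(start + size, chrom_length)
        if end - start < size and (end - start) < size / 2:
            logger.info("dropping %d bp tail window at %d", end - start, start)
            break
        out.append(Window(chromosome, start, end))
        if end == chrom_length:
            break
        start += step
    return out


def resolve_group(metadata: MetadataTable, spec: str,
                  hap_ids: Sequence[str],
                  xy_labels: dict[str, str] | None = None) -> list[str]:
    """Resolve a group expression to an ordered haplotype-id list.

    Grammar: ``species``, ``species&sex`` (e.g. ``pungitius&male``), or a
    phased-group label ``pungitius_X`` / ``pungitius_Y`` which requires
    ``xy_labels`` (haplotype id -> "X"/"Y") from the Y-phasing stage.
    Order follows ``hap_ids``. Empty results raise.
    """
    spec = spec.strip()
    valid_species = {s.value for s in Species}
    want_xy: str | None = None
    if spec.endswith(("_X", "_Y")) and spec[:-2] in valid_species:
        species, want_xy = spec[:-2], spec[-1]
        if xy_labels is None:
            raise ValueError(f"group {spec!r} requires X/Y labels from y-phasing")
        sex = None
    elif "&" in spec:
        species, sex = (t.strip() for t in spec.split("&", 1))
        if sex not in {s.value for s in Sex}:
            raise ValueError(f"unknown sex label {sex!r} in group {spec!r}")
    else:
        species, sex = spec, None
    if species not in valid_species:
        raise ValueError(f"unknown species label {species!r} in group {spec!r}")

    wanted_samples = set(metadata.select(species=species, sex=sex))
    out = []
    for h in hap_ids:
        if h.rsplit("_", 1)[0] not in wanted_samples:
            continue
        if want_xy is not None and (xy_labels or {}).get(h) != want_xy:
            continue
        out.append(h)
    if not out:
        raise ValueError(f"group expression {spec!r} matched no haplotypes")
    return out
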
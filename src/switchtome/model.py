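"""Shared genomic data model.

All coordinates are 0-based, half-open, on a single (by default circular)
chromosome.  An interval with ``start > end`` wraps across the origin of the
coordinate system; this is only legal when the chromosome is circular.  The
conversion to/from 1-based GFF3 happens exclusively in :mod:`switchtome.genome_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an on-disk input violates the data model's invariants."""


# --------------------------------------------------------------------------- #
# circular-interval arithmetic
# --------------------------------------------------------------------------- #

def interval_length(start: int, end: int, genome_length: int) -> int:
    """Length of a (possibly origin-wrapping) half-open interval."""
    if start < end:
        return end - start
    return genome_length - start + end


def interval_positions(start: int, end: int, genome_length: int) -> np.ndarray:
    """All positions covered by the interval, in 5'->3' genomic order."""
    if start < end:
        return np.arange(start, end)
    return np.concatenate([np.arange(start, genome_length), np.arange(0, end)])


def interval_slice(arr: np.ndarray, start: int, end: int) -> np.ndarray:
    """View/copy of ``arr`` over a possibly wrapping interval."""
    if start < end:
        return arr[start:end]
    return np.concatenate([arr[start:], arr[:end]])


def interval_sum(arr: np.ndarray, start: int, end: int) -> float:
    if start < end:
        return float(arr[start:end].sum())
    return float(arr[start:].sum() + arr[:end].sum())


def interval_add(arr: np.ndarray, start: int, end: int, values) -> None:
    """In-place ``arr[start:end] += values`` with origin wrapping."""
    if start < end:
        arr[start:end] += values
        return
    head = len(arr) - start
    if np.isscalar(values):
        arr[start:] += values
        arr[:end] += values
    else:
        arr[start:] += values[:head]
        arr[:end] += values[head:]


def midpoint(start: int, end: int, genome_length: int) -> int:
    return (start + interval_length(start, end, genome_length) // 2) % genome_length


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

GENE_FLAGS = frozenset({"transposon", "ribonuclease", "rRNA", "transcription_factor"})


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    start: int
    end: int
    strand: str            # '+' or '-'
    length: int            # bp, wrapped length for origin-spanning genes
    category: str = "unknown"
    region: str = ""       # 'core' or 'noncore'
    flags: frozenset = field(default_factory=frozenset)

    def has_flag(self, flag: str) -> bool:
        return flag in self.flags


@dataclass(frozen=True)
class ChromosomeModel:
    name: str
    genome_length: int
    circular: bool = True
    origin: int = 0
    terminus: int | None = None   # None -> origin + L/2 (replichore symmetry null)

    def __post_init__(self):
        if not (0 <= self.origin < self.genome_length):
            raise ValidationError(f"origin {self.origin} outside chromosome")
        term = self.terminus
        if term is None:
            object.__setattr__(
                self, "terminus",
                (self.origin + self.genome_length // 2) % self.genome_length)
        elif not (0 <= term < self.genome_length):
            raise ValidationError(f"terminus {term} outside chromosome")
        if self.terminus == self.origin:
            raise ValidationError("origin and terminus coincide")

    def replichore(self, position: int) -> int:
        """1 for positions clockwise of the origin (origin -> terminus in
        increasing coordinates, modulo wrap), else 2."""
        o, t, L = self.origin, self.terminus, self.genome_length
        d = (position - o) % L
        span1 = (t - o) % L
        return 1 if d < span1 else 2


@dataclass
class RegionPartition:
    """Core / non-core tiling of the chromosome.

    ``intervals`` tile the chromosome exactly once; ``borders`` are the
    positions where the label changes (including the wrap at the origin when
    the first and last interval differ in label).
    """
    intervals: list            # [(start, end, label)]
    genome_length: int

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv[0])
        if not ivs:
            raise ValidationError("empty region partition")
        covered = 0
        for (s, e, lab) in ivs:
            if lab not in ("core", "noncore"):
                raise ValidationError(f"unknown region label {lab!r} at ({s},{e})")
            covered += interval_length(s, e, self.genome_length)
        if covered != self.genome_length:
            raise ValidationError(
                f"region partition covers {covered} bp of {self.genome_length}; "
                "intervals must tile the chromosome exactly once")
        prev_end = ivs[0][0]
        for (s, e, lab) in ivs:
            if s != prev_end:
                raise ValidationError(
                    f"region partition gap/overlap before interval ({s},{e},{lab})")
            prev_end = e % self.genome_length if e == self.genome_length else e
        self.intervals = ivs

    @property
    def borders(self) -> list:
        ivs = self.intervals
        out = []
        n = len(ivs)
        for i, (s, e, lab) in enumerate(ivs):
            nxt = ivs[(i + 1) % n]
            if nxt[2] != lab:
                out.append(nxt[0])
        return out

    def label_at(self, position: int) -> str:
        p = position % self.genome_length
        for (s, e, lab) in self.intervals:
            if s < e:
                if s <= p < e:
                    return lab
            elif p >= s or p < e:
                return lab
        raise ValidationError(f"position {position} not covered by partition")

    def label_vector(self, bin_size: int = 1) -> np.ndarray:
        """Per-bin label array ('core'/'noncore'), bins by their start position."""
        n_bins = -(-self.genome_length // bin_size)
        starts = np.arange(n_bins) * bin_size
        lab = np.empty(n_bins, dtype=object)
        for i, s in enumerate(starts):
            lab[i] = self.label_at(int(s))
        return lab


@dataclass
class CoverageTrack:
    library_id: str
    timepoint: float
    stranded: bool
    plus: np.ndarray
    minus: np.ndarray | None = None
    bin_size: int = 1
    library_size: float = 0.0

    def __post_init__(self):
        if self.stranded and self.minus is None:
            raise ValidationError("stranded track requires a minus-strand vector")
        if self.minus is not None and len(self.minus) != len(self.plus):
            raise ValidationError("strand vectors differ in length")
        if (self.plus < 0).any() or (self.minus is not None and (self.minus < 0).any()):
            raise ValidationError("negative coverage value")
        if self.library_size <= 0:
            total = float(self.plus.sum())
            if self.minus is not None:
                total += float(self.minus.sum())
            self.library_size = total if total > 0 else 1.0

    @property
    def total(self) -> np.ndarray:
        if self.minus is None:
            return self.plus
        return self.plus + self.minus

    def strand_vector(self, strand: str) -> np.ndarray:
        if strand == "+":
            return self.plus
        if strand == "-":
            if not self.stranded:
                raise ValidationError("minus-strand requested from unstranded track")
            return self.minus
        raise ValidationError(f"unknown strand {strand!r}")


@dataclass(frozen=True)
class LibraryInfo:
    library_id: str
    timepoint: float
    kind: str = "long"         # 'long' or 'fragment'
    library_size: float = 0.0  # nominal sequencing effort used for per-million scaling


@dataclass
class CountTable:
    """Gene x library table of non-negative integer read counts."""
    counts: pd.DataFrame               # index: gene_id, columns: library_id
    libraries: list                    # [LibraryInfo] in column order

    def __post_init__(self):
        ids = [lib.library_id for lib in self.libraries]
        if list(self.counts.columns) != ids:
            raise ValidationError("library metadata order does not match columns")
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate library_id")
        if self.counts.index.has_duplicates:
            raise ValidationError("duplicate gene_id")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative count")

    @property
    def genes(self) -> list:
        return list(self.counts.index)

    def library(self, library_id: str) -> LibraryInfo:
        for lib in self.libraries:
            if lib.library_id == library_id:
                return lib
        raise KeyError(library_id)

    def column_for_timepoint(self, timepoint: float, kind: str = "long") -> str:
        for lib in self.libraries:
            if lib.timepoint == timepoint and lib.kind == kind:
                return lib.library_id
        raise KeyError(f"no {kind} library at timepoint {timepoint}")

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountTable":
        return CountTable(self.counts.loc[list(gene_ids)].copy(), list(self.libraries))
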
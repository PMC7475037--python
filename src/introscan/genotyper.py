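"""Genotype a mobile-element insertion from short aligned fragments.

The evidence model combines three signals computed against a pair of
references (with and without the insertion):

* a read-depth profile on the insertion-free reference, where the depth
  should drop symmetrically around the insertion point if the element is
  present (to ~zero if homozygous);
* counts of *junction* fragments that contain the exact 2k-mer formed by
  the k bases immediately upstream of the insertion joined to the first k
  bases of the inserted element (default k=11, so a unique 22-mer);
* counts of *spanning* fragments that cross the insertion site on the
  insertion-free reference with a minimum anchor on both sides.

Coordinates are 0-based half-open throughout. ``insertion_point`` is the
index of the first base of the insertion-free reference that follows the
insertion site.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .util import find_all, revcomp

INSERTION_GENOTYPES = ("hom_present", "het", "hom_absent")

#: sentinel call when the evidence is insufficient or contradictory
NO_CALL = "no_call"


class JunctionNotUniqueError(ValueError):
    """The junction 2k-mer is not unique in ref_with or occurs in ref_without."""

    def __init__(self, kmer: str, message: str):
        self.kmer = kmer
        super().__init__(f"{message}: {kmer!r}")


@dataclass(frozen=True)
class ReferencePair:
    """A reference sequence with and without the insertion.

    ``ref_with`` must equal ``ref_without[:insertion_point]`` + (a copy of
    the ``tsd_length`` bases immediately upstream, if any) + ``insertion_seq``
    + ``ref_without[insertion_point:]``.
    """

    ref_without: str
    ref_with: str
    insertion_point: int
    insertion_seq: str
    tsd_length: int = 0
    name_without: str = "ref_without"
    name_with: str = "ref_with"

    def __post_init__(self) -> None:
        if not 0 <= self.insertion_point <= len(self.ref_without):
            raise ValueError("insertion_point outside ref_without")
        if self.tsd_length < 0:
            raise ValueError("tsd_length must be >= 0")
        if len(self.insertion_seq) <= 22:
            raise ValueError("insertion_seq must be longer than 22 bp")
        expected = self.build_ref_with(
            self.ref_without, self.insertion_seq, self.insertion_point, self.tsd_length
        )
        if self.ref_with != expected:
            raise ValueError("ref_with inconsistent with ref_without + insertion_seq")

    @staticmethod
    def build_ref_with(
        ref_without: str, insertion_seq: str, insertion_point: int, tsd_length: int = 0
    ) -> str:
        tsd = ref_without[insertion_point - tsd_length : insertion_point] if tsd_length else ""
        return ref_without[:insertion_point] + tsd + insertion_seq + ref_without[insertion_point:]

    @classmethod
    def from_parts(
        cls,
        ref_without: str,
        insertion_seq: str,
        insertion_point: int,
        tsd_length: int = 0,
        **names,
    ) -> "ReferencePair":
        ref_with = cls.build_ref_with(ref_without, insertion_seq, insertion_point, tsd_length)
        return cls(ref_without, ref_with, insertion_point, insertion_seq, tsd_length, **names)

    @property
    def insertion_start_in_ref_with(self) -> int:
        """Index in ref_with of the first base of the inserted element."""
        return self.insertion_point + self.tsd_length


@dataclass(frozen=True)
class AlignedFragment:
    """A short fragment placed ungapped on a named reference."""

    fragment_id: str
    ref_name: str
    start: int
    end: int
    strand: str
    sequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("require 0 <= start < end")
        if self.end - self.start != len(self.sequence):
            raise ValueError("end - start must equal sequence length")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class DepthProfile:
    """Per-base fragment depth over a window on a reference."""

    window_start: int
    window_end: int
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.window_end - self.window_start != len(self.depth):
            raise ValueError("depth length must match window size")

    @property
    def total(self) -> int:
        return int(self.depth.sum())


@dataclass(frozen=True)
class InsertionEvidence:
    """Summary of insertion evidence for one individual."""

    n_junction: int
    n_spanning: int
    drop_ratio: float
    asymmetry: float
    call: str
    het_pvalue: float | None

    def to_dict(self) -> dict:
        return {
            "n_junction": self.n_junction,
            "n_spanning": self.n_spanning,
            "drop_ratio": None if math.isnan(self.drop_ratio) else self.drop_ratio,
            "asymmetry": None if math.isnan(self.asymmetry) else self.asymmetry,
            "call": self.call,
            "het_pvalue": self.het_pvalue,
        }


def depth_profile(
    fragments: Iterable[AlignedFragment], window: tuple[int, int]
) -> DepthProfile:
    """Per-base depth: depth[i] = number of fragments whose [start, end) covers i."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window rejected")
    diff = np.zeros(hi - lo + 1, dtype=np.int64)
    for frag in fragments:
        a = max(frag.start, lo)
        b = min(frag.end, hi)
        if a < b:
            diff[a - lo] += 1
            diff[b - lo] -= 1
    depth = np.cumsum(diff[:-1])
    return DepthProfile(lo, hi, depth)


def coverage_drop(
    profile: DepthProfile,
    insertion_point: int,
    inner_halfwidth_bp: int,
    flank_width_bp: int,
) -> tuple[float, float]:
    """Mean-depth drop ratio (inner / flanks) and flank asymmetry.

    Returns ``(drop_ratio, asymmetry)``; a flank mean of zero yields NaN
    (no-data) for the ratio.
    """
    if inner_halfwidth_bp <= 0 or flank_width_bp <= 0:
        raise ValueError("zero-width windows rejected")
    inner_lo = insertion_point - inner_halfwidth_bp
    inner_hi = insertion_point + inner_halfwidth_bp
    left_lo = inner_lo - flank_width_bp
    right_hi = inner_hi + flank_width_bp
    if left_lo < profile.window_start or right_hi > profile.window_end:
        raise ValueError("inner and flank windows must fit inside the profile window")

    def mean_depth(a: int, b: int) -> float:
        return float(
            profile.depth[a - profile.window_start : b - profile.window_start].mean()
        )

    inner = mean_depth(inner_lo, inner_hi)
    left = mean_depth(left_lo, inner_lo)
    right = mean_depth(inner_hi, right_hi)
    flank = 0.5 * (left + right)
    drop_ratio = inner / flank if flank > 0 else float("nan")
    asymmetry = abs(left - right) / flank if flank > 0 else float("nan")
    return drop_ratio, asymmetry


def junction_kmer(ref_pair: ReferencePair, k: int = 11) -> str:
    """The 2k-mer straddling the 5' junction of the insertion, with uniqueness checks.

    The k reference bases immediately 5' of the inserted element joined to the
    first k bases of the element. Raises :class:`JunctionNotUniqueError` if the
    2k-mer (on either strand) is not unique in ref_with or occurs in ref_without.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    start = ref_pair.insertion_start_in_ref_with
    if start < k:
        raise ValueError("not enough upstream sequence for the junction k-mer")
    if len(ref_pair.insertion_seq) < k:
        raise ValueError("insertion shorter than k")
    kmer = ref_pair.ref_with[start - k : start + k]

    def n_hits(ref: str) -> int:
        n = len(find_all(ref, kmer))
        rc = revcomp(kmer)
        if rc != kmer:
            n += len(find_all(ref, rc))
        return n

    if n_hits(ref_pair.ref_with) != 1:
        raise JunctionNotUniqueError(kmer, "junction 2k-mer is not unique in ref_with")
    if n_hits(ref_pair.ref_without) != 0:
        raise JunctionNotUniqueError(kmer, "junction 2k-mer occurs in ref_without")
    return kmer


def _fragment_sequences(fragments: Iterable) -> list[str]:
    seqs = []
    for frag in fragments:
        seqs.append(frag.sequence if hasattr(frag, "sequence") else str(frag))
    return seqs


def count_junction_fragments(
    fragments: Sequence, ref_pair: ReferencePair, k: int = 11
) -> int:
    """Count fragments containing the exact junction 2k-mer on either strand.

    Fragments shorter than 2k are skipped. Accepts raw sequences or any
    objects with a ``sequence`` attribute.
    """
    kmer = junction_kmer(ref_pair, k)
    rc = revcomp(kmer)
    n = 0
    for seq in _fragment_sequences(fragments):
        if len(seq) < 2 * k:
            continue
        if kmer in seq or rc in seq:
            n += 1
    return n


def count_spanning_fragments(
    fragments: Iterable[AlignedFragment],
    insertion_point: int,
    min_anchor_bp: int = 11,
) -> int:
    """Count fragments crossing the insertion site with >= min_anchor_bp on each side."""
    if min_anchor_bp < 1:
        raise ValueError("min_anchor_bp must be >= 1")
    n = 0
    for frag in fragments:
        if (
            frag.start <= insertion_point - min_anchor_bp
            and frag.end >= insertion_point + min_anchor_bp
        ):
            n += 1
    return n


def call_genotype(
    n_junction: int,
    n_spanning: int,
    min_support: int = 5,
    het_alpha: float = 0.05,
) -> tuple[str, float | None]:
    """Call an insertion genotype from junction/spanning fragment counts.

    Decision rule: with total = n_junction + n_spanning,

    * total < min_support -> no_call;
    * n_spanning == 0 -> hom_present;
    * n_junction == 0 -> hom_absent;
    * otherwise het, with a two-sided exact binomial test of n_junction vs
      total at 0.5 reported; the call is downgraded to no_call if the test
      rejects (p < het_alpha) AND the minority count is below min_support.
    """
    if n_junction < 0 or n_spanning < 0:
        raise ValueError("negative counts rejected")
    total = n_junction + n_spanning
    if total < min_support:
        return NO_CALL, None
    if n_spanning == 0:
        return "hom_present", None
    if n_junction == 0:
        return "hom_absent", None
    pvalue = float(stats.binomtest(n_junction, total, 0.5).pvalue)
    if pvalue < het_alpha and min(n_junction, n_spanning) < min_support:
        return NO_CALL, pvalue
    return "het", pvalue


def evaluate_insertion(
    raw_fragments: Sequence[str],
    ref_pair: ReferencePair,
    k: int = 11,
    min_anchor_bp: int = 11,
    inner_halfwidth_bp: int = 5,
    flank_width_bp: int = 500,
    min_support: int = 5,
    het_alpha: float = 0.05,
) -> InsertionEvidence:
    """End-to-end evidence for one individual from raw fragment sequences.

    Fragments are placed on the insertion-free reference by exact ungapped
    matching; spanning counts and the depth profile use those placements,
    while junction counts use the raw sequences.
    """
    from .synthetic import align_fragments  # local import to avoid a module cycle

    placements = align_fragments(raw_fragments, ref_pair.ref_without, ref_name=ref_pair.name_without)
    placed = [p.fragment for p in placements if p.fragment is not None]
    n_junction = count_junction_fragments(raw_fragments, ref_pair, k=k)
    n_spanning = count_spanning_fragments(placed, ref_pair.insertion_point, min_anchor_bp)
    lo = max(0, ref_pair.insertion_point - inner_halfwidth_bp - flank_width_bp)
    hi = min(len(ref_pair.ref_without), ref_pair.insertion_point + inner_halfwidth_bp + flank_width_bp)
    profile = depth_profile(placed, (lo, hi))
    drop_ratio, asymmetry = coverage_drop(
        profile, ref_pair.insertion_point, inner_halfwidth_bp, flank_width_bp
    )
    call, pvalue = call_genotype(n_junction, n_spanning, min_support, het_alpha)
    return InsertionEvidence(n_junction, n_spanning, drop_ratio, asymmetry, call, pvalue)
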
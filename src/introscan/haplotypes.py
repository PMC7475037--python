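"""Characterize introgressed haplotypes in a phased biallelic panel.

Provides per-population allele frequencies, pairwise r² from phased gamete
counts, lineage-private SNP detection against an outgroup, the r²-defined
extent of the introgressed segment around a focal site, and a per-site
archaic-match table comparing carrier/non-carrier haplotype classes to
archaic genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class MonomorphicSiteError(ValueError):
    """LD is undefined for a monomorphic site (not zero)."""


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotype matrix with coordinates and population labels.

    ``alleles`` is a (n_haplotypes, n_sites) matrix of {0, 1}; positions are
    strictly increasing base-pair coordinates.
    """

    positions: np.ndarray
    ref_alleles: list[str]
    alt_alleles: list[str]
    alleles: np.ndarray
    haplotype_ids: list[str]
    pop_of_haplotype: dict[str, str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        n_hap, n_sites = self.alleles.shape
        if len(self.haplotype_ids) != n_hap:
            raise ValueError("haplotype_ids length must match allele matrix rows")
        if len(self.positions) != n_sites:
            raise ValueError("positions length must match allele matrix columns")
        if len(self.ref_alleles) != n_sites or len(self.alt_alleles) != n_sites:
            raise ValueError("allele labels must match site count")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("panel must be biallelic 0/1")
        missing = [h for h in self.haplotype_ids if h not in self.pop_of_haplotype]
        if missing:
            raise ValueError(f"haplotypes without population label: {missing[:3]}")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.haplotype_ids:
            seen.setdefault(self.pop_of_haplotype[h], None)
        return list(seen)

    def haplotype_indices(self, pop: str) -> np.ndarray:
        idx = [i for i, h in enumerate(self.haplotype_ids) if self.pop_of_haplotype[h] == pop]
        return np.asarray(idx, dtype=np.intp)

    def indices_of(self, haplotype_ids: Iterable[str]) -> np.ndarray:
        lookup = {h: i for i, h in enumerate(self.haplotype_ids)}
        return np.asarray([lookup[h] for h in haplotype_ids], dtype=np.intp)

    def site_at_position(self, position_bp: int) -> int:
        hits = np.flatnonzero(self.positions == position_bp)
        if len(hits) != 1:
            raise KeyError(f"no unique site at position {position_bp}")
        return int(hits[0])


@dataclass
class ArchaicGenotypes:
    """Alt-allele dosage matrix for archaic individuals at panel sites.

    ``genotypes`` is (n_individuals, n_sites) with values {0, 1, 2} or NaN
    for missing.
    """

    individuals: list[str]
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.shape[0] != len(self.individuals):
            raise ValueError("genotype rows must match individuals")
        valid = np.isnan(self.genotypes) | np.isin(self.genotypes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or NaN")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def dosage_totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-site total dosage of the alt (1) and ref (0) alleles, ignoring missing."""
        observed = ~np.isnan(self.genotypes)
        alt = np.nansum(self.genotypes, axis=0)
        ref = 2 * observed.sum(axis=0) - alt
        return alt, ref


@dataclass(frozen=True)
class LDResult:
    """Pairwise linkage disequilibrium from phased gamete counts."""

    r2: float
    d: float
    haplotype_counts: np.ndarray  # 2x2: rows allele at A (0/1), cols allele at B

    @property
    def n(self) -> int:
        return int(self.haplotype_counts.sum())


@dataclass(frozen=True)
class IntrogressionSegment:
    """Maximal run of consecutive sites in LD above threshold with a focal site."""

    focal_site: int
    start_bp: int
    end_bp: int
    member_sites: np.ndarray
    n_private: int | None

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp


def allele_frequency(panel: HaplotypePanel, site: int) -> dict[str, float]:
    """Alt-allele frequency per population, plus "ALL" for the whole panel."""
    col = panel.alleles[:, site]
    out: dict[str, float] = {}
    for pop in panel.populations:
        idx = panel.haplotype_indices(pop)
        if len(idx) == 0:
            raise ValueError(f"empty population: {pop}")
        out[pop] = float(col[idx].mean())
    out["ALL"] = float(col.mean())
    return out


def _site_column(panel: HaplotypePanel, site) -> np.ndarray:
    """A panel site index, or an explicit 0/1 pseudo-SNP vector (e.g. insertion carrier status)."""
    if isinstance(site, (int, np.integer)):
        return panel.alleles[:, site].astype(np.int8)
    col = np.asarray(site, dtype=np.int8)
    if col.shape != (panel.n_haplotypes,):
        raise ValueError("pseudo-SNP column length must equal haplotype count")
    if not np.isin(col, (0, 1)).all():
        raise ValueError("pseudo-SNP column must be 0/1")
    return col


def ld_r2(
    panel: HaplotypePanel,
    site_a,
    site_b,
    haplotype_subset: Sequence[int] | None = None,
) -> LDResult:
    """r² and D between two sites from phased gamete counts.

    Either site may be a panel index or an explicit 0/1 vector treated as a
    presence/absence pseudo-SNP. Raises :class:`MonomorphicSiteError` if a
    site is monomorphic in the (sub)set of haplotypes.
    """
    a = _site_column(panel, site_a)
    b = _site_column(panel, site_b)
    if haplotype_subset is not None:
        idx = np.asarray(haplotype_subset, dtype=np.intp)
        a, b = a[idx], b[idx]
    n = len(a)
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    p_a = counts[1].sum() / n
    p_b = counts[:, 1].sum() / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise MonomorphicSiteError("LD undefined for a monomorphic site")
    p_ab = counts[1, 1] / n
    d = p_ab - p_a * p_b
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(r2=float(r2), d=float(d), haplotype_counts=counts)


def private_archaic_sites(
    panel: HaplotypePanel,
    outgroup_pop: str,
    archaic: ArchaicGenotypes,
    min_archaic_dosage_total: int = 1,
) -> np.ndarray:
    """Sites where an archaic-carried allele is entirely absent from the outgroup.

    An allele counts as archaic-carried when its total dosage across
    individuals (missing ignored) is >= ``min_archaic_dosage_total``.
    """
    if outgroup_pop not in panel.populations:
        raise ValueError(f"outgroup population not in panel: {outgroup_pop}")
    if archaic.n_sites != panel.n_sites:
        raise ValueError("archaic genotypes must cover panel sites")
    out_idx = panel.haplotype_indices(outgroup_pop)
    out_freq_alt = panel.alleles[out_idx].mean(axis=0)
    alt_dose, ref_dose = archaic.dosage_totals()
    private_alt = (alt_dose >= min_archaic_dosage_total) & (out_freq_alt == 0.0)
    private_ref = (ref_dose >= min_archaic_dosage_total) & (out_freq_alt == 1.0)
    return np.flatnonzero(private_alt | private_ref)


def introgression_segment(
    panel: HaplotypePanel,
    focal_site: int,
    r2_threshold: float = 0.8,
    private_sites: Sequence[int] | None = None,
) -> IntrogressionSegment:
    """Maximal consecutive-site run around the focal site with r² above threshold.

    Extension in each direction stops at the first site whose r² with the
    focal site fails the threshold (monomorphic sites, where LD is
    undefined, also terminate extension). The focal site is always a member.
    """
    focal_col = panel.alleles[:, focal_site]
    if focal_col.min() == focal_col.max():
        raise MonomorphicSiteError("focal site is monomorphic")

    def passes(site: int) -> bool:
        try:
            return ld_r2(panel, site, focal_site).r2 > r2_threshold
        except MonomorphicSiteError:
            return False

    lo = focal_site
    while lo - 1 >= 0 and passes(lo - 1):
        lo -= 1
    hi = focal_site
    while hi + 1 < panel.n_sites and passes(hi + 1):
        hi += 1
    members = np.arange(lo, hi + 1)
    n_private = None
    if private_sites is not None:
        priv = np.asarray(private_sites)
        n_private = int(np.isin(priv, members).sum())
    return IntrogressionSegment(
        focal_site=focal_site,
        start_bp=int(panel.positions[lo]),
        end_bp=int(panel.positions[hi]),
        member_sites=members,
        n_private=n_private,
    )


def archaic_match_matrix(
    panel: HaplotypePanel,
    carrier_subset: Sequence,
    noncarrier_subset: Sequence,
    outgroup_pop: str,
    archaic: ArchaicGenotypes,
    min_archaic_count: int = 3,
) -> pd.DataFrame:
    """Long-format per-site match table against the archaic-carried allele.

    Site selection: sites where an allele that is minor (< 0.5) or absent in
    the outgroup has total archaic dosage >= ``min_archaic_count``. For each
    selected site and each haplotype subset, status is "match" if the
    subset's major allele equals the archaic allele, "mismatch" otherwise,
    and "tie" when the subset frequency is exactly 0.5.
    """
    if len(carrier_subset) == 0 or len(noncarrier_subset) == 0:
        raise ValueError("subsets must be non-empty")
    subsets = {
        "carrier": _as_indices(panel, carrier_subset),
        "noncarrier": _as_indices(panel, noncarrier_subset),
    }
    out_idx = panel.haplotype_indices(outgroup_pop)
    out_freq_alt = panel.alleles[out_idx].mean(axis=0)
    alt_dose, ref_dose = archaic.dosage_totals()

    rows = []
    for site in range(panel.n_sites):
        if out_freq_alt[site] < 0.5:
            candidate, dose = 1, alt_dose[site]
        elif out_freq_alt[site] > 0.5:
            candidate, dose = 0, ref_dose[site]
        else:
            continue  # no minor allele in the outgroup at an exact tie
        if dose < min_archaic_count:
            continue
        for label, idx in subsets.items():
            freq_alt = float(panel.alleles[idx, site].mean())
            freq_candidate = freq_alt if candidate == 1 else 1 - freq_alt
            if freq_candidate == 0.5:
                status = "tie"
            elif freq_candidate > 0.5:
                status = "match"
            else:
                status = "mismatch"
            rows.append(
                {
                    "site": site,
                    "position_bp": int(panel.positions[site]),
                    "archaic_allele": candidate,
                    "archaic_dosage": float(dose),
                    "subset": label,
                    "subset_archaic_allele_freq": freq_candidate,
                    "status": status,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "site",
            "position_bp",
            "archaic_allele",
            "archaic_dosage",
            "subset",
            "subset_archaic_allele_freq",
            "status",
        ],
    )


def _as_indices(panel: HaplotypePanel, subset: Sequence) -> np.ndarray:
    subset = list(subset)
    if subset and isinstance(subset[0], str):
        return panel.indices_of(subset)
    return np.asarray(subset, dtype=np.intp)
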
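"""Synthetic inputs for the whole pipeline, with recorded ground truth.

A copying model generates a phased panel: every haplotype starts from a
shared ancestral background, population-private rare mutations are overlaid
at a Poisson rate per kb, and an archaic segment with hard boundaries is
pasted onto designated carrier haplotypes. All sites inside the segment
bounds are private archaic SNPs (allele 1 exactly on the carriers, absent
from every outgroup haplotype and homozygous in the archaic individuals).
Carriers split into two archaic sub-haplotypes, one carrying the mobile
element insertion and one without it.

Fragment simulation draws short reads uniformly from the two donor
chromosomes implied by an insertion genotype, with truncated-normal
lengths, optional terminal deamination and uniform sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .genotyper import INSERTION_GENOTYPES, AlignedFragment, ReferencePair
from .haplotypes import ArchaicGenotypes, HaplotypePanel
from .util import DNA_ALPHABET, find_all, random_dna, revcomp

DEFAULT_ARCHAIC_GENOTYPES = {
    "archaic1": "hom_present",
    "archaic2": "het",
    "archaic3": "hom_absent",
}


@dataclass(frozen=True)
class SimPanelConfig:
    """Configuration for the synthetic haplotype panel."""

    n_haplotypes_per_pop: int
    pop_labels: tuple[str, ...]
    outgroup_pop: str
    n_sites: int
    region_length_bp: int
    introgressed_freq_per_pop: Mapping[str, float]
    n_private_archaic_snps: int
    segment_bounds_bp: tuple[int, int]
    alu_subhaplotype_fraction: float
    mutation_density: float = 0.5  # expected population-private SNPs per kb
    endpoint_jitter_bp: int = 0
    archaic_individuals: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ARCHAIC_GENOTYPES)
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.pop_labels:
            raise ValueError("population list must be non-empty")
        if self.outgroup_pop not in self.pop_labels:
            raise ValueError("outgroup_pop must be one of pop_labels")
        if self.n_haplotypes_per_pop <= 0:
            raise ValueError("n_haplotypes_per_pop must be positive")
        if self.n_sites < self.n_private_archaic_snps:
            raise ValueError("n_sites must be >= n_private_archaic_snps")
        if self.n_private_archaic_snps < 0:
            raise ValueError("n_private_archaic_snps must be >= 0")
        lo, hi = self.segment_bounds_bp
        if not 0 <= lo < hi <= self.region_length_bp:
            raise ValueError("segment_bounds must be a half-open interval inside the region")
        for pop, freq in self.introgressed_freq_per_pop.items():
            if pop not in self.pop_labels:
                raise ValueError(f"unknown population in introgressed_freq_per_pop: {pop}")
            if not 0.0 <= freq <= 1.0:
                raise ValueError("introgressed frequencies must be in [0, 1]")
        if self.introgressed_freq_per_pop.get(self.outgroup_pop, 0.0) != 0.0:
            raise ValueError("outgroup introgressed frequency must be 0")
        if not 0.0 <= self.alu_subhaplotype_fraction <= 1.0:
            raise ValueError("alu_subhaplotype_fraction must be in [0, 1]")
        if self.mutation_density < 0:
            raise ValueError("mutation_density must be >= 0")
        for name, gt in self.archaic_individuals.items():
            if gt not in INSERTION_GENOTYPES:
                raise ValueError(f"bad insertion genotype for {name}: {gt}")


@dataclass(frozen=True)
class SimFragmentConfig:
    """Configuration for the ancient-fragment simulator."""

    target_coverage: float
    fragment_length_mean_bp: float = 55.0
    fragment_length_sd_bp: float = 15.0
    fragment_length_min_bp: int = 30
    deamination_rate: float = 0.0
    sequencing_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be positive")
        if self.fragment_length_mean_bp < self.fragment_length_min_bp:
            raise ValueError("mean fragment length must be >= minimum length")
        if self.fragment_length_sd_bp <= 0:
            raise ValueError("fragment_length_sd_bp must be positive")
        # junction detection needs the full 22-mer to fit inside a fragment
        if self.fragment_length_min_bp < 22:
            raise ValueError("fragment_length_min_bp must be >= 22 (junction 2k-mer)")
        for rate in (self.deamination_rate, self.sequencing_error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass
class GroundTruth:
    """Every planted feature of a simulated dataset."""

    segment_bounds_bp: tuple[int, int] | None = None
    introgressed_haplotype_ids: set[str] = field(default_factory=set)
    alu_carrier_haplotype_ids: set[str] = field(default_factory=set)
    archaic_insertion_genotypes: dict[str, str] = field(default_factory=dict)
    private_site_indices: set[int] = field(default_factory=set)
    seed: int | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["introgressed_haplotype_ids"] = sorted(self.introgressed_haplotype_ids)
        d["alu_carrier_haplotype_ids"] = sorted(self.alu_carrier_haplotype_ids)
        d["private_site_indices"] = sorted(int(i) for i in self.private_site_indices)
        if self.segment_bounds_bp is not None:
            d["segment_bounds_bp"] = list(self.segment_bounds_bp)
        return d


@dataclass(frozen=True)
class Placement:
    """Outcome of placing one raw fragment on a reference."""

    fragment_id: str
    fragment: AlignedFragment | None
    reason: str  # "placed", "no_match" or "ambiguous"


def simulate_panel(
    config: SimPanelConfig,
) -> tuple[HaplotypePanel, ArchaicGenotypes, GroundTruth]:
    """Simulate a phased panel, archaic diploid genotypes and ground truth.

    Exactly ``n_private_archaic_snps`` site positions fall inside the
    segment bounds; carriers of the archaic segment (and both archaic
    sub-haplotypes) hold allele 1 there, everyone else allele 0. Background
    sites outside the segment are a mix of shared polymorphisms (kept
    polymorphic within the outgroup, so no background site can masquerade
    as archaic-private) and population-private rare variants at which the
    archaic individuals are homozygous ancestral.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    seg_lo, seg_hi = config.segment_bounds_bp
    n_private = config.n_private_archaic_snps
    n_background = config.n_sites - n_private
    if seg_hi - seg_lo < n_private:
        raise ValueError("segment too short to hold the requested private SNPs")

    inside = rng.choice(np.arange(seg_lo, seg_hi), size=n_private, replace=False)
    outside_pool = np.concatenate(
        [np.arange(0, seg_lo), np.arange(seg_hi, config.region_length_bp)]
    )
    if len(outside_pool) < n_background:
        raise ValueError("region too short for the requested background sites")
    outside = rng.choice(outside_pool, size=n_background, replace=False)
    positions = np.sort(np.concatenate([inside, outside]))
    private_idx = np.flatnonzero((positions >= seg_lo) & (positions < seg_hi))
    background_idx = np.setdiff1d(np.arange(config.n_sites), private_idx)

    haplotype_ids: list[str] = []
    pop_of_haplotype: dict[str, str] = {}
    for pop in config.pop_labels:
        for i in range(config.n_haplotypes_per_pop):
            hid = f"{pop}_h{i}"
            haplotype_ids.append(hid)
            pop_of_haplotype[hid] = pop
    n_hap = len(haplotype_ids)

    introgressed = np.zeros(n_hap, dtype=bool)
    for pop in config.pop_labels:
        freq = config.introgressed_freq_per_pop.get(pop, 0.0)
        idx = [i for i, h in enumerate(haplotype_ids) if pop_of_haplotype[h] == pop]
        introgressed[idx] = rng.random(len(idx)) < freq
    alu_carrier = introgressed & (rng.random(n_hap) < config.alu_subhaplotype_fraction)

    alleles = np.zeros((n_hap, config.n_sites), dtype=np.int8)

    # archaic segment with hard boundaries (optional per-haplotype erosion)
    carrier_rows = np.flatnonzero(introgressed)
    for row in carrier_rows:
        lo, hi = seg_lo, seg_hi
        if config.endpoint_jitter_bp > 0:
            lo += int(rng.integers(0, config.endpoint_jitter_bp + 1))
            hi -= int(rng.integers(0, config.endpoint_jitter_bp + 1))
        covered = (positions >= lo) & (positions < hi)
        alleles[row, private_idx[covered[private_idx]]] = 1

    outgroup_rows = np.asarray(
        [i for i, h in enumerate(haplotype_ids) if pop_of_haplotype[h] == config.outgroup_pop]
    )

    n_pop_private = min(
        len(background_idx),
        int(rng.poisson(config.mutation_density * config.region_length_bp / 1000.0)),
    )
    pop_private_sites = set(
        rng.choice(background_idx, size=n_pop_private, replace=False).tolist()
        if n_pop_private
        else []
    )

    archaic_names = list(config.archaic_individuals)
    archaic = np.zeros((len(archaic_names), config.n_sites), dtype=float)
    archaic[:, private_idx] = 2.0  # both archaic sub-haplotypes carry the segment

    for site in background_idx:
        if site in pop_private_sites:
            pop = config.pop_labels[rng.integers(0, len(config.pop_labels))]
            idx = np.asarray(
                [i for i, h in enumerate(haplotype_ids) if pop_of_haplotype[h] == pop]
            )
            freq = rng.uniform(0.05, 0.3)
            alleles[idx, site] = (rng.random(len(idx)) < freq).astype(np.int8)
            # mutation arose within a modern population: archaics stay ancestral
        else:
            freq = rng.uniform(0.1, 0.9)
            col = (rng.random(n_hap) < freq).astype(np.int8)
            # keep the outgroup polymorphic so the site cannot look archaic-private
            out_col = col[outgroup_rows]
            if out_col.min() == out_col.max():
                flip = outgroup_rows[rng.integers(0, len(outgroup_rows))]
                col[flip] = 1 - col[flip]
            alleles[:, site] = col
            archaic[:, site] = rng.binomial(2, freq, size=len(archaic_names)).astype(float)

    panel = HaplotypePanel(
        positions=positions,
        ref_alleles=["A"] * config.n_sites,
        alt_alleles=["G"] * config.n_sites,
        alleles=alleles,
        haplotype_ids=haplotype_ids,
        pop_of_haplotype=pop_of_haplotype,
    )
    archaic_genotypes = ArchaicGenotypes(individuals=archaic_names, genotypes=archaic)
    truth = GroundTruth(
        segment_bounds_bp=(seg_lo, seg_hi),
        introgressed_haplotype_ids={haplotype_ids[i] for i in carrier_rows},
        alu_carrier_haplotype_ids={haplotype_ids[i] for i in np.flatnonzero(alu_carrier)},
        archaic_insertion_genotypes=dict(config.archaic_individuals),
        private_site_indices=set(int(i) for i in private_idx),
        seed=config.seed,
    )
    return panel, archaic_genotypes, truth


def simulate_reference_pair(
    region_length_bp: int,
    insertion_point: int,
    insertion_length_bp: int = 300,
    tsd_length: int = 0,
    seed: int = 0,
    avoid_junction_microhomology: bool = True,
) -> ReferencePair:
    """Random reference pair with a planted mobile-element insertion.

    By default the terminal insertion bases are forced to differ from the
    flanking reference continuation, so no read can overhang a junction by a
    chance-matching base and still align to the insertion-free reference.
    """
    if insertion_length_bp <= 22:
        raise ValueError("insertion must be longer than 22 bp")
    rng = np.random.default_rng(seed)
    ref_without = random_dna(rng, region_length_bp)
    insertion = list(random_dna(rng, insertion_length_bp))
    if avoid_junction_microhomology:
        p = insertion_point
        if p < len(ref_without) and insertion[0] == ref_without[p]:
            insertion[0] = DNA_ALPHABET[(DNA_ALPHABET.index(insertion[0]) + 1) % 4]
        if p > 0 and insertion[-1] == ref_without[p - 1]:
            insertion[-1] = DNA_ALPHABET[(DNA_ALPHABET.index(insertion[-1]) + 1) % 4]
    return ReferencePair.from_parts(ref_without, "".join(insertion), insertion_point, tsd_length)


def _donor_chromosomes(ref_pair: ReferencePair, genotype: str) -> list[tuple[str, str]]:
    with_ = (ref_pair.name_with, ref_pair.ref_with)
    without = (ref_pair.name_without, ref_pair.ref_without)
    if genotype == "hom_present":
        return [with_, with_]
    if genotype == "het":
        return [with_, without]
    if genotype == "hom_absent":
        return [without, without]
    raise ValueError(f"genotype must be one of {INSERTION_GENOTYPES}, got {genotype!r}")


def _apply_noise(seq: str, config: SimFragmentConfig, rng: np.random.Generator) -> str:
    if config.deamination_rate == 0 and config.sequencing_error_rate == 0:
        return seq
    bases = list(seq)
    if config.deamination_rate > 0:
        for i in range(min(3, len(bases))):
            if bases[i] == "C" and rng.random() < config.deamination_rate:
                bases[i] = "T"
        for i in range(max(0, len(bases) - 3), len(bases)):
            if bases[i] == "G" and rng.random() < config.deamination_rate:
                bases[i] = "A"
    if config.sequencing_error_rate > 0:
        for i in range(len(bases)):
            if rng.random() < config.sequencing_error_rate:
                alternatives = [b for b in DNA_ALPHABET if b != bases[i]]
                bases[i] = alternatives[rng.integers(0, 3)]
    return "".join(bases)


def simulate_ancient_fragments(
    ref_pair: ReferencePair,
    genotype: str,
    config: SimFragmentConfig,
) -> tuple[list[AlignedFragment], GroundTruth]:
    """Draw short fragments uniformly from the two donor chromosomes.

    Fragment coordinates are reported against the donor chromosome each
    fragment was drawn from (``ref_name`` distinguishes the two). Lengths
    follow a truncated normal with the configured minimum enforced by
    resampling. Deterministic under the config seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    donors = _donor_chromosomes(ref_pair, genotype)
    mean_len = config.fragment_length_mean_bp
    mean_donor_len = sum(len(s) for _, s in donors) / 2
    n_fragments = int(round(config.target_coverage * mean_donor_len / mean_len))

    fragments: list[AlignedFragment] = []
    for i in range(n_fragments):
        name, donor = donors[int(rng.integers(0, 2))]
        while True:
            length = int(round(rng.normal(mean_len, config.fragment_length_sd_bp)))
            if config.fragment_length_min_bp <= length <= len(donor):
                break
        start = int(rng.integers(0, len(donor) - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = donor[start : start + length]
        if strand == "-":
            seq = revcomp(seq)
        seq = _apply_noise(seq, config, rng)
        fragments.append(
            AlignedFragment(
                fragment_id=f"frag{i:06d}",
                ref_name=name,
                start=start,
                end=start + length,
                strand=strand,
                sequence=seq,
            )
        )
    truth = GroundTruth(
        archaic_insertion_genotypes={"individual": genotype},
        seed=config.seed,
    )
    return fragments, truth


def align_fragments(
    fragments: Sequence,
    reference: str,
    ref_name: str = "reference",
) -> list[Placement]:
    """Place raw fragment sequences on a reference by exact ungapped matching.

    Both strands are searched; a fragment with no exact match, or with more
    than one match position across strands, is returned unplaced with a
    reason code ("no_match" / "ambiguous").
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    results: list[Placement] = []
    for i, frag in enumerate(fragments):
        if hasattr(frag, "sequence"):
            fid, seq = frag.fragment_id, frag.sequence
        else:
            fid, seq = f"frag{i:06d}", str(frag)
        hits = [(pos, "+") for pos in find_all(reference, seq)]
        rc = revcomp(seq)
        if rc != seq:
            hits += [(pos, "-") for pos in find_all(reference, rc)]
        if not hits:
            results.append(Placement(fid, None, "no_match"))
        elif len(hits) > 1:
            results.append(Placement(fid, None, "ambiguous"))
        else:
            pos, strand = hits[0]
            placed = AlignedFragment(
                fragment_id=fid,
                ref_name=ref_name,
                start=pos,
                end=pos + len(seq),
                strand=strand,
                sequence=seq,
            )
            results.append(Placement(fid, placed, "placed"))
    return results
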
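"""Readers and writers for the plain-text interchange formats.

Panels travel as minimal VCF (phased GT, consecutive haplotype pairs per
sample) plus a sample->population TSV; references and fragments as FASTA;
fragment placements as a TSV with 0-based half-open coordinates; archaic
genotypes as a dosage TSV; ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genotyper import AlignedFragment
from .haplotypes import ArchaicGenotypes, HaplotypePanel
from .synthetic import GroundTruth

PLACEMENT_COLUMNS = ["fragment_id", "ref_name", "start", "end", "strand"]


# ---------------------------------------------------------------- FASTA

def write_fasta(path, records: dict[str, str]) -> None:
    seq_records = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------- fragments

def write_fragments(fasta_path, tsv_path, fragments: Sequence[AlignedFragment]) -> None:
    records = [
        SeqRecord(
            Seq(f.sequence),
            id=f.fragment_id,
            description=f"{f.ref_name}:{f.start}-{f.end}({f.strand})",
        )
        for f in fragments
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    table = pd.DataFrame(
        [[f.fragment_id, f.ref_name, f.start, f.end, f.strand] for f in fragments],
        columns=PLACEMENT_COLUMNS,
    )
    table.to_csv(tsv_path, sep="\t", index=False)


def read_fragments(fasta_path, tsv_path) -> list[AlignedFragment]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    table = pd.read_csv(tsv_path, sep="\t")
    fragments = []
    for row in table.itertuples(index=False):
        fragments.append(
            AlignedFragment(
                fragment_id=row.fragment_id,
                ref_name=row.ref_name,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                sequence=seqs[row.fragment_id],
            )
        )
    return fragments


def read_fragment_sequences(fasta_path) -> list[str]:
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")]


# ------------------------------------------------------------------ VCF

def write_panel_vcf(vcf_path, popmap_path, panel: HaplotypePanel, chrom: str = "chrSIM") -> None:
    """Write the panel as a minimal phased VCF plus a sample->population map.

    Haplotypes are paired in panel order into diploid samples; each sample's
    two haplotypes must come from the same population.
    """
    if panel.n_haplotypes % 2 != 0:
        raise ValueError("VCF output needs an even number of haplotypes")
    samples = []
    for i in range(0, panel.n_haplotypes, 2):
        h0, h1 = panel.haplotype_ids[i], panel.haplotype_ids[i + 1]
        if panel.pop_of_haplotype[h0] != panel.pop_of_haplotype[h1]:
            raise ValueError("haplotype pairs must share a population")
        samples.append((f"sample{i // 2}", panel.pop_of_haplotype[h0], i))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(name for name, _, _ in samples)
            + "\n"
        )
        for s in range(panel.n_sites):
            gts = "\t".join(
                f"{panel.alleles[i, s]}|{panel.alleles[i + 1, s]}" for _, _, i in samples
            )
            fh.write(
                f"{chrom}\t{panel.positions[s] + 1}\tsite{s}\t"
                f"{panel.ref_alleles[s]}\t{panel.alt_alleles[s]}\t.\t.\t.\tGT\t{gts}\n"
            )
    popmap = pd.DataFrame(
        [(name, pop) for name, pop, _ in samples], columns=["sample_id", "population"]
    )
    popmap.to_csv(popmap_path, sep="\t", index=False)


def read_panel_vcf(vcf_path, popmap_path) -> HaplotypePanel:
    from cyvcf2 import VCF

    popmap = pd.read_csv(popmap_path, sep="\t").set_index("sample_id")["population"]
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    positions, refs, alts, columns = [], [], [], []
    for variant in vcf:
        positions.append(variant.POS - 1)  # back to 0-based
        refs.append(variant.REF)
        alts.append(variant.ALT[0])
        col = []
        for gt in variant.genotypes:
            col.extend(gt[:2])
        columns.append(col)
    vcf.close()
    alleles = np.asarray(columns, dtype=np.int8).T
    haplotype_ids, pop_of = [], {}
    for sample in samples:
        for k in (0, 1):
            hid = f"{sample}|{k}"
            haplotype_ids.append(hid)
            pop_of[hid] = str(popmap[sample])
    return HaplotypePanel(
        positions=np.asarray(positions),
        ref_alleles=refs,
        alt_alleles=alts,
        alleles=alleles,
        haplotype_ids=haplotype_ids,
        pop_of_haplotype=pop_of,
    )


# -------------------------------------------------------------- archaic

def write_archaic_tsv(path, archaic: ArchaicGenotypes, positions: Iterable[int]) -> None:
    df = pd.DataFrame(
        archaic.genotypes.T, columns=archaic.individuals, index=list(positions)
    )
    df.index.name = "position_bp"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_archaic_tsv(path) -> tuple[ArchaicGenotypes, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col="position_bp", na_values="NA")
    archaic = ArchaicGenotypes(
        individuals=[str(c) for c in df.columns],
        genotypes=df.to_numpy(dtype=float).T,
    )
    return archaic, df.index.to_numpy(dtype=np.int64)


# ---------------------------------------------------------------- truth

def write_ground_truth(path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    d = json.loads(Path(path).read_text())
    return GroundTruth(
        segment_bounds_bp=tuple(d["segment_bounds_bp"]) if d.get("segment_bounds_bp") else None,
        introgressed_haplotype_ids=set(d.get("introgressed_haplotype_ids", [])),
        alu_carrier_haplotype_ids=set(d.get("alu_carrier_haplotype_ids", [])),
        archaic_insertion_genotypes=dict(d.get("archaic_insertion_genotypes", {})),
        private_site_indices=set(d.get("private_site_indices", [])),
        seed=d.get("seed"),
    )
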
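"""End-to-end synthetic study: simulate, genotype, characterize, test, adjust.

``run_pipeline`` executes the stages in dependency order, records a
per-stage status, and returns a JSON-serializable report. Timings are kept
under a separate ``timing`` key so the report payload itself is
deterministic under a fixed config.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import adjust_table
from .genotyper import evaluate_insertion
from .haplotypes import (
    allele_frequency,
    archaic_match_matrix,
    introgression_segment,
    ld_r2,
    private_archaic_sites,
)
from .ils import ILSParams, expected_tract_length, ils_probability
from .synthetic import (
    SimFragmentConfig,
    SimPanelConfig,
    simulate_ancient_fragments,
    simulate_panel,
    simulate_reference_pair,
)

logger = logging.getLogger("introscan.pipeline")

REPORT_SCHEMA_VERSION = 1


def demo_config(seed: int = 0) -> dict:
    """A fixed small synthetic study that runs in seconds."""
    return {
        "seed": seed,
        "panel": {
            "n_haplotypes_per_pop": 50,
            "pop_labels": ["YRI-like", "EUR-like", "EAS-like", "AMR-like"],
            "outgroup_pop": "YRI-like",
            "n_sites": 140,
            "region_length_bp": 80_000,
            "introgressed_freq_per_pop": {
                "YRI-like": 0.0,
                "EUR-like": 0.18,
                "EAS-like": 0.12,
                "AMR-like": 0.15,
            },
            "n_private_archaic_snps": 28,
            "segment_bounds_bp": [20_000, 60_000],
            "alu_subhaplotype_fraction": 0.7,
            "mutation_density": 0.3,
        },
        "reference": {
            "region_length_bp": 4_000,
            "insertion_point": 2_000,
            "insertion_length_bp": 300,
            "tsd_length": 0,
        },
        "fragments": {
            "target_coverage": 30.0,
            "fragment_length_mean_bp": 55.0,
            "fragment_length_sd_bp": 15.0,
            "fragment_length_min_bp": 30,
        },
        "genotyper": {
            "k": 11,
            "min_anchor_bp": 11,
            "inner_halfwidth_bp": 5,
            "flank_width_bp": 500,
            "min_support": 5,
            "het_alpha": 0.05,
        },
        "haplotype": {"r2_threshold": 0.8, "min_archaic_count": 3},
        "ils": {
            "m_bp": 56_200,
            "r_cM_per_Mb": 0.87,
            "gen_time_years": 25,
            "t_modern_years": 200_000,
            "t_archaic_years": 100_000,
        },
        "assoc": {
            "method": "bonferroni",
            "family_column": "group",
            "rows": _demo_assoc_rows(),
        },
    }


def _demo_assoc_rows() -> list[dict]:
    """A 22-diagnosis family with one nominally significant association."""
    rows = [{"phenotype_id": "DX01", "group": "pregnancy", "p": 0.002}]
    # remaining 21 family members, deterministic non-significant spread
    for i in range(2, 23):
        rows.append(
            {"phenotype_id": f"DX{i:02d}", "group": "pregnancy", "p": round(0.04 * i, 3)}
        )
    return rows


def _stage(report: dict, timing: dict, name: str):
    """Context manager recording stage status, errors and wall time."""

    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timing[name] = time.perf_counter() - self.t0
            if exc is None:
                report["stages"][name]["status"] = "ok"
                logger.info("stage %s: ok (%.2fs)", name, timing[name])
            else:
                report["stages"][name]["status"] = "failed"
                report["stages"][name]["error"] = f"{exc_type.__name__}: {exc}"
                logger.error("stage %s: failed: %s", name, exc)
            return exc is not None  # swallow; status carries the failure

    report["stages"].setdefault(name, {})
    return _Ctx()


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic study and return the structured report."""
    seed = int(config.get("seed", 0))
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "version": __version__,
        "config": config,
        "stages": {},
    }
    timing: dict = {}

    panel = archaic = truth = ref_pair = None
    fragment_sets: dict[str, list] = {}

    with _stage(report, timing, "simulate"):
        panel_cfg = SimPanelConfig(seed=seed, **_tupled(config["panel"]))
        panel, archaic, truth = simulate_panel(panel_cfg)
        ref_cfg = config["reference"]
        ref_pair = simulate_reference_pair(seed=seed, **ref_cfg)
        for i, (name, genotype) in enumerate(truth.archaic_insertion_genotypes.items()):
            frag_cfg = SimFragmentConfig(seed=seed + 1000 + i, **config["fragments"])
            fragments, _ = simulate_ancient_fragments(ref_pair, genotype, frag_cfg)
            fragment_sets[name] = fragments
        report["stages"]["simulate"].update(
            {
                "n_haplotypes": panel.n_haplotypes,
                "n_sites": panel.n_sites,
                "n_introgressed": len(truth.introgressed_haplotype_ids),
                "n_alu_carriers": len(truth.alu_carrier_haplotype_ids),
                "fragments_per_individual": {k: len(v) for k, v in fragment_sets.items()},
            }
        )

    with _stage(report, timing, "genotype_insertion"):
        calls = {}
        for name, fragments in fragment_sets.items():
            evidence = evaluate_insertion(
                [f.sequence for f in fragments], ref_pair, **config["genotyper"]
            )
            calls[name] = evidence.to_dict()
            calls[name]["truth"] = truth.archaic_insertion_genotypes[name]
            calls[name]["correct"] = calls[name]["call"] == calls[name]["truth"]
        report["stages"]["genotype_insertion"]["calls"] = calls

    with _stage(report, timing, "haplotype"):
        hap_cfg = config["haplotype"]
        private = private_archaic_sites(panel, panel_cfg.outgroup_pop, archaic)
        focal = int(private[len(private) // 2])
        segment = introgression_segment(
            panel, focal, r2_threshold=hap_cfg["r2_threshold"], private_sites=private
        )
        alu_column = np.asarray(
            [1 if h in truth.alu_carrier_haplotype_ids else 0 for h in panel.haplotype_ids],
            dtype=np.int8,
        )
        ld = ld_r2(panel, focal, alu_column)
        carriers = sorted(truth.alu_carrier_haplotype_ids)
        noncarriers = sorted(truth.introgressed_haplotype_ids - truth.alu_carrier_haplotype_ids)
        matrix = archaic_match_matrix(
            panel, carriers, noncarriers, panel_cfg.outgroup_pop, archaic,
            min_archaic_count=hap_cfg["min_archaic_count"],
        )
        report["stages"]["haplotype"].update(
            {
                "focal_site": focal,
                "focal_position_bp": int(panel.positions[focal]),
                "focal_allele_frequency": allele_frequency(panel, focal),
                "r2_focal_vs_insertion": ld.r2,
                "segment": {
                    "start_bp": segment.start_bp,
                    "end_bp": segment.end_bp,
                    "length_bp": segment.length_bp,
                    "n_member_sites": int(len(segment.member_sites)),
                    "n_private": segment.n_private,
                },
                "n_private_sites": int(len(private)),
                "n_matrix_sites": int(matrix["site"].nunique()) if len(matrix) else 0,
                "truth_vs_inferred": {
                    "segment_bounds_truth": list(truth.segment_bounds_bp),
                    "private_sites_recovered": sorted(map(int, private))
                    == sorted(truth.private_site_indices),
                },
            }
        )
        report["stages"]["haplotype"]["_match_matrix"] = matrix

    with _stage(report, timing, "ils"):
        params = ILSParams(**config["ils"])
        report["stages"]["ils"].update(
            {
                "expected_tract_length_bp": expected_tract_length(params),
                "probability": ils_probability(params),
            }
        )

    with _stage(report, timing, "assoc"):
        assoc_cfg = config["assoc"]
        if "table_path" in assoc_cfg:
            table = pd.read_csv(assoc_cfg["table_path"], sep="\t")
        else:
            table = pd.DataFrame(assoc_cfg["rows"])
        adjusted = adjust_table(
            table,
            family_column=assoc_cfg.get("family_column", "group"),
            method=assoc_cfg.get("method", "bonferroni"),
        )
        report["stages"]["assoc"]["table"] = adjusted.where(pd.notna(adjusted), None).to_dict(
            "records"
        )

    # extract the non-serializable table before finalizing the payload
    matrix = report["stages"].get("haplotype", {}).pop("_match_matrix", None)
    report["timing"] = timing

    if outdir is not None and panel is not None:
        _write_outputs(Path(outdir), report, panel, archaic, truth, ref_pair, fragment_sets, matrix)
    return report


def _tupled(panel_cfg: dict) -> dict:
    cfg = dict(panel_cfg)
    cfg["pop_labels"] = tuple(cfg["pop_labels"])
    cfg["segment_bounds_bp"] = tuple(cfg["segment_bounds_bp"])
    return cfg


def _write_outputs(outdir, report, panel, archaic, truth, ref_pair, fragment_sets, matrix):
    from . import io as iomod

    outdir.mkdir(parents=True, exist_ok=True)
    iomod.write_panel_vcf(outdir / "panel.vcf", outdir / "populations.tsv", panel)
    iomod.write_archaic_tsv(outdir / "archaic.tsv", archaic, panel.positions)
    iomod.write_ground_truth(outdir / "truth.json", truth)
    iomod.write_fasta(
        outdir / "references.fa",
        {ref_pair.name_without: ref_pair.ref_without, ref_pair.name_with: ref_pair.ref_with},
    )
    for name, fragments in fragment_sets.items():
        iomod.write_fragments(
            outdir / f"fragments_{name}.fa", outdir / f"fragments_{name}.tsv", fragments
        )
    if matrix is not None:
        matrix.to_csv(outdir / "match_matrix.tsv", sep="\t", index=False)
    payload = {k: v for k, v in report.items() if k != "timing"}
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    calls = report["stages"].get("genotype_insertion", {}).get("calls", {})
    if calls:
        rows = [{"individual": k, **v} for k, v in calls.items()]
        pd.DataFrame(rows).to_csv(outdir / "insertion_calls.tsv", sep="\t", index=False)


def pipeline_failed(report: dict) -> bool:
    return any(s.get("status") != "ok" for s in report["stages"].values())
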
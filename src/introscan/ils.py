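"""Incomplete-lineage-sorting test for a shared haplotype of observed length.

The expected length of a tract shared by descent through the ancestral
population is L = 1 / (r * t), with r the local recombination rate per bp
per generation and t the total branch length (both branches summed) in
generations. The length of the shared tract around a focal point is the sum
of two independent exponential extents (left and right), i.e. Gamma with
shape 2 and scale L; the ILS probability for an observed length m is the
survival function (1 + m/L) * exp(-m/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

CM_PER_MB_TO_PER_BP = 1e-8  # 1 cM/Mb = 1e-8 Morgans per bp


@dataclass(frozen=True)
class ILSParams:
    """Inputs of the haplotype-length ILS test."""

    m_bp: float
    r_cM_per_Mb: float
    gen_time_years: float
    t_modern_years: float
    t_archaic_years: float

    def validate(self) -> None:
        for name in ("m_bp", "r_cM_per_Mb", "gen_time_years", "t_modern_years", "t_archaic_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def total_branch_generations(self) -> float:
        return (self.t_modern_years + self.t_archaic_years) / self.gen_time_years


def expected_tract_length(params: ILSParams) -> float:
    """Expected shared-tract length L = 1 / (r * t) in bp."""
    params.validate()
    r_per_bp = params.r_cM_per_Mb * CM_PER_MB_TO_PER_BP
    return 1.0 / (r_per_bp * params.total_branch_generations)


def ils_probability(params: ILSParams) -> float:
    """P(shared tract >= m_bp) under the two-sided exponential-extent model."""
    params.validate()
    x = params.m_bp / expected_tract_length(params)
    return (1.0 + x) * math.exp(-x)


def ils_sensitivity(
    params: ILSParams,
    modern_branch_years: list[float],
    archaic_branch_years: list[float],
) -> pd.DataFrame:
    """ILS probability over a grid of branch-length assumptions."""
    rows = []
    for tm in modern_branch_years:
        for ta in archaic_branch_years:
            p = ILSParams(params.m_bp, params.r_cM_per_Mb, params.gen_time_years, tm, ta)
            rows.append(
                {
                    "t_modern_years": tm,
                    "t_archaic_years": ta,
                    "expected_tract_length_bp": expected_tract_length(p),
                    "ils_probability": ils_probability(p),
                }
            )
    return pd.DataFrame(rows)
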
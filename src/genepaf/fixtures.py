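"""Bundled example inputs: lung-cancer GWAS summary statistics.

Two GWAS of lung cancer in Asian populations reported the variants below:
rs7086803, rs9387478 and rs2395185 from a study of never-smoking females and
rs3817963 from a Japanese study (6,029 cases / 13,535 controls).  The
never-smoking study was two-stage — 5,510 cases / 4,544 controls in the
initial scan plus 1,099 / 2,913 in the replication — and its printed ORs and
CIs are from the combined analysis, so the matching sample size is
6,609 cases / 7,457 controls (the CI-implied standard errors agree with the
score-statistic standard errors only at the combined N).  rs9387478's
reported allele is protective (OR 0.85).
rs2395185 and rs3817963 both sit near HLA-DRA at 6p21.3 and are in modest LD
(average r^2 = 0.14 across Han Chinese and Japanese panels); the other three
variants are on different genomic regions and treated as independent.

Lung-cancer prevalence for the liability transform uses the age-standardised
incidence of 16.1 per 100,000 person-years over an average 15-year window,
i.e. about 0.0024.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core_paf import VariantSummary
from .gwas_summary import write_summary_table
from .simstudy import CohortModel, simulate_cohort

__all__ = [
    "LUNG_CANCER_PREVALENCE",
    "PAIR_LD_R2",
    "lung_gwas_variants",
    "independent_trio",
    "correlated_pair",
    "write_fixture_files",
]

LUNG_CANCER_PREVALENCE = 16.1e-5 * 15  # ~0.0024

#: Average HapMap r^2 between rs2395185 and rs3817963.
PAIR_LD_R2 = 0.14


def lung_gwas_variants() -> list[VariantSummary]:
    """All four reported variants, as printed (protective allele unoriented)."""
    return [
        VariantSummary("rs7086803", raf=0.27, or_point=1.28, ci_low=1.21,
                       ci_high=1.35, n_cases=6609, n_controls=7457),
        VariantSummary("rs9387478", raf=0.50, or_point=0.85, ci_low=0.81,
                       ci_high=0.90, n_cases=6609, n_controls=7457),
        VariantSummary("rs2395185", raf=0.36, or_point=1.17, ci_low=1.11,
                       ci_high=1.23, n_cases=6609, n_controls=7457),
        VariantSummary("rs3817963", raf=0.32, or_point=1.18, ci_low=1.12,
                       ci_high=1.24, n_cases=6029, n_controls=13535),
    ]


def independent_trio() -> list[VariantSummary]:
    """The three mutually independent lung-cancer variants."""
    return [v for v in lung_gwas_variants()
            if v.variant_id in ("rs7086803", "rs9387478", "rs2395185")]


def correlated_pair() -> tuple[list[VariantSummary], np.ndarray]:
    """The LD-correlated 6p21.3 pair plus its r^2 matrix."""
    pair = [v for v in lung_gwas_variants()
            if v.variant_id in ("rs2395185", "rs3817963")]
    r2 = np.array([[1.0, PAIR_LD_R2], [PAIR_LD_R2, 1.0]])
    return pair, r2


def write_fixture_files(out_dir, cohort_seed: int = 42,
                        cohort_n: int = 2000) -> dict[str, Path]:
    """Write the summary TSV, the pair LD matrix, and a small synthetic cohort.

    The cohort is a seed-pinned draw from a one-variant log-linear model and is
    byte-identical across runs with the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["summary"] = out_dir / "lung_gwas_summary.tsv"
    write_summary_table(lung_gwas_variants(), paths["summary"])

    pair, r2 = correlated_pair()
    paths["ld"] = out_dir / "pair_ld_r2.tsv"
    ids = [v.variant_id for v in pair]
    pd.DataFrame(r2, index=ids, columns=ids).to_csv(paths["ld"], sep="\t",
                                                    index_label="variant_id")

    model = CohortModel(rafs=(0.3,), log_effects=(0.2,), baseline_risk=0.05,
                        n_cohort=cohort_n)
    y, genotypes = simulate_cohort(model, seed=cohort_seed)
    paths["cohort"] = out_dir / "synthetic_cohort.tsv"
    pd.DataFrame({"y": y, "X1": genotypes[:, 0]}).to_csv(
        paths["cohort"], sep="\t", index=False)
    return paths
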
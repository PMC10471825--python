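"""Publication-style summary tables and packaged reference fixtures.

Numeric report rounding follows the conventions of meta-QTL summary tables:
positions and CI bounds to 2 decimals, PVE to 1 decimal. Every report is
written with a comment header carrying the configuration hash and seed so
runs are auditable and byte-reproducible.

The packaged ``data/rice_pue_*.tsv`` fixtures are a transcription of the
summary numbers of the compiled rice phosphorus-use-efficiency meta-QTL
catalog (per-chromosome QTL/meta-QTL counts, the 38 multi-study meta-QTLs
and the 16-study overview); they serve as consistency surfaces for tests and
reporting, not as pipeline inputs.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .mqtl_engine import MQTL
from .qtl_catalog import QTLRecord

__all__ = [
    "load_reference_chromosome_counts",
    "load_reference_mqtl_summary",
    "load_reference_study_overview",
    "chromosome_count_report",
    "mqtl_table",
    "mqtl_summary_stats",
    "write_tsv",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("metaqtl.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_reference_chromosome_counts() -> pd.DataFrame:
    return _load("rice_pue_chromosome_counts.tsv")


def load_reference_mqtl_summary() -> pd.DataFrame:
    return _load("rice_pue_mqtl_summary.tsv")


def load_reference_study_overview() -> pd.DataFrame:
    return _load("rice_pue_study_overview.tsv")


def chromosome_count_report(
    records: Sequence[QTLRecord], mqtls: Sequence[MQTL]
) -> pd.DataFrame:
    """Per-chromosome initial-QTL and meta-QTL counts with a totals row."""
    chroms = sorted({r.chromosome for r in records} | {m.chromosome for m in mqtls})
    rows = []
    for chrom in chroms:
        rows.append(
            {
                "chrom": str(chrom),
                "n_initial_qtls": sum(1 for r in records if r.chromosome == chrom),
                "n_mqtls": sum(1 for m in mqtls if m.chromosome == chrom),
            }
        )
    df = pd.DataFrame(rows, columns=["chrom", "n_initial_qtls", "n_mqtls"])
    total = pd.DataFrame(
        [
            {
                "chrom": "Total",
                "n_initial_qtls": int(df["n_initial_qtls"].sum()),
                "n_mqtls": int(df["n_mqtls"].sum()),
            }
        ]
    )
    return pd.concat([df, total], ignore_index=True)


def mqtl_table(mqtls: Sequence[MQTL]) -> pd.DataFrame:
    """One row per meta-QTL at publication precision (positions 2 dp, PVE 1 dp)."""
    rows = []
    for m in mqtls:
        rows.append(
            {
                "mqtl_id": m.mqtl_id,
                "chrom": m.chromosome,
                "position_cM": round(m.position_cM, 2),
                "ci95_lo_cM": round(m.ci95_lo_cM, 2),
                "ci95_hi_cM": round(m.ci95_hi_cM, 2),
                "ci95_cM": round(m.ci95_width_cM, 2),
                "start_bp": m.start_bp,
                "stop_bp": m.stop_bp,
                "n_members": m.n_members,
                "n_studies": m.n_studies,
                "avg_pve": round(m.avg_pve_percent, 1),
                "traits": ",".join(m.traits),
                "member_qtl_ids": ",".join(m.member_qtl_ids),
                "aic": round(m.aic, 2),
                "model_K": m.model_K,
            }
        )
    return pd.DataFrame(rows)


def mqtl_summary_stats(summary: pd.DataFrame) -> dict[str, float]:
    """Headline statistics of a meta-QTL summary table (reference or computed):
    row count, CI mean/min/max and the member-count range."""
    ci = summary["ci95_cM"]
    return {
        "n_mqtls": int(len(summary)),
        "ci_mean_cM": float(ci.mean()),
        "ci_min_cM": float(ci.min()),
        "ci_max_cM": float(ci.max()),
        "members_min": int(summary["n_qtls"].min()) if "n_qtls" in summary else int(summary["n_members"].min()),
        "members_max": int(summary["n_qtls"].max()) if "n_qtls" in summary else int(summary["n_members"].max()),
    }


def write_tsv(
    df: pd.DataFrame, path: str | Path, header_meta: Mapping[str, object] | None = None
) -> None:
    """Write a report TSV with '# key: value' comment headers (config hash,
    seed, stage counts) followed by the table."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_meta:
            for key in sorted(header_meta):
                fh.write(f"# {key}: {header_meta[key]}\n")
        df.to_csv(fh, sep="\t", index=False)
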
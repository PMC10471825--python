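"""Candidate-gene mining inside meta-QTL physical intervals.

Genes overlapping a meta-QTL interval are pooled (non-redundantly across
meta-QTLs), filtered by annotation keywords related to phosphorus-use
efficiency, and then screened against root expression under phosphorus-non-
supplied versus control conditions at two timepoints (6 h and 24 h):

* stage A — consistent direction of regulation at both timepoints;
* stage B — additionally at least 1.5-fold change at both timepoints
  (the "P-responsive" set);
* stage C — additionally at least 2-fold change at 24 h.

Fold change is mean(minusP)/mean(control); down-regulation is measured as the
reciprocal against the same threshold. Significance uses a two-sided Welch
t-test per timepoint, tiered at P<0.10, P<0.05 and P<0.01. GO enrichment
is an upper-tail hypergeometric test with the unfiltered meta-QTL genes as
background and Benjamini-Hochberg FDR control.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mqtl_engine import MQTL

__all__ = [
    "GeneRecord",
    "ResponseCall",
    "MinerError",
    "DEFAULT_KEYWORDS",
    "read_gene_table",
    "read_gff3",
    "read_expression",
    "genes_in_mqtl",
    "genes_in_mqtls",
    "keyword_filter",
    "response_call",
    "response_calls",
    "cascade_filter",
    "go_enrichment",
]


class MinerError(ValueError):
    pass


#: annotation keywords for phosphorus-use-efficiency candidate genes
DEFAULT_KEYWORDS = [
    "p homeostasis",
    "phosphate",
    "pi transporter",
    "phosphorus translocation",
    "phosphorus uptake",
    "crown root",
    "root hair",
    "abiotic stress",
]

TIMEPOINTS = ("6h", "24h")
CONDITIONS = ("minusP", "control")


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    annotation_text: str = ""
    aliases: tuple[str, ...] = ()
    go_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise MinerError(f"{self.gene_id}: start_bp > end_bp")


@dataclass(frozen=True)
class ResponseCall:
    gene_id: str
    fc_6h: float
    fc_24h: float
    direction_6h: str  # "up" | "down"
    direction_24h: str
    p_6h: float
    p_24h: float
    tier: str  # "ns" | "p10" | "p05" | "p01"


def read_gene_table(path: str | Path) -> list[GeneRecord]:
    """TSV with header gene_id, chrom, start_bp, end_bp, annotation, aliases, go_terms
    (aliases/go_terms are comma-separated, may be empty)."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    need = {"gene_id", "chrom", "start_bp", "end_bp", "annotation"}
    missing = need - set(df.columns)
    if missing:
        raise MinerError(f"{path}: missing gene columns {sorted(missing)}")
    genes = []
    for _, row in df.iterrows():
        genes.append(
            GeneRecord(
                gene_id=row["gene_id"],
                chromosome=int(row["chrom"]),
                start_bp=int(row["start_bp"]),
                end_bp=int(row["end_bp"]),
                annotation_text=row["annotation"],
                aliases=tuple(a for a in row.get("aliases", "").split(",") if a),
                go_terms=tuple(g for g in row.get("go_terms", "").split(",") if g),
            )
        )
    return genes


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[GeneRecord]:
    """Gene features from a GFF3 file (ID and Note/description attributes)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for feat in db.features_of_type(feature_type):
        notes = feat.attributes.get("Note", []) + feat.attributes.get("description", [])
        aliases = tuple(feat.attributes.get("Alias", []))
        go = tuple(feat.attributes.get("Ontology_term", []))
        chrom = str(feat.seqid).removeprefix("chr").removeprefix("Chr")
        genes.append(
            GeneRecord(
                gene_id=feat.attributes.get("ID", [feat.id])[0],
                chromosome=int(chrom),
                start_bp=int(feat.start),
                end_bp=int(feat.end),
                annotation_text="; ".join(notes),
                aliases=aliases,
                go_terms=go,
            )
        )
    return genes


def genes_in_mqtl(mqtl: MQTL, annotation: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Genes on the meta-QTL's chromosome whose span overlaps its physical
    interval (any overlap, closed coordinates)."""
    lo, hi = mqtl.start_bp, mqtl.stop_bp
    return [
        g
        for g in annotation
        if g.chromosome == mqtl.chromosome and g.start_bp <= hi and g.end_bp >= lo
    ]


def genes_in_mqtls(
    mqtls: Sequence[MQTL], annotation: Sequence[GeneRecord]
) -> tuple[dict[str, list[GeneRecord]], list[GeneRecord]]:
    """Per-meta-QTL gene lists plus the pooled non-redundant union."""
    per = {m.mqtl_id: genes_in_mqtl(m, annotation) for m in mqtls}
    seen: dict[str, GeneRecord] = {}
    for genes in per.values():
        for g in genes:
            seen.setdefault(g.gene_id, g)
    return per, list(seen.values())


def keyword_filter(
    genes: Iterable[GeneRecord], keywords: Sequence[str] = DEFAULT_KEYWORDS
) -> list[GeneRecord]:
    """Case-insensitive substring match of any keyword against the annotation
    text, aliases or GO labels."""
    if not keywords:
        raise MinerError("empty keyword list would pass every gene")
    kws = [k.lower() for k in keywords]
    out = []
    for g in genes:
        hay = " | ".join([g.annotation_text, *g.aliases, *g.go_terms]).lower()
        if any(k in hay for k in kws):
            out.append(g)
    return out


def read_expression(path: str | Path) -> pd.DataFrame:
    """Long-form expression TSV: gene_id, timepoint, condition, rep1..repk."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = {"gene_id", "timepoint", "condition"}
    missing = need - set(df.columns)
    if missing:
        raise MinerError(f"{path}: missing expression columns {sorted(missing)}")
    return df


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch t-test; degenerate (zero-variance, equal-mean) -> 1.0."""
    if len(a) < 2 or len(b) < 2:
        return 1.0
    if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
        return 1.0
    with warnings.catch_warnings():
        # constant replicate sets are a legitimate degenerate input
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def _tier(p_min: float) -> str:
    if p_min < 0.01:
        return "p01"
    if p_min < 0.05:
        return "p05"
    if p_min < 0.10:
        return "p10"
    return "ns"


def response_call(gene_expr: pd.DataFrame) -> ResponseCall:
    """Fold-change and significance call for one gene.

    ``gene_expr`` holds that gene's rows of the long-form expression table;
    both conditions must be present at both timepoints, otherwise the gene is
    a no-data case and the caller should flag it.
    """
    gene_id = gene_expr["gene_id"].iloc[0]
    rep_cols = [c for c in gene_expr.columns if c.startswith("rep")]
    fc = {}
    p = {}
    for tp in TIMEPOINTS:
        sub = gene_expr[gene_expr["timepoint"] == tp]
        minus = sub[sub["condition"] == "minusP"][rep_cols].to_numpy(float).ravel()
        ctrl = sub[sub["condition"] == "control"][rep_cols].to_numpy(float).ravel()
        minus = minus[~np.isnan(minus)]
        ctrl = ctrl[~np.isnan(ctrl)]
        if len(minus) == 0 or len(ctrl) == 0:
            raise MinerError(f"{gene_id}: no data for timepoint {tp}")
        fc[tp] = float(minus.mean() / ctrl.mean())
        p[tp] = _welch_p(minus, ctrl)
    return ResponseCall(
        gene_id=gene_id,
        fc_6h=fc["6h"],
        fc_24h=fc["24h"],
        direction_6h="up" if fc["6h"] > 1 else "down",
        direction_24h="up" if fc["24h"] > 1 else "down",
        p_6h=p["6h"],
        p_24h=p["24h"],
        tier=_tier(min(p.values())),
    )


def response_calls(expr: pd.DataFrame) -> tuple[list[ResponseCall], list[str]]:
    """Calls for every gene with complete data; returns (calls, no_data_ids)."""
    calls = []
    no_data = []
    for gene_id, sub in expr.groupby("gene_id", sort=True):
        try:
            calls.append(response_call(sub))
        except MinerError:
            no_data.append(gene_id)
    return calls, no_data


def _magnitude(fc: float) -> float:
    return max(fc, 1.0 / fc)


def cascade_filter(
    calls: Sequence[ResponseCall], fc1: float = 1.5, fc2: float = 2.0
) -> dict[str, list[ResponseCall]]:
    """Nested expression filters: stage A (consistent direction at both
    timepoints), stage B = A and fold change >= ``fc1`` at both, stage C = B
    and fold change >= ``fc2`` at 24 h."""
    stage_a = [c for c in calls if c.direction_6h == c.direction_24h]
    stage_b = [
        c for c in stage_a if _magnitude(c.fc_6h) >= fc1 and _magnitude(c.fc_24h) >= fc1
    ]
    stage_c = [c for c in stage_b if _magnitude(c.fc_24h) >= fc2]
    return {"A": stage_a, "B": stage_b, "C": stage_c}


def cascade_counts(stages: Mapping[str, Sequence[ResponseCall]]) -> pd.DataFrame:
    rows = []
    for name, calls in stages.items():
        up = sum(1 for c in calls if c.direction_24h == "up")
        rows.append(
            {"stage": name, "n_genes": len(calls), "n_up": up, "n_down": len(calls) - up}
        )
    return pd.DataFrame(rows)


def go_enrichment(
    foreground: Sequence[str],
    background: Sequence[str],
    gene2go: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail GO enrichment with BH FDR.

    For a term covering ``n`` of the ``M`` background genes, the p-value of
    observing ``k`` or more of them among the ``N`` foreground genes is
    ``P[X >= k]`` with ``X ~ Hypergeom(M, n, N)``. Terms absent from the
    foreground are omitted.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg <= bg:
        raise MinerError("foreground must be a subset of the background")
    term_bg: dict[str, set[str]] = {}
    for gene in bg:
        for term in gene2go.get(gene, []):
            term_bg.setdefault(term, set()).add(gene)
    rows = []
    M, N = len(bg), len(fg)
    for term, members in sorted(term_bg.items()):
        k = len(members & fg)
        if k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, M, len(members), N))
        rows.append(
            {"term": term, "bg_count": len(members), "fg_count": k, "p": p}
        )
    df = pd.DataFrame(rows, columns=["term", "bg_count", "fg_count", "p"])
    if not df.empty:
        df["q"] = multipletests(df["p"].to_numpy(), alpha=alpha, method="fdr_bh")[1]
        df = df.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
    return df
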
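"""Gene-haplotype grouping and superior-haplotype donor selection.

Accessions are grouped by their allele strings at a gene's SNP sites.
Accessions with more than 20% missing or heterozygous calls are removed;
remaining missing/het calls are imputed to the site's major allele for
clustering only. Biallelic sites embed as 0/1 vectors, k-means partitions
the accessions for each candidate number of groups, and the
Calinski-Harabasz index CH(k) = [B/(k-1)] / [W/(n-k)] selects k. Groups with
fewer than three members are dropped (their accessions reported as
unassigned) and the rest are numbered "Haplotype 1..k" by descending size.

The superior haplotype of a gene is the group containing a known
beneficial-allele donor accession. Donor panels per subpopulation are
assembled by greedy set-cover over genes.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = [
    "SNPMatrix",
    "HaplotypeGroup",
    "HaplotypeResult",
    "HaplotypeError",
    "read_matrix_tsv",
    "read_subpop_table",
    "filter_accessions",
    "calinski_harabasz",
    "group_haplotypes",
    "superior_haplotype",
    "subpop_frequency",
    "select_donors",
]

MISSING = "."
HET = "H"


class HaplotypeError(ValueError):
    pass


@dataclass
class SNPMatrix:
    """Accession x site call matrix for one gene.

    ``calls``: DataFrame indexed by accession, columns are site ids, values
    in {"0" (ref), "1" (alt), "H" (het), "." (missing)}. ``subpop`` maps each
    accession to its subpopulation label.
    """

    gene_id: str
    calls: pd.DataFrame
    subpop: pd.Series

    def __post_init__(self) -> None:
        if self.calls.empty:
            raise HaplotypeError(f"{self.gene_id}: empty call matrix")
        bad = set(np.unique(self.calls.to_numpy().astype(str))) - {"0", "1", HET, MISSING}
        if bad:
            raise HaplotypeError(f"{self.gene_id}: unknown call codes {sorted(bad)}")
        self.subpop = self.subpop.reindex(self.calls.index)
        if self.subpop.isna().any():
            missing = self.subpop[self.subpop.isna()].index.tolist()
            raise HaplotypeError(f"{self.gene_id}: accessions without subpopulation: {missing}")


@dataclass
class HaplotypeGroup:
    group_id: str  # "Haplotype 1" ... ordered by descending size
    profile: str  # per-site modal call code
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HaplotypeResult:
    gene_id: str
    groups: list[HaplotypeGroup]
    unassigned: list[str]
    k_selected: int
    ch_scores: dict[int, float]
    monomorphic: bool = False

    def group_of(self, accession: str) -> str | None:
        for g in self.groups:
            if accession in g.members:
                return g.group_id
        return None


def read_matrix_tsv(path: str | Path, gene_id: str, subpop: pd.Series) -> SNPMatrix:
    """Matrix TSV: first column ``accession``, remaining columns site ids."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#").set_index("accession")
    return SNPMatrix(gene_id=gene_id, calls=df, subpop=subpop)


def read_subpop_table(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    return df.set_index("accession")["subpop"]


def filter_accessions(matrix: SNPMatrix, max_bad_fraction: float = 0.20) -> SNPMatrix:
    """Drop accessions whose missing + heterozygous fraction exceeds the
    threshold (strict >, so exactly 20% bad calls is retained)."""
    if not 0.0 < max_bad_fraction < 1.0:
        raise HaplotypeError("max_bad_fraction must be in (0, 1)")
    calls = matrix.calls.astype(str)
    bad = calls.isin([MISSING, HET]).sum(axis=1) / calls.shape[1]
    keep = bad.index[bad <= max_bad_fraction]
    if len(keep) == 0:
        raise HaplotypeError(f"{matrix.gene_id}: all accessions filtered out")
    return SNPMatrix(
        gene_id=matrix.gene_id,
        calls=calls.loc[keep],
        subpop=matrix.subpop.loc[keep],
    )


def _impute_major(calls: pd.DataFrame) -> np.ndarray:
    """0/1 embedding with missing/het imputed to the site's major allele."""
    X = np.zeros(calls.shape, dtype=float)
    arr = calls.to_numpy().astype(str)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        n1 = int((col == "1").sum())
        n0 = int((col == "0").sum())
        major = 1.0 if n1 > n0 else 0.0
        X[:, j] = np.where(col == "1", 1.0, np.where(col == "0", 0.0, major))
    return X


def calinski_harabasz(X: np.ndarray, labels: Sequence[int]) -> float:
    """CH(k) = [B/(k-1)] / [W/(n-k)] with B/W the between/within scatter.

    A partition with zero within-cluster scatter (every cluster internally
    identical) scores +inf, so exact haplotype splits always win.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    ks = np.unique(labels)
    k = len(ks)
    if k < 2 or k >= n:
        raise HaplotypeError("CH index needs 2 <= k < n")
    grand = X.mean(axis=0)
    B = W = 0.0
    for lab in ks:
        sub = X[labels == lab]
        c = sub.mean(axis=0)
        B += len(sub) * float(np.sum((c - grand) ** 2))
        W += float(np.sum((sub - c) ** 2))
    if W == 0.0:
        return float("inf")
    return (B / (k - 1)) / (W / (n - k))


def _profile(calls: pd.DataFrame, members: Sequence[str]) -> str:
    """Per-site modal raw call among members (ties prefer 0 < 1 < H < .)."""
    order = {"0": 0, "1": 1, HET: 2, MISSING: 3}
    sub = calls.loc[list(members)].to_numpy().astype(str)
    out = []
    for j in range(sub.shape[1]):
        codes, counts = np.unique(sub[:, j], return_counts=True)
        best = sorted(zip(-counts, [order[c] for c in codes], codes))[0][2]
        out.append(best)
    return "".join(out)


def group_haplotypes(
    matrix: SNPMatrix,
    k_candidates: Iterable[int] = range(2, 11),
    min_group_size: int = 3,
    seed: int = 0,
) -> HaplotypeResult:
    """Partition accessions into haplotype groups, selecting k by the
    Calinski-Harabasz criterion over the candidate range.

    Accessions and sites are sorted canonically first so the result is
    invariant to input order. Monomorphic matrices (fewer than two distinct
    allele strings) short-circuit to a single flagged group.
    """
    calls = matrix.calls.sort_index(axis=0).sort_index(axis=1).astype(str)
    accessions = calls.index.to_list()
    X = _impute_major(calls)
    strings = ["".join(row) for row in X.astype(int).astype(str)]
    n_distinct = len(set(strings))

    if n_distinct < 2:
        grp = HaplotypeGroup(
            group_id="Haplotype 1",
            profile=_profile(calls, accessions),
            members=accessions,
        )
        return HaplotypeResult(
            gene_id=matrix.gene_id,
            groups=[grp],
            unassigned=[],
            k_selected=1,
            ch_scores={},
            monomorphic=True,
        )

    n = len(accessions)
    ch_scores: dict[int, float] = {}
    best: tuple[float, int, np.ndarray] | None = None
    for k in k_candidates:
        if k < 2 or k > min(n - 1, n_distinct):
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(set(labels.tolist())) < 2:
            continue
        score = calinski_harabasz(X, labels)
        ch_scores[k] = score
        if best is None or score > best[0]:
            best = (score, k, labels)
    if best is None:
        raise HaplotypeError(f"{matrix.gene_id}: no valid clustering found")
    _, k_sel, labels = best

    clusters: dict[int, list[str]] = {}
    for acc, lab in zip(accessions, labels):
        clusters.setdefault(int(lab), []).append(acc)

    kept = []
    unassigned: list[str] = []
    for members in clusters.values():
        if len(members) < min_group_size:
            unassigned.extend(members)
        else:
            kept.append(members)
    # number by descending size; deterministic tie-break on the profile string
    kept.sort(key=lambda m: (-len(m), _profile(calls, m)))
    groups = [
        HaplotypeGroup(
            group_id=f"Haplotype {i}",
            profile=_profile(calls, members),
            members=sorted(members),
        )
        for i, members in enumerate(kept, start=1)
    ]
    return HaplotypeResult(
        gene_id=matrix.gene_id,
        groups=groups,
        unassigned=sorted(unassigned),
        k_selected=k_sel,
        ch_scores=ch_scores,
    )


def superior_haplotype(
    result: HaplotypeResult, donor_accession: str, matrix: SNPMatrix | None = None
) -> str:
    """Group containing the beneficial-allele donor.

    If the donor was filtered out of the clustering, fall back to exact
    allele-string equality between the donor's calls and group profiles;
    with no match the result is "undetermined".
    """
    grp = result.group_of(donor_accession)
    if grp is not None:
        return grp
    if matrix is not None and donor_accession in matrix.calls.index:
        donor_string = "".join(
            matrix.calls.sort_index(axis=1).loc[donor_accession].astype(str)
        )
        for g in result.groups:
            if g.profile == donor_string:
                return g.group_id
    return "undetermined"


def subpop_frequency(result: HaplotypeResult, subpop: pd.Series) -> pd.DataFrame:
    """Count and fraction of each haplotype group per subpopulation.

    Zero counts are reported explicitly — a haplotype absent from one
    subpopulation still gets a row.
    """
    labels = sorted(subpop.dropna().unique().tolist())
    rows = []
    for g in result.groups:
        member_subpops = subpop.reindex(g.members)
        for lab in labels:
            n_lab = int((subpop == lab).sum())
            count = int((member_subpops == lab).sum())
            rows.append(
                {
                    "gene_id": result.gene_id,
                    "group_id": g.group_id,
                    "subpop": lab,
                    "count": count,
                    "fraction": count / n_lab if n_lab else 0.0,
                }
            )
    return pd.DataFrame(rows)


def select_donors(
    per_gene_superior: Mapping[str, set[str]],
    subpop: pd.Series,
) -> pd.DataFrame:
    """Greedy set-cover donor panel per subpopulation.

    ``per_gene_superior`` maps gene -> accessions carrying that gene's
    superior haplotype. Within each subpopulation, repeatedly pick the
    accession covering the most not-yet-covered genes (ties break on the
    accession id) until no accession adds coverage. The output is a
    presence/absence table of genes x chosen accessions.
    """
    if not per_gene_superior:
        raise HaplotypeError("no genes provided")
    genes = sorted(per_gene_superior)
    rows = []
    for lab in sorted(subpop.dropna().unique().tolist()):
        members = set(subpop[subpop == lab].index)
        coverage = {
            acc: {g for g in genes if acc in per_gene_superior[g]}
            for acc in sorted(members)
        }
        uncovered = {g for g in genes if any(acc in members for acc in per_gene_superior[g])}
        while uncovered:
            # deterministic tie-break: most coverage, then lexicographic id
            best_n = max(len(v & uncovered) for v in coverage.values())
            if best_n == 0:
                break
            cands = sorted(a for a, v in coverage.items() if len(v & uncovered) == best_n)
            acc = cands[0]
            covered = coverage[acc] & uncovered
            rows.append(
                {
                    "subpop": lab,
                    "accession": acc,
                    "n_covered": len(covered),
                    **{g: ("+" if g in coverage[acc] else "-") for g in genes},
                }
            )
            uncovered -= covered
    return pd.DataFrame(rows)
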
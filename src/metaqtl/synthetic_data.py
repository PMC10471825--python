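"""Synthetic pipeline inputs with known ground truth.

Every stage of the meta-QTL pipeline can be exercised without external
downloads: the generator plants true meta-QTL positions on each chromosome,
draws per-study QTL observations around them with the position error implied
by each study's confidence-interval width, emulates a dense physically
anchored marker map, a two-timepoint / two-condition root expression panel
and per-gene SNP call matrices with planted haplotype centers and designated
donor accessions.

Default distributional choices emulate the compiled rice
phosphorus-use-efficiency catalog: PVE is right-skewed with mode near 4%
clipped to [1.25, 27.9]; LOD is right-skewed on [2, 17], mostly below 5.
All generators are driven by one integer seed and are byte-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .qtl_catalog import (
    CI_CONSTANTS,
    PopulationType,
    QTLRecord,
    QTLStudy,
    TraitClass,
)
from .mqtl_engine import CI_TO_SD

__all__ = [
    "StudySpec",
    "TrueLayout",
    "simulate_catalog",
    "simulate_map",
    "simulate_expression",
    "simulate_snp_matrix",
    "simulate_workspace",
]

PVE_RANGE = (1.25, 27.9)
LOD_RANGE = (2.0, 16.98)
_TRAITS = [t for t in TraitClass]


@dataclass(frozen=True)
class StudySpec:
    study_id: str
    population_type: PopulationType
    population_size: int
    missing_ci: float = 0.3
    missing_pve: float = 0.2
    missing_lod: float = 0.2
    year: int = 2015


@dataclass
class TrueLayout:
    """Ground truth for one synthetic study system.

    ``chromosomes`` maps chromosome -> true meta-QTL positions (cM). The
    default is a compact three-chromosome system (2, 3 and 1 loci) surveyed
    by four mapping studies; ``qtl_prob`` is the chance a given study detects
    a given locus. CI widths computed from the population formulas are
    clipped to ``ci_clip_cM`` so position noise stays in a realistic range.
    """

    chromosomes: dict[int, list[float]] = field(
        default_factory=lambda: {1: [20.0, 70.0], 2: [15.0, 45.0, 80.0], 3: [30.0]}
    )
    studies: list[StudySpec] = field(
        default_factory=lambda: [
            StudySpec("SIM1", PopulationType.RIL, 200),
            StudySpec("SIM2", PopulationType.F2, 150),
            StudySpec("SIM3", PopulationType.BIL, 120),
            StudySpec("SIM4", PopulationType.DH, 130),
        ]
    )
    qtl_prob: float = 0.85
    ci_clip_cM: tuple[float, float] = (2.0, 20.0)
    seed: int = 0


def _draw_pve(rng: np.random.Generator, size: int) -> np.ndarray:
    """Right-skewed PVE (percent), mode near 4%, clipped to [1.25, 27.9]."""
    lo, hi = PVE_RANGE
    return lo + (hi - lo) * rng.beta(2.0, 9.7, size=size)


def _draw_lod(rng: np.random.Generator, size: int) -> np.ndarray:
    lo, hi = LOD_RANGE
    return lo + (hi - lo) * rng.beta(1.5, 6.0, size=size)


def simulate_catalog(
    layout: TrueLayout, seed: int | None = None
) -> tuple[dict[str, QTLStudy], list[QTLRecord], pd.DataFrame]:
    """Draw per-study QTL observations around the planted loci.

    Each observed peak is Normal(true position, (CI/3.92)^2) where the CI
    width comes from the population-design imputation formula at the drawn
    PVE. CI, PVE and LOD fields are then masked at the study's missingness
    rates. Returns (studies, records, truth) where ``truth`` maps each
    qtl_id to its chromosome, true locus index and true position.
    """
    rng = np.random.default_rng(layout.seed if seed is None else seed)
    studies = {
        s.study_id: QTLStudy(
            study_id=s.study_id,
            population_type=s.population_type,
            population_size=s.population_size,
            year=s.year,
        )
        for s in layout.studies
    }
    records: list[QTLRecord] = []
    truth_rows = []
    counter = 0
    for chrom in sorted(layout.chromosomes):
        for locus_idx, pos in enumerate(layout.chromosomes[chrom]):
            for spec in layout.studies:
                if rng.random() > layout.qtl_prob:
                    continue
                counter += 1
                pve = float(_draw_pve(rng, 1)[0])
                lod = float(_draw_lod(rng, 1)[0])
                const = CI_CONSTANTS[spec.population_type]
                ci = const / (spec.population_size * pve / 100.0)
                ci = float(np.clip(ci, *layout.ci_clip_cM))
                sd = ci / CI_TO_SD
                x = float(max(rng.normal(pos, sd), 0.0))
                qtl_id = f"q{counter:04d}"
                lo, hi = max(x - ci / 2.0, 0.0), x + ci / 2.0
                if lo == 0.0:
                    hi = ci
                rec = QTLRecord(
                    qtl_id=qtl_id,
                    study_id=spec.study_id,
                    trait=_TRAITS[int(rng.integers(len(_TRAITS)))],
                    chromosome=chrom,
                    peak_cM=x,
                    ci_lo_cM=lo,
                    ci_hi_cM=hi,
                    lod=lod,
                    pve_percent=pve,
                )
                # mask fields per the study's missingness rates
                if rng.random() < spec.missing_ci:
                    rec = replace(rec, ci_lo_cM=None, ci_hi_cM=None)
                if rng.random() < spec.missing_pve:
                    rec = replace(rec, pve_percent=None)
                if rng.random() < spec.missing_lod:
                    rec = replace(rec, lod=None)
                records.append(rec)
                truth_rows.append(
                    {
                        "qtl_id": qtl_id,
                        "chrom": chrom,
                        "true_locus": locus_idx,
                        "true_position_cM": pos,
                        "true_ci_cM": ci,
                        "study_id": spec.study_id,
                    }
                )
    truth = pd.DataFrame(truth_rows)
    return studies, records, truth


def simulate_map(
    markers_per_chrom: int = 400,
    chrom_length_bp: int = 40_000_000,
    chromosomes: Sequence[int] = (1, 2, 3),
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform unique marker positions per chromosome, sorted by (chrom, bp)."""
    rng = np.random.default_rng(seed)
    rows = []
    for chrom in chromosomes:
        bp = np.sort(
            rng.choice(chrom_length_bp, size=markers_per_chrom, replace=False)
        )
        for i, b in enumerate(bp):
            rows.append({"marker": f"m{chrom}_{i:05d}", "chrom": chrom, "bp": int(b)})
    return pd.DataFrame(rows)


def simulate_expression(
    effects: pd.DataFrame,
    n_reps: int = 3,
    control_mean: float = 500.0,
    noise_sd_log: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Log-normal replicate signals under control and minusP at 6 h and 24 h.

    ``effects`` columns: gene_id, fc_6h, fc_24h (true fold changes applied to
    the minusP condition; non-responsive genes use 1.0).
    """
    rng = np.random.default_rng(seed)
    rows = []
    rep_cols = [f"rep{i + 1}" for i in range(n_reps)]
    for _, eff in effects.iterrows():
        base = control_mean * float(np.exp(rng.normal(0.0, 0.3)))
        for tp, fc in (("6h", float(eff["fc_6h"])), ("24h", float(eff["fc_24h"]))):
            for cond, mean in (("control", base), ("minusP", base * fc)):
                reps = mean * np.exp(
                    rng.normal(0.0, noise_sd_log, size=n_reps)
                    - noise_sd_log**2 / 2.0
                )
                rows.append(
                    {
                        "gene_id": eff["gene_id"],
                        "timepoint": tp,
                        "condition": cond,
                        **{c: float(v) for c, v in zip(rep_cols, reps)},
                    }
                )
    return pd.DataFrame(rows)


def simulate_snp_matrix(
    gene_id: str,
    centers: Sequence[str],
    n_per_center: Sequence[int],
    subpops: Sequence[str] | None = None,
    subpop_weights: dict[str, Sequence[float]] | None = None,
    flip_noise: float = 0.0,
    missing_rate: float = 0.0,
    het_rate: float = 0.0,
    donor: tuple[str, int] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Accession call matrix drawn from planted haplotype centers.

    ``centers`` are allele strings over {0,1}; accession i of center c copies
    the center then flips/masks sites at the configured rates. ``donor``
    places one named noise-free accession on the given center. Returns
    (calls, subpop labels, truth mapping accession -> center index).
    """
    rng = np.random.default_rng(seed)
    n_sites = len(centers[0])
    if any(len(c) != n_sites for c in centers):
        raise ValueError("all centers must have the same number of sites")
    if subpops is None:
        subpops = ["indica", "japonica", "aus"]
    site_cols = [f"s{j + 1}" for j in range(n_sites)]
    rows = {}
    labels = {}
    truth = {}
    counter = 0
    for c_idx, (center, n_acc) in enumerate(zip(centers, n_per_center)):
        for _ in range(n_acc):
            counter += 1
            acc = f"ACC{counter:04d}"
            alleles = list(center)
            for j in range(n_sites):
                if rng.random() < flip_noise:
                    alleles[j] = "1" if alleles[j] == "0" else "0"
                r = rng.random()
                if r < missing_rate:
                    alleles[j] = MISSING_CODE
                elif r < missing_rate + het_rate:
                    alleles[j] = "H"
            rows[acc] = alleles
            if subpop_weights is not None:
                # per-center subpopulation skew
                w = np.asarray(
                    [subpop_weights.get(sp, [1.0] * len(centers))[c_idx] for sp in subpops],
                    dtype=float,
                )
                w = w / w.sum()
                labels[acc] = subpops[int(rng.choice(len(subpops), p=w))]
            else:
                labels[acc] = subpops[int(rng.integers(len(subpops)))]
            truth[acc] = c_idx
    if donor is not None:
        name, c_idx = donor
        rows[name] = list(centers[c_idx])
        labels[name] = subpops[0]
        truth[name] = c_idx
    calls = pd.DataFrame.from_dict(rows, orient="index", columns=site_cols)
    return calls, pd.Series(labels, name="subpop"), pd.Series(truth, name="center")


MISSING_CODE = "."


def simulate_workspace(
    outdir: str | Path,
    layout: TrueLayout | None = None,
    seed: int = 0,
    n_genes: int = 60,
    n_responsive: int = 12,
) -> Path:
    """Materialize a self-consistent demo workspace for the full pipeline.

    Writes the QTL catalog and study table, marker map, gene annotation,
    gene-to-GO map, expression panel, per-gene SNP matrices with donors, a
    subpopulation map and the ground-truth tables, all in the dialects the
    pipeline modules read. Byte-reproducible for a fixed seed.
    """
    from .qtl_catalog import write_catalog

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if layout is None:
        layout = TrueLayout(seed=seed)
    else:
        layout = replace(layout, seed=seed)
    rng = np.random.default_rng(seed)

    studies, records, truth = simulate_catalog(layout)
    write_catalog(outdir / "qtl_catalog.tsv", outdir / "studies.tsv", studies, records)
    truth.to_csv(outdir / "truth_qtls.tsv", sep="\t", index=False)

    chroms = sorted(layout.chromosomes)
    max_cm = max(max(v) for v in layout.chromosomes.values()) + 40.0
    markers = simulate_map(
        markers_per_chrom=300,
        chrom_length_bp=int(max_cm * 250_000),
        chromosomes=chroms,
        seed=seed + 1,
    )
    markers.to_csv(outdir / "markers.tsv", sep="\t", index=False)

    # genes scattered across the true-locus neighborhoods and elsewhere
    gene_rows = []
    keywords = ["Phosphate transporter", "Pi homeostasis protein", "Crown root regulator",
                "Abiotic stress response factor", "tRNA ligase", "Cell wall protein",
                "Histone chaperone", "Photosystem subunit"]
    go_pool = ["GO:0006817 phosphate ion transport", "GO:0009737 response to abscisic acid",
               "GO:0006355 regulation of transcription", "GO:0055062 phosphate ion homeostasis"]
    g2g_rows = []
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        loci = layout.chromosomes[chrom]
        center_cm = loci[i % len(loci)] + rng.normal(0.0, 4.0)
        start = max(int(center_cm * 250_000 + rng.integers(-100_000, 100_000)), 1)
        end = start + int(rng.integers(2_000, 8_000))
        ann = keywords[int(rng.integers(len(keywords)))]
        gid = f"G{chrom:02d}g{i:04d}"
        gene_rows.append(
            {"gene_id": gid, "chrom": chrom, "start_bp": start, "end_bp": end,
             "annotation": ann, "aliases": "", "go_terms": ""}
        )
        for term in rng.choice(go_pool, size=int(rng.integers(1, 3)), replace=False):
            g2g_rows.append({"gene_id": gid, "go_term": term.split(" ")[0]})
    genes_df = pd.DataFrame(gene_rows)
    genes_df.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.DataFrame(g2g_rows).to_csv(outdir / "gene2go.tsv", sep="\t", index=False)

    # expression: first n_responsive genes get real fold changes
    fc_choices = [2.5, 3.0, 0.4, 2.2]
    eff_rows = []
    for i, row in genes_df.iterrows():
        if i < n_responsive:
            fc = fc_choices[i % len(fc_choices)]
            eff_rows.append({"gene_id": row["gene_id"], "fc_6h": fc, "fc_24h": fc})
        else:
            eff_rows.append({"gene_id": row["gene_id"], "fc_6h": 1.0, "fc_24h": 1.0})
    effects = pd.DataFrame(eff_rows)
    effects.to_csv(outdir / "truth_expression.tsv", sep="\t", index=False)
    expr = simulate_expression(effects, seed=seed + 2)
    expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)

    # SNP matrices for the first three responsive genes; one donor each
    hap_genes = genes_df["gene_id"].tolist()[: min(3, n_responsive)]
    donor_rows = []
    subpop_all: dict[str, str] = {}
    for gi, gid in enumerate(hap_genes):
        calls, subpop, hap_truth = simulate_snp_matrix(
            gene_id=gid,
            centers=["00000", "11000", "00111"],
            n_per_center=[14, 10, 8],
            subpop_weights={"indica": [1.0, 3.0, 1.0], "japonica": [3.0, 0.3, 1.0],
                            "aus": [1.0, 1.0, 2.0]},
            flip_noise=0.02,
            missing_rate=0.03,
            het_rate=0.03,
            donor=(f"DONOR_{gid}", 1),
            seed=seed + 10 + gi,
        )
        calls.rename_axis("accession").to_csv(outdir / f"snp_{gid}.tsv", sep="\t")
        hap_truth.rename_axis("accession").to_csv(
            outdir / f"truth_snp_{gid}.tsv", sep="\t"
        )
        subpop_all.update(subpop.to_dict())
        donor_rows.append({"gene_id": gid, "donor": f"DONOR_{gid}"})
    pd.Series(subpop_all, name="subpop").rename_axis("accession").to_csv(
        outdir / "subpop.tsv", sep="\t"
    )
    pd.DataFrame(donor_rows).to_csv(outdir / "donors.tsv", sep="\t", index=False)
    return outdir
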
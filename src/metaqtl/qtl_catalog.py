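"""Compiled QTL catalog: data model, I/O and imputation of missing statistics.

A meta-QTL analysis starts from a catalog of QTLs compiled from independent
mapping studies. Source studies rarely report every statistic, so the catalog
carries well-defined imputation rules:

* missing confidence intervals (CI) are estimated from population size ``N``
  and phenotypic variance explained (PVE) using population-type-specific
  constants (163 for recombinant inbred lines, 530 for F2-derived, backcross
  inbred, chromosome-segment substitution and doubled-haploid designs);
* missing PVE is recovered from the LOD score as ``100*(1 - 10**(-2*LOD/N))``;
* missing peak positions are the midpoint of the flanking-marker interval;
* missing LOD scores default to 3.0, the usual declaration threshold.

Every imputation is recorded in per-field provenance flags so downstream
reports can stratify reported versus imputed values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "PopulationType",
    "TraitClass",
    "QTLStudy",
    "QTLRecord",
    "CatalogError",
    "CI_CONSTANTS",
    "DEFAULT_LOD",
    "impute_ci",
    "impute_pve",
    "pve_to_lod",
    "infer_peak",
    "default_lod",
    "finalize_record",
    "finalize_catalog",
    "read_catalog",
    "write_catalog",
]


class CatalogError(ValueError):
    """Raised for domain errors in catalog values or malformed catalog files."""


class PopulationType(str, Enum):
    RIL = "RIL"
    BIL = "BIL"
    CSSL = "CSSL"
    DH = "DH"
    F2 = "F2"
    F2_3 = "F2_3"


class TraitClass(str, Enum):
    """Trait categories for phosphorus-use-efficiency QTLs.

    SDW shoot dry weight; RT root traits; RSR root-shoot ratio; BM total dry
    biomass; SPC seed P content; RRP relative response to P; IPT internal P
    translocation; YLD yield components; PUP P uptake (accepted on input and
    reported as-is).
    """

    SDW = "SDW"
    RT = "RT"
    RSR = "RSR"
    BM = "BM"
    SPC = "SPC"
    RRP = "RRP"
    IPT = "IPT"
    YLD = "YLD"
    PUP = "PUP"


#: CI-imputation constant per population design. RILs accumulate more
#: recombination per line, giving tighter intervals for the same N*PVE.
CI_CONSTANTS: dict[PopulationType, float] = {
    PopulationType.RIL: 163.0,
    PopulationType.BIL: 530.0,
    PopulationType.CSSL: 530.0,
    PopulationType.DH: 530.0,
    PopulationType.F2: 530.0,
    PopulationType.F2_3: 530.0,
}

DEFAULT_LOD = 3.0


@dataclass(frozen=True)
class QTLStudy:
    study_id: str
    population_type: PopulationType
    population_size: int
    marker_system: str = ""
    parents: str = ""
    year: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise CatalogError(
                f"study {self.study_id}: population_size must be >= 2, "
                f"got {self.population_size}"
            )


@dataclass(frozen=True)
class QTLRecord:
    """One mapped QTL with study provenance.

    Coordinate fields are optional on input; :func:`finalize_record` fills
    them. ``provenance`` maps field name -> "reported" | "imputed".
    """

    qtl_id: str
    study_id: str
    trait: TraitClass
    chromosome: int
    peak_cM: float | None = None
    ci_lo_cM: float | None = None
    ci_hi_cM: float | None = None
    ci_width_cM: float | None = None
    lod: float | None = None
    pve_percent: float | None = None
    left_marker_bp: int | None = None
    right_marker_bp: int | None = None
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1 <= self.chromosome <= 12:
            raise CatalogError(
                f"{self.qtl_id}: chromosome must be in 1..12, got {self.chromosome}"
            )

    @property
    def is_final(self) -> bool:
        return (
            self.peak_cM is not None
            and self.ci_lo_cM is not None
            and self.ci_hi_cM is not None
            and self.ci_width_cM is not None
            and self.lod is not None
            and self.pve_percent is not None
        )


def impute_ci(
    population_type: PopulationType,
    n: int,
    pve_percent: float,
    constants: Mapping[PopulationType, float] = CI_CONSTANTS,
) -> float:
    """Estimated CI width (cM) from population size and PVE.

    ``CI = c / (N * p)`` where ``p`` is PVE as a proportion and ``c`` is the
    population-design constant (163 for RIL, 530 otherwise).
    """
    if n < 2:
        raise CatalogError(f"population size N must be >= 2, got {n}")
    if not 0.0 < pve_percent <= 100.0:
        raise CatalogError(f"pve_percent must be in (0, 100], got {pve_percent}")
    c = constants[PopulationType(population_type)]
    return c / (n * pve_percent / 100.0)


def impute_pve(lod: float, n: int) -> float:
    """PVE (percent) from the LOD score: ``100*(1 - 10**(-2*LOD/N))``.

    Strictly increasing in LOD and strictly decreasing in N.
    """
    if lod <= 0:
        raise CatalogError(f"lod must be positive, got {lod}")
    if n < 2:
        raise CatalogError(f"population size N must be >= 2, got {n}")
    return 100.0 * (1.0 - 10.0 ** (-2.0 * lod / n))


def pve_to_lod(pve_percent: float, n: int) -> float:
    """Inverse of :func:`impute_pve`: ``LOD = -(N/2) * log10(1 - p)``."""
    if not 0.0 < pve_percent < 100.0:
        raise CatalogError(f"pve_percent must be in (0, 100), got {pve_percent}")
    return -(n / 2.0) * math.log10(1.0 - pve_percent / 100.0)


def infer_peak(ci_lo_cM: float, ci_hi_cM: float) -> float:
    """Peak position as the midpoint of the flanking-marker interval."""
    if ci_lo_cM >= ci_hi_cM:
        raise CatalogError(
            f"ci_lo_cM must be < ci_hi_cM, got [{ci_lo_cM}, {ci_hi_cM}]"
        )
    return (ci_lo_cM + ci_hi_cM) / 2.0


def default_lod(record: QTLRecord, threshold: float = DEFAULT_LOD) -> QTLRecord:
    """Fill a missing LOD score with the declaration threshold (3.0)."""
    if record.lod is not None:
        return record
    prov = dict(record.provenance)
    prov["lod"] = "imputed"
    return replace(record, lod=threshold, provenance=prov)


def finalize_record(record: QTLRecord, study: QTLStudy) -> QTLRecord:
    """Apply all imputation rules so every coordinate/statistic is present.

    Order: peak from CI midpoint -> LOD default -> PVE from LOD -> CI width
    from the population formula -> CI endpoints from peak +/- width/2.
    Idempotent: a finalized record passes through unchanged.
    """
    prov = dict(record.provenance)

    peak, lo, hi, width = (
        record.peak_cM,
        record.ci_lo_cM,
        record.ci_hi_cM,
        record.ci_width_cM,
    )

    if peak is None:
        if lo is None or hi is None:
            raise CatalogError(
                f"{record.qtl_id}: peak_cM missing and no CI endpoints to infer it"
            )
        peak = infer_peak(lo, hi)
        prov["peak_cM"] = "imputed"
    else:
        prov.setdefault("peak_cM", "reported")

    lod = record.lod
    if lod is None:
        lod = DEFAULT_LOD
        prov["lod"] = "imputed"
    else:
        prov.setdefault("lod", "reported")

    pve = record.pve_percent
    if pve is None:
        pve = impute_pve(lod, study.population_size)
        prov["pve_percent"] = "imputed"
    else:
        prov.setdefault("pve_percent", "reported")

    if lo is not None and hi is not None:
        if lo > hi:
            raise CatalogError(f"{record.qtl_id}: ci_lo_cM > ci_hi_cM")
        # keep the stated peak; widen the interval minimally if inconsistent
        if peak < lo or peak > hi:
            lo, hi = min(lo, peak), max(hi, peak)
            prov["ci"] = "widened-to-contain-peak"
        width = hi - lo
        prov.setdefault("ci_width_cM", "reported")
    else:
        if width is None:
            width = impute_ci(study.population_type, study.population_size, pve)
            prov["ci_width_cM"] = "imputed"
        lo = peak - width / 2.0
        hi = peak + width / 2.0
        if lo < 0:
            # shift right so coordinates stay nonnegative and width is kept
            lo, hi = 0.0, width
        prov.setdefault("ci_endpoints", "imputed")

    return replace(
        record,
        peak_cM=peak,
        ci_lo_cM=lo,
        ci_hi_cM=hi,
        ci_width_cM=width,
        lod=lod,
        pve_percent=pve,
        provenance=prov,
    )


def finalize_catalog(
    records: Iterable[QTLRecord], studies: Mapping[str, QTLStudy]
) -> list[QTLRecord]:
    out = []
    for rec in records:
        if rec.study_id not in studies:
            raise CatalogError(f"{rec.qtl_id}: unknown study_id {rec.study_id!r}")
        out.append(finalize_record(rec, studies[rec.study_id]))
    return out


# ---------------------------------------------------------------------------
# TSV I/O

RECORD_COLUMNS = [
    "qtl_id",
    "study_id",
    "trait",
    "chrom",
    "peak_cM",
    "ci_lo_cM",
    "ci_hi_cM",
    "lod",
    "pve_percent",
    "left_marker_bp",
    "right_marker_bp",
]

STUDY_COLUMNS = ["study_id", "population_type", "population_size", "year"]


def _opt_float(value, row: int, col: str, errors: list[str]) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        errors.append(f"row {row}: malformed number in {col}: {value!r}")
        return None


def read_catalog(
    records_path: str | Path, studies_path: str | Path
) -> tuple[dict[str, QTLStudy], list[QTLRecord]]:
    """Read the study table and QTL table; reject malformed rows by number."""
    errors: list[str] = []

    sdf = pd.read_csv(studies_path, sep="\t", dtype=str, comment="#")
    missing = set(STUDY_COLUMNS) - set(sdf.columns)
    if missing:
        raise CatalogError(f"{studies_path}: missing study columns {sorted(missing)}")
    studies: dict[str, QTLStudy] = {}
    for i, row in sdf.iterrows():
        try:
            studies[row["study_id"]] = QTLStudy(
                study_id=row["study_id"],
                population_type=PopulationType(row["population_type"]),
                population_size=int(row["population_size"]),
                year=int(row["year"]) if row["year"] else 0,
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"studies row {i + 2}: {exc}")

    rdf = pd.read_csv(records_path, sep="\t", dtype=str, comment="#")
    missing = set(RECORD_COLUMNS) - set(rdf.columns)
    if missing:
        raise CatalogError(f"{records_path}: missing catalog columns {sorted(missing)}")
    records: list[QTLRecord] = []
    for i, row in rdf.iterrows():
        line = i + 2  # header is line 1
        try:
            trait = TraitClass(row["trait"])
        except ValueError:
            errors.append(f"row {line}: unknown trait class {row['trait']!r}")
            continue
        try:
            rec = QTLRecord(
                qtl_id=row["qtl_id"],
                study_id=row["study_id"],
                trait=trait,
                chromosome=int(row["chrom"]),
                peak_cM=_opt_float(row["peak_cM"], line, "peak_cM", errors),
                ci_lo_cM=_opt_float(row["ci_lo_cM"], line, "ci_lo_cM", errors),
                ci_hi_cM=_opt_float(row["ci_hi_cM"], line, "ci_hi_cM", errors),
                lod=_opt_float(row["lod"], line, "lod", errors),
                pve_percent=_opt_float(row["pve_percent"], line, "pve_percent", errors),
                left_marker_bp=(
                    int(float(row["left_marker_bp"]))
                    if isinstance(row["left_marker_bp"], str) and row["left_marker_bp"]
                    else None
                ),
                right_marker_bp=(
                    int(float(row["right_marker_bp"]))
                    if isinstance(row["right_marker_bp"], str) and row["right_marker_bp"]
                    else None
                ),
            )
        except (ValueError, CatalogError) as exc:
            errors.append(f"row {line}: {exc}")
            continue
        records.append(rec)

    if errors:
        raise CatalogError("catalog read failed:\n" + "\n".join(errors))
    return studies, records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable decimal text
    return str(value)


def write_catalog(
    records_path: str | Path,
    studies_path: str | Path,
    studies: Mapping[str, QTLStudy],
    records: Iterable[QTLRecord],
) -> None:
    """Write both tables; numeric text round-trips bit-for-bit."""
    srows = [
        {
            "study_id": s.study_id,
            "population_type": s.population_type.value,
            "population_size": s.population_size,
            "year": s.year,
        }
        for s in studies.values()
    ]
    pd.DataFrame(srows, columns=STUDY_COLUMNS).to_csv(
        studies_path, sep="\t", index=False
    )

    rrows = []
    for r in records:
        rrows.append(
            {
                "qtl_id": r.qtl_id,
                "study_id": r.study_id,
                "trait": r.trait.value,
                "chrom": r.chromosome,
                "peak_cM": _fmt(r.peak_cM),
                "ci_lo_cM": _fmt(r.ci_lo_cM),
                "ci_hi_cM": _fmt(r.ci_hi_cM),
                "lod": _fmt(r.lod),
                "pve_percent": _fmt(r.pve_percent),
                "left_marker_bp": _fmt(r.left_marker_bp),
                "right_marker_bp": _fmt(r.right_marker_bp),
            }
        )
    pd.DataFrame(rrows, columns=RECORD_COLUMNS).to_csv(
        records_path, sep="\t", index=False
    )
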
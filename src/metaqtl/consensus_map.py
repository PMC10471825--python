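"""Physically anchored consensus map and QTL projection.

The consensus map places every marker at a genetic coordinate derived from
its physical position on the reference assembly with a fixed conversion of
1 cM = 250 kb. QTLs whose flanking markers have known physical positions are
projected by snapping each flank to the nearest map marker (by |delta bp|,
ties toward the lower position) and re-expressing the interval on the
consensus cM scale; records that only carry cM coordinates pass through
unchanged. Coordinates are 1-based inclusive bp; intervals are closed.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .qtl_catalog import QTLRecord

__all__ = [
    "CM_PER_BP",
    "BP_PER_CM",
    "MarkerRecord",
    "ConsensusMap",
    "MapError",
    "build_map",
    "read_marker_table",
    "read_bed",
    "project_qtl",
    "map_stats",
]

BP_PER_CM = 250_000.0
CM_PER_BP = 1.0 / BP_PER_CM


class MapError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerRecord:
    name: str
    chromosome: int
    physical_bp: int
    genetic_cM: float


class ConsensusMap:
    """Ordered markers per chromosome with physical and genetic coordinates."""

    def __init__(self, frame: pd.DataFrame):
        self._frame = frame

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def chromosomes(self) -> list[int]:
        return sorted(self._frame["chrom"].unique().tolist())

    def markers(self, chromosome: int) -> pd.DataFrame:
        sub = self._frame[self._frame["chrom"] == chromosome]
        if sub.empty:
            raise MapError(f"no markers on chromosome {chromosome}")
        return sub

    def nearest_marker(self, chromosome: int, bp: int) -> MarkerRecord:
        """Closest marker by |delta bp|; equidistant ties -> lower position."""
        sub = self.markers(chromosome)
        pos = sub["bp"].to_numpy()
        idx = int(np.searchsorted(pos, bp))
        best = None
        for j in (idx - 1, idx):
            if 0 <= j < len(pos):
                d = abs(int(pos[j]) - bp)
                # strict < keeps the lower-bp candidate on ties
                if best is None or d < best[0]:
                    best = (d, j)
        row = sub.iloc[best[1]]
        return MarkerRecord(row["marker"], int(row["chrom"]), int(row["bp"]), float(row["cM"]))

    def cumulative_length_cM(self) -> float:
        return float(self._frame.groupby("chrom")["cM"].max().sum())

    def __len__(self) -> int:
        return len(self._frame)


def build_map(
    markers: Iterable[tuple[str, int, int]] | pd.DataFrame,
    cm_per_bp: float = CM_PER_BP,
) -> ConsensusMap:
    """Arrange markers by physical position and assign genetic coordinates.

    Exact-position duplicates (same chromosome and bp) are collapsed keeping
    the first name; one name listed at two different positions is an error.
    """
    if isinstance(markers, pd.DataFrame):
        df = markers.rename(columns={"marker": "marker", "chrom": "chrom", "bp": "bp"}).copy()
    else:
        df = pd.DataFrame(list(markers), columns=["marker", "chrom", "bp"])
    if df.empty:
        raise MapError("empty marker table")
    df["chrom"] = df["chrom"].astype(int)
    df["bp"] = df["bp"].astype(int)
    if (df["bp"] < 0).any():
        raise MapError("negative physical positions")
    bad_chrom = df[(df["chrom"] < 1) | (df["chrom"] > 12)]
    if not bad_chrom.empty:
        raise MapError(f"chromosome out of 1..12: {bad_chrom['chrom'].unique().tolist()}")

    dup = df.groupby("marker")[["chrom", "bp"]].nunique()
    conflicted = dup[(dup["chrom"] > 1) | (dup["bp"] > 1)].index.tolist()
    if conflicted:
        raise MapError(f"markers listed at conflicting positions: {conflicted}")

    df = df.sort_values(["chrom", "bp"], kind="mergesort")
    df = df.drop_duplicates(subset=["chrom", "bp"], keep="first")
    df["cM"] = df["bp"] * cm_per_bp
    return ConsensusMap(df.reset_index(drop=True))


def read_marker_table(path: str | Path) -> ConsensusMap:
    """TSV with header ``marker, chrom, bp``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"marker", "chrom", "bp"} - set(df.columns)
    if missing:
        raise MapError(f"{path}: missing marker columns {sorted(missing)}")
    return build_map(df[["marker", "chrom", "bp"]])


def read_bed(path: str | Path) -> ConsensusMap:
    """BED (0-based half-open) marker reader; start is converted to 1-based."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=[0, 1, 2, 3],
    )
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr").astype(int)
    out = pd.DataFrame(
        {"marker": df["name"], "chrom": df["chrom"], "bp": df["start"].astype(int) + 1}
    )
    return build_map(out)


def project_qtl(record: QTLRecord, cmap: ConsensusMap) -> QTLRecord:
    """Express a finalized QTL on the consensus cM scale.

    With flanking physical positions, each flank snaps to the nearest map
    marker and the peak becomes the midpoint of the snapped interval. With
    cM-only coordinates the record passes through (left CI truncated at 0).
    Idempotent: projecting a projected record changes nothing.
    """
    if not record.is_final:
        raise MapError(f"{record.qtl_id}: record must be finalized before projection")

    prov = dict(record.provenance)
    if record.left_marker_bp is not None and record.right_marker_bp is not None:
        left = cmap.nearest_marker(record.chromosome, record.left_marker_bp)
        right = cmap.nearest_marker(record.chromosome, record.right_marker_bp)
        lo, hi = sorted((left.genetic_cM, right.genetic_cM))
        # coincident snaps would give a zero-width CI and an invalid sd
        width = max(hi - lo, 0.01)
        hi = lo + width
        peak = (lo + hi) / 2.0
        prov["projection"] = f"snapped:{left.name},{right.name}"
        return replace(
            record,
            peak_cM=peak,
            ci_lo_cM=lo,
            ci_hi_cM=hi,
            ci_width_cM=width,
            provenance=prov,
        )

    lo = max(0.0, record.ci_lo_cM)
    if lo == record.ci_lo_cM and "projection" in prov:
        return record
    prov.setdefault("projection", "pass-through")
    return replace(
        record,
        ci_lo_cM=lo,
        ci_width_cM=record.ci_hi_cM - lo,
        provenance=prov,
    )


def map_stats(
    cmap: ConsensusMap, window_bp: int = 500_000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chromosome summary and marker density per window.

    Returns ``(per_chrom, windows)``: length (cM of the last marker), marker
    count and mean adjacent spacing per chromosome; marker counts per
    half-open window ``[k*w, (k+1)*w)`` including zero-count gaps.
    """
    if window_bp <= 0:
        raise MapError("window_bp must be positive")
    per_rows = []
    win_rows = []
    for chrom in cmap.chromosomes():
        sub = cmap.markers(chrom)
        cm = sub["cM"].to_numpy()
        bp = sub["bp"].to_numpy()
        spacing = float(np.diff(cm).mean()) if len(cm) > 1 else 0.0
        per_rows.append(
            {
                "chrom": chrom,
                "length_cM": float(cm[-1]),
                "n_markers": len(cm),
                "mean_spacing_cM": spacing,
            }
        )
        n_windows = int(bp[-1] // window_bp) + 1
        counts = np.bincount((bp // window_bp).astype(int), minlength=n_windows)
        for k, c in enumerate(counts):
            win_rows.append(
                {
                    "chrom": chrom,
                    "window_start_bp": k * window_bp,
                    "window_end_bp": (k + 1) * window_bp,
                    "n_markers": int(c),
                }
            )
    return pd.DataFrame(per_rows), pd.DataFrame(win_rows)
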
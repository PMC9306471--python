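"""Region building and the consensus adaptive-region procedure.

Significant markers are chained into regions when consecutive gaps are at
most 1 kb, each region is expanded to the 150th tested marker on either
side, and overlapping expansions are merged.  Per environment variable,
regions from the two association methods are intersected (bedtools
semantics, >= 1 bp); the smaller parent of each overlapping pair is kept
as a consensus (GEA) region if it also overlaps a differentiation-scan
(XtX) region.  GEA regions overlapping across variables collapse into
distinct regions, which are finally tested for overlap with hyper-divergent
intervals.

Coordinates are 1-based inclusive internally and 0-based half-open in BED
export.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd


@dataclass
class Region:
    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    provenance: str = ""  # gwa | baypass | xtx | method_overlap | gea
    variable: Optional[str] = None
    peak_pos: Optional[int] = None
    peak_stat: Optional[float] = None
    parents: tuple = field(default_factory=tuple)
    variables: tuple = field(default_factory=tuple)  # for distinct regions

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


def build_regions(
    significant: pd.DataFrame,
    tested: pd.DataFrame,
    gap: int = 1_000,
    flank: int = 150,
    provenance: str = "",
    variable: Optional[str] = None,
) -> list[Region]:
    """Chain-merge significant markers and expand by tested-marker flanks.

    ``significant`` needs columns chrom, pos, stat (larger = more
    significant); ``tested`` needs chrom, pos and must contain every
    significant marker.  Markers within ``gap`` bp chain into one cluster;
    each cluster expands to the ``flank``-th tested marker on either side
    (clipped at the chromosome's tested extent); overlapping expansions
    merge, keeping the best peak.
    """
    if len(significant) == 0:
        return []
    regions: list[Region] = []
    for c in sorted(set(significant["chrom"])):
        sig = significant[significant["chrom"] == c].sort_values("pos")
        tpos = np.sort(tested.loc[tested["chrom"] == c, "pos"].to_numpy())
        spos = sig["pos"].to_numpy()
        sstat = sig["stat"].to_numpy()
        # chain markers with consecutive gaps <= gap (inclusive)
        breaks = np.flatnonzero(np.diff(spos) > gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(spos) - 1]])
        raw: list[Region] = []
        for a, b in zip(starts, ends):
            i_left = int(np.searchsorted(tpos, spos[a], side="left"))
            i_right = int(np.searchsorted(tpos, spos[b], side="right")) - 1
            lo = tpos[max(i_left - flank, 0)]
            hi = tpos[min(i_right + flank, len(tpos) - 1)]
            peak = int(np.argmax(sstat[a: b + 1])) + a
            raw.append(
                Region(
                    chrom=c,
                    start=int(lo),
                    end=int(hi),
                    provenance=provenance,
                    variable=variable,
                    peak_pos=int(spos[peak]),
                    peak_stat=float(sstat[peak]),
                )
            )
        # merge overlapping expanded regions
        raw.sort(key=lambda r: r.start)
        merged: list[Region] = []
        for r in raw:
            if merged and r.start <= merged[-1].end:
                prev = merged[-1]
                best = max((prev, r), key=lambda x: x.peak_stat)
                merged[-1] = replace(
                    prev,
                    end=max(prev.end, r.end),
                    peak_pos=best.peak_pos,
                    peak_stat=best.peak_stat,
                )
            else:
                merged.append(r)
        regions.extend(merged)
    return regions


def intersect_regions(
    track_a: Iterable[Region], track_b: Iterable[Region]
) -> list[Region]:
    """Pairwise >= 1 bp intersections, bedtools-style.

    Each output region spans the overlap, carries provenance
    ``method_overlap``, the (matching) environment variable, and both
    parents.  A declared same-variable intersection with mismatched
    variables is an error.
    """
    out: list[Region] = []
    for a in track_a:
        for b in track_b:
            if not a.overlaps(b):
                continue
            if a.variable is not None and b.variable is not None and a.variable != b.variable:
                raise ValueError(
                    f"variable mismatch in intersection: {a.variable} vs {b.variable}"
                )
            out.append(
                Region(
                    chrom=a.chrom,
                    start=max(a.start, b.start),
                    end=min(a.end, b.end),
                    provenance="method_overlap",
                    variable=a.variable or b.variable,
                    peak_pos=a.peak_pos,
                    peak_stat=a.peak_stat,
                    parents=(a, b),
                )
            )
    return out


def consensus_gea_regions(
    method_overlaps: Iterable[Region], xtx_regions: list[Region]
) -> list[Region]:
    """Keep the smaller parent of each method overlap if it hits an XtX region."""
    out: list[Region] = []
    for ov in method_overlaps:
        if len(ov.parents) != 2:
            raise ValueError("method-overlap region lacks its two parents")
        smaller = min(ov.parents, key=lambda r: (r.length, r.start))
        if any(smaller.overlaps(x) for x in xtx_regions):
            out.append(
                Region(
                    chrom=smaller.chrom,
                    start=smaller.start,
                    end=smaller.end,
                    provenance="gea",
                    variable=ov.variable,
                    peak_pos=smaller.peak_pos,
                    peak_stat=smaller.peak_stat,
                    parents=ov.parents,
                )
            )
    return out


def distinct_regions(gea_regions: Iterable[Region]) -> list[Region]:
    """Collapse GEA regions overlapping across environment variables.

    Overlap chains are merged transitively into one region spanning the
    union, listing every contributing variable.
    """
    regs = sorted(gea_regions, key=lambda r: (r.chrom, r.start, r.end))
    out: list[Region] = []
    for r in regs:
        if out and r.chrom == out[-1].chrom and r.start <= out[-1].end:
            prev = out[-1]
            variables = tuple(
                dict.fromkeys(prev.variables + ((r.variable,) if r.variable else ()))
            )
            best_peak = prev
            if (r.peak_stat or -np.inf) > (prev.peak_stat or -np.inf):
                best_peak = r
            out[-1] = replace(
                prev,
                end=max(prev.end, r.end),
                variables=variables,
                peak_pos=best_peak.peak_pos,
                peak_stat=best_peak.peak_stat,
            )
        else:
            out.append(
                Region(
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    provenance="gea_distinct",
                    variables=(r.variable,) if r.variable else (),
                    peak_pos=r.peak_pos,
                    peak_stat=r.peak_stat,
                )
            )
    return out


def hyperdivergent_overlap(
    regions: list[Region], bed: pd.DataFrame
) -> tuple[list[bool], float]:
    """Flag regions overlapping >= 1 bp of a hyper-divergent interval.

    ``bed`` holds 0-based half-open chrom/start/end rows.  If the BED is
    non-empty and shares no chromosome name with the regions, the naming
    conventions disagree and an error lists the unmatched names.
    """
    if len(regions) == 0:
        return [], 0.0
    if len(bed) == 0:
        return [False] * len(regions), 0.0
    bed_chroms = set(bed["chrom"])
    reg_chroms = {r.chrom for r in regions}
    if not bed_chroms & reg_chroms:
        raise ValueError(
            f"chromosome naming mismatch: regions {sorted(reg_chroms)} vs "
            f"BED {sorted(bed_chroms)}"
        )
    flags = []
    for r in regions:
        sub = bed[bed["chrom"] == r.chrom]
        # BED [start, end) covers 1-based positions start+1 .. end
        hit = ((sub["start"] + 1 <= r.end) & (r.start <= sub["end"])).any()
        flags.append(bool(hit))
    return flags, float(np.mean(flags))


def regions_to_frame(regions: Iterable[Region]) -> pd.DataFrame:
    """Tabular export with BED-convention 0-based half-open coordinates."""
    rows = []
    for r in regions:
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start - 1,
                "end": r.end,
                "provenance": r.provenance,
                "variable": r.variable or ",".join(v for v in r.variables if v),
                "peak_pos": r.peak_pos,
                "peak_stat": r.peak_stat,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "provenance", "variable",
                 "peak_pos", "peak_stat"],
    )


def frame_to_regions(df: pd.DataFrame, provenance: str = "") -> list[Region]:
    """Inverse of :func:`regions_to_frame` (lossless coordinate round-trip)."""
    out = []
    for row in df.itertuples():
        out.append(
            Region(
                chrom=row.chrom,
                start=int(row.start) + 1,
                end=int(row.end),
                provenance=provenance or getattr(row, "provenance", ""),
                variable=getattr(row, "variable", None) or None,
                peak_pos=getattr(row, "peak_pos", None),
                peak_stat=getattr(row, "peak_stat", None),
            )
        )
    return out
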
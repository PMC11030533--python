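"""Genomic scar scores from allele-specific copy-number segments.

Three counts quantify the footprint of homologous-recombination
deficiency on a tumor genome:

* HRD-LOH — interstitial loss-of-heterozygosity segments (minor copy 0,
  at least one major copy) longer than 15 Mb that do not span a whole
  chromosome;
* LST — large-scale state transitions: breakpoints between adjacent
  segments each >= 10 Mb within one chromosome arm, after smoothing away
  segments < 3 Mb;
* ntAI — telomeric allelic imbalances: segments with unequal allele
  copies that reach a telomere without crossing the centromere.

Their sum is the HRD score used clinically. The size constants (15/10/3
Mb) are exposed because comparability with any given clinical threshold
depends on matching that assay's reference implementation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

SEGMENT_COLUMNS = ["chrom", "start", "end", "A", "B"]
KARYOTYPE_COLUMNS = ["chrom", "length", "cen_start", "cen_end"]

HRD_LOH_MIN_LENGTH = 15_000_000
LST_MIN_SEGMENT = 10_000_000
LST_SMOOTH_BELOW = 3_000_000


@dataclass
class ScarScores:
    hrd_loh: int
    lst: int
    ntai: int

    @property
    def hrd_score(self) -> int:
        return self.hrd_loh + self.lst + self.ntai


def toy_karyotype() -> pd.DataFrame:
    """Three-chromosome toy karyotype (100/80/60 Mb, 1 Mb centromeres at
    the midpoints) used by the simulator and as the test default."""
    rows = []
    for name, length in [("chr1", 100_000_000), ("chr2", 80_000_000), ("chr3", 60_000_000)]:
        mid = length // 2
        rows.append((name, length, mid - 500_000, mid + 500_000))
    return pd.DataFrame(rows, columns=KARYOTYPE_COLUMNS)


def validate_segments(segments: pd.DataFrame, karyotype: pd.DataFrame) -> pd.DataFrame:
    """Check the segment-table invariants; returns a sorted copy."""
    missing = set(SEGMENT_COLUMNS) - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns {sorted(missing)}")
    seg = segments[SEGMENT_COLUMNS].copy()
    seg = seg.sort_values(["chrom", "start"]).reset_index(drop=True)
    if (seg["A"] < seg["B"]).any() or (seg["B"] < 0).any():
        raise ValueError("require copy numbers A >= B >= 0")
    if (seg["end"] < seg["start"]).any():
        raise ValueError("segment end before start")
    lengths = karyotype.set_index("chrom")["length"]
    for chrom, grp in seg.groupby("chrom"):
        if chrom not in lengths.index:
            raise ValueError(f"chromosome {chrom} not in karyotype")
        if grp["start"].min() < 1 or grp["end"].max() > lengths[chrom]:
            raise ValueError(f"segment outside {chrom} bounds")
        if (grp["start"].to_numpy()[1:] <= grp["end"].to_numpy()[:-1]).any():
            raise ValueError(f"overlapping segments on {chrom}")
    return seg


def _seg_len(row) -> int:
    return int(row.end - row.start + 1)


def _merge_adjacent(seg: pd.DataFrame) -> pd.DataFrame:
    """Merge touching same-state segments so that scores are invariant to
    how a constant region happens to be split."""
    rows: list[dict] = []
    for row in seg.itertuples():
        if (rows and rows[-1]["chrom"] == row.chrom
                and rows[-1]["end"] + 1 == row.start
                and rows[-1]["A"] == row.A and rows[-1]["B"] == row.B):
            rows[-1]["end"] = row.end
        else:
            rows.append({"chrom": row.chrom, "start": row.start, "end": row.end,
                         "A": row.A, "B": row.B})
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def hrd_loh(segments: pd.DataFrame, karyotype: pd.DataFrame,
            min_length: int = HRD_LOH_MIN_LENGTH) -> int:
    """Count long interstitial LOH segments (B = 0, A >= 1, > min_length,
    not spanning the whole chromosome)."""
    seg = _merge_adjacent(validate_segments(segments, karyotype))
    lengths = karyotype.set_index("chrom")["length"]
    count = 0
    for row in seg.itertuples():
        if row.B == 0 and row.A >= 1 and _seg_len(row) > min_length:
            whole = row.start == 1 and row.end == lengths[row.chrom]
            if not whole:
                count += 1
    return count


def _arm_segments(seg: pd.DataFrame, karyotype: pd.DataFrame):
    """Yield per-arm segment lists, clipping segments at the centromere."""
    karyo = karyotype.set_index("chrom")
    for chrom, grp in seg.groupby("chrom"):
        cen_start = int(karyo.loc[chrom, "cen_start"])
        cen_end = int(karyo.loc[chrom, "cen_end"])
        length = int(karyo.loc[chrom, "length"])
        for arm_lo, arm_hi in [(1, cen_start - 1), (cen_end + 1, length)]:
            rows = []
            for row in grp.itertuples():
                lo, hi = max(row.start, arm_lo), min(row.end, arm_hi)
                if lo <= hi:
                    rows.append([lo, hi, int(row.A), int(row.B)])
            yield rows


def _smooth_arm(rows: list[list[int]], smooth_below: int) -> list[list[int]]:
    """Merge equal-state neighbours, then iteratively drop sub-threshold
    segments (smallest first), re-merging after each removal."""

    def merge(rs):
        out: list[list[int]] = []
        for r in rs:
            if out and out[-1][2] == r[2] and out[-1][3] == r[3]:
                out[-1][1] = r[1]
            else:
                out.append(list(r))
        return out

    rows = merge(rows)
    while True:
        small = [i for i, r in enumerate(rows)
                 if r[1] - r[0] + 1 < smooth_below]
        if not small:
            return rows
        i = min(small, key=lambda j: rows[j][1] - rows[j][0])
        del rows[i]
        rows = merge(rows)


def lst(segments: pd.DataFrame, karyotype: pd.DataFrame,
        min_segment: int = LST_MIN_SEGMENT,
        smooth_below: int = LST_SMOOTH_BELOW) -> int:
    """Count large-scale transitions per chromosome arm.

    A transition is a breakpoint between adjacent (post-smoothing)
    segments of different allele-specific state, each >= min_segment.
    Segments are clipped at the centromere first, so no breakpoint is
    ever counted across it.
    """
    seg = validate_segments(segments, karyotype)
    count = 0
    for rows in _arm_segments(seg, karyotype):
        rows = _smooth_arm(rows, smooth_below)
        for left, right in zip(rows[:-1], rows[1:]):
            if (left[2], left[3]) == (right[2], right[3]):
                continue
            if (left[1] - left[0] + 1 >= min_segment
                    and right[1] - right[0] + 1 >= min_segment):
                count += 1
    return count


def ntai(segments: pd.DataFrame, karyotype: pd.DataFrame) -> int:
    """Count telomeric allelic imbalances (A != B segments touching a
    telomere but not spanning the centromere)."""
    seg = _merge_adjacent(validate_segments(segments, karyotype))
    karyo = karyotype.set_index("chrom")
    count = 0
    for row in seg.itertuples():
        if row.A == row.B:
            continue
        length = int(karyo.loc[row.chrom, "length"])
        cen_start = int(karyo.loc[row.chrom, "cen_start"])
        cen_end = int(karyo.loc[row.chrom, "cen_end"])
        telomeric = row.start == 1 or row.end == length
        crosses_cen = row.start < cen_start and row.end > cen_end
        if telomeric and not crosses_cen:
            count += 1
    return count


def compute_scar_scores(segments: pd.DataFrame,
                        karyotype: pd.DataFrame | None = None,
                        hrd_loh_min_length: int = HRD_LOH_MIN_LENGTH,
                        lst_min_segment: int = LST_MIN_SEGMENT,
                        lst_smooth_below: int = LST_SMOOTH_BELOW) -> ScarScores:
    """All three scar scores and their sum on one segment table."""
    if karyotype is None:
        karyotype = toy_karyotype()
    return ScarScores(
        hrd_loh=hrd_loh(segments, karyotype, min_length=hrd_loh_min_length),
        lst=lst(segments, karyotype, min_segment=lst_min_segment,
                smooth_below=lst_smooth_below),
        ntai=ntai(segments, karyotype),
    )
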
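"""Deuterium-uptake computation, overlapping-peptide region resolution, and
state difference maps.

Uptake for a peptide is the centroid-mass shift relative to the undeuterated
control.  Where two peptic peptides are nested (one a prefix- or suffix-span
of the other), subtracting the shorter from the longer localizes uptake to
the non-shared region at sub-peptide resolution — e.g. peptides 47-59 and
53-59 resolve region 48-52.  Percent deuteration is normalized by the number
of observable amides times the labeling fraction of the D2O dilution; no
back-exchange correction is applied (raw uptake is reported).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .peptides import Peptide, ProteinSequence, observable_amides

__all__ = [
    "UptakeRecord",
    "RegionUptake",
    "deuterium_uptake",
    "resolve_region_uptake",
    "state_difference_map",
]

log = logging.getLogger(__name__)

DEFAULT_LABEL_FRACTION = 0.8  # 5-fold dilution into D2O: 40/50


@dataclass
class UptakeRecord:
    """Deuterium uptake of one peptide x state x exposure time."""

    peptide_id: str
    state: str
    time_s: float
    uptake_D: float  # Da, centroid shift vs undeuterated
    percent_D: float
    sd: float = 0.0
    n_replicates: int = 1
    flagged: bool = False
    message: str = ""


@dataclass
class RegionUptake:
    """Uptake localized to a sub-peptide region by overlap subtraction."""

    start: int
    end: int
    state: str
    time_s: float
    n_amides: int
    uptake_D: float
    percent_D: float
    sd: float
    flagged: bool = False
    message: str = ""


def deuterium_uptake(centroid_t: float, centroid_undeut: float, n_amides: int,
                     label_fraction: float = DEFAULT_LABEL_FRACTION,
                     *, peptide_id: str = "", state: str = "",
                     time_s: float = 0.0, sd: float = 0.0,
                     n_replicates: int = 1) -> UptakeRecord:
    """Centroid shift -> uptake (Da) and percent of the observable maximum.

    percent_D = uptake / (n_amides * label_fraction) * 100, uncorrected for
    back-exchange.  Small negative shifts (within 2 SD) are clipped to zero
    with a warning; larger ones are flagged as inconsistent.
    """
    if not 0.0 < label_fraction <= 1.0:
        raise ValueError("label_fraction must be in (0, 1]")
    if n_amides < 1:
        raise ValueError("need at least one observable amide")
    shift = centroid_t - centroid_undeut
    flagged, msg = False, ""
    if shift < 0:
        if shift >= -2.0 * sd:
            warnings.warn(
                f"negative uptake {shift:.3f} Da within 2 SD; clipped to 0",
                stacklevel=2)
            shift = 0.0
        else:
            flagged, msg = True, (
                f"negative uptake {shift:.3f} Da beyond 2 SD ({sd:.3f})")
    pct = shift / (n_amides * label_fraction) * 100.0
    return UptakeRecord(peptide_id=peptide_id, state=state, time_s=time_s,
                        uptake_D=shift, percent_D=pct, sd=sd,
                        n_replicates=n_replicates, flagged=flagged,
                        message=msg)


def _region_span(long: Peptide, short: Peptide) -> tuple[int, int]:
    """Span of the region resolved by subtracting ``short`` from ``long``."""
    if not (long.start <= short.start and short.end <= long.end):
        raise ValueError("short peptide must be nested inside the long one")
    if (long.start, long.end) == (short.start, short.end):
        raise ValueError("peptides have identical spans; no region to resolve")
    if short.end == long.end and short.start > long.start:
        # suffix geometry, e.g. 47-59 minus 53-59 -> 48-52: the region starts
        # one past the long peptide's N-terminal residue (no observable amide
        # there) and runs to just before the short peptide's start
        return long.start + 1, short.start - 1
    if short.start == long.start and short.end < long.end:
        # prefix-extension geometry, e.g. 215-237 minus 215-230 -> 231-237
        return short.end + 1, long.end
    raise ValueError(
        "peptides must share one endpoint (prefix or suffix nesting); got "
        f"{long.start}-{long.end} vs {short.start}-{short.end}")


def resolve_region_uptake(long_pep: Peptide, long_rec: UptakeRecord,
                          short_pep: Peptide, short_rec: UptakeRecord,
                          seq: ProteinSequence,
                          label_fraction: float = DEFAULT_LABEL_FRACTION,
                          n_term_loss: int = 1) -> RegionUptake:
    """Resolve uptake in the region covered by ``long_pep`` but not ``short_pep``.

    The region's amide set is the set difference of observable amides, its
    uptake the difference of uptakes, and its SD the quadrature sum.  Region
    uptake in [-2 SD, 0) is clipped to zero with a warning; lower values are
    flagged.
    """
    if (long_rec.state, long_rec.time_s) != (short_rec.state, short_rec.time_s):
        raise ValueError("records must share state and exposure time")
    if long_pep.end - long_pep.start < short_pep.end - short_pep.start:
        long_pep, short_pep = short_pep, long_pep
        long_rec, short_rec = short_rec, long_rec
    start, end = _region_span(long_pep, short_pep)
    amides_long = set(observable_amides(long_pep, seq, n_term_loss))
    amides_short = set(observable_amides(short_pep, seq, n_term_loss))
    region_amides = sorted(amides_long - amides_short)
    n = len(region_amides)
    if n == 0:
        raise ValueError("resolved region carries no observable amide")

    uptake = long_rec.uptake_D - short_rec.uptake_D
    sd = float(np.hypot(long_rec.sd, short_rec.sd))
    flagged, msg = False, ""
    if uptake < 0:
        if uptake >= -2.0 * sd:
            warnings.warn(
                f"negative region uptake {uptake:.3f} Da within 2 SD; clipped",
                stacklevel=2)
            uptake = 0.0
        else:
            flagged, msg = True, (
                f"negative region uptake {uptake:.3f} Da beyond 2 SD")
    pct = uptake / (n * label_fraction) * 100.0
    return RegionUptake(start=start, end=end, state=long_rec.state,
                        time_s=long_rec.time_s, n_amides=n, uptake_D=uptake,
                        percent_D=pct, sd=sd, flagged=flagged, message=msg)


def state_difference_map(records_a: list[UptakeRecord],
                         records_b: list[UptakeRecord],
                         time_s: float | None = None) -> pd.DataFrame:
    """Per-peptide delta %D between two states (positive = more exchange in a).

    Rows are matched on (peptide_id, time_s); SDs combine in quadrature.
    Peptides present in only one state are excluded and logged.
    """
    def frame(recs, suffix):
        return pd.DataFrame(
            [{"peptide_id": r.peptide_id, "time_s": r.time_s,
              f"percent_D_{suffix}": r.percent_D, f"sd_{suffix}": r.sd}
             for r in recs if time_s is None or r.time_s == time_s])

    a, b = frame(records_a, "a"), frame(records_b, "b")
    if a.empty or b.empty:
        raise ValueError("no records at the requested exposure time")
    merged = a.merge(b, on=["peptide_id", "time_s"], how="outer", indicator=True)
    dropped = merged.loc[merged["_merge"] != "both", "peptide_id"].tolist()
    for pid in dropped:
        log.warning("peptide %s missing in one state; excluded from map", pid)
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    # uptake percentages are in the same normalization on both sides, so the
    # state difference is a plain subtraction with quadrature errors
    merged["delta_percent_D"] = merged["percent_D_a"] - merged["percent_D_b"]
    merged["delta_sd"] = np.hypot(merged["sd_a"], merged["sd_b"])
    return merged.reset_index(drop=True)
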
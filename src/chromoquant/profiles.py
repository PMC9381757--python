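"""Chromocenter midline profiles and the DAPI-marker PCC enrichment score.

The central statistic of the package: a fluorescence intensity profile is
sampled across a chromocenter midline, the chromocenter is delineated on the
DAPI profile as the bell-shaped run of values above the profile mean, and
the Pearson correlation coefficient (PCC) between DAPI and a marker channel
is computed over the delineated segment.  A PCC near 1 means the marker
accumulates at the chromocenter in proportion to DNA density; values near 0
indicate a diffuse marker, and negative values marker exclusion.

Conventions (the source protocol leaves these open, so they are fixed here):

* the delineation threshold is the arithmetic mean of the DAPI values over
  the extracted line profile — not over the nucleus or the whole image;
* comparison with the threshold is strictly greater, so a flat profile
  yields no chromocenter;
* one segment per profile: the contiguous above-mean run containing the
  global DAPI maximum; other above-mean runs are counted but ignored;
* profiles are sampled by bilinear interpolation at half the smaller
  in-plane pixel pitch, on a single z-plane for 3D input;
* no smoothing or background subtraction is applied before the PCC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from chromoquant.image import ImageStack

__all__ = [
    "LineProfile",
    "ChromocenterSegment",
    "PCCRecord",
    "extract_profile",
    "delineate_chromocenter",
    "pcc_enrichment",
    "summarize_pcc",
]

logger = logging.getLogger(__name__)

STAGES = (
    "2-cell", "4-cell", "8-cell", "16-cell",
    "E3.25", "E3.5", "E4.0", "E4.25", "E4.5", "E5.5",
    "ESC", "EpiLC", "EpiSC", "none",
)
LINEAGES = ("EPI", "PrE", "TE", "ICM", "ExE", "none")


@dataclass
class LineProfile:
    """A 1D multi-channel intensity trace along a sampled line.

    ``positions`` are µm along the line, centred so the requested line
    center sits at 0; ``intensity`` maps channel name to the sampled values,
    one per position, identical sampling grid for all channels.
    """

    positions: np.ndarray
    intensity: dict[str, np.ndarray]
    line_endpoints: tuple[tuple[float, ...], tuple[float, ...]]
    source_plane: int | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.size < 5:
            raise ValueError("profile must have at least 5 samples")
        if not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        for name, vals in self.intensity.items():
            vals = np.asarray(vals, dtype=np.float64)
            if vals.shape != self.positions.shape:
                raise ValueError(f"channel {name!r} length differs from positions")
            self.intensity[name] = vals

    def __len__(self) -> int:
        return self.positions.size

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.intensity[name]
        except KeyError:
            raise KeyError(
                f"profile has no channel {name!r}; available: {list(self.intensity)}"
            ) from None


@dataclass
class ChromocenterSegment:
    """The delineated chromocenter: an above-mean bell on the DAPI profile.

    ``start_index``/``end_index`` are inclusive bounds on the profile,
    ``threshold`` the profile-mean DAPI value used, ``peak_index`` the
    global DAPI maximum (contained in the segment).  ``n_ignored_runs``
    counts other above-mean runs that were not the one containing the peak.
    """

    start_index: int
    end_index: int
    threshold: float
    peak_index: int
    n_ignored_runs: int = 0

    def __post_init__(self) -> None:
        if not self.start_index <= self.peak_index <= self.end_index:
            raise ValueError("peak index must lie inside the segment")

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1

    @property
    def slice(self) -> slice:
        return slice(self.start_index, self.end_index + 1)


@dataclass
class PCCRecord:
    """One chromocenter's DAPI-vs-marker Pearson coefficient with metadata."""

    pcc: float
    marker: str
    chromocenter_id: str = ""
    nucleus_id: str = ""
    embryo_id: str = ""
    stage: str = "none"
    lineage: str = "none"
    undefined: bool = False

    def __post_init__(self) -> None:
        if not self.undefined and not -1 - 1e-12 <= self.pcc <= 1 + 1e-12:
            raise ValueError(f"PCC {self.pcc} outside [-1, 1]")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}; expected one of {LINEAGES}")

    def to_row(self) -> dict:
        return {
            "pcc": self.pcc,
            "marker": self.marker,
            "chromocenter_id": self.chromocenter_id,
            "nucleus_id": self.nucleus_id,
            "embryo_id": self.embryo_id,
            "stage": self.stage,
            "lineage": self.lineage,
            "undefined": self.undefined,
        }


def extract_profile(
    image: ImageStack,
    center: Sequence[float],
    direction: Sequence[float] = (0.0, 1.0),
    half_length: float = 2.5,
    channels: Sequence[str] | None = None,
) -> LineProfile:
    """Sample intensity profiles along a line through ``center``.

    Parameters
    ----------
    image
        The image; 2D, or 3D in which case ``center`` must carry a z
        coordinate and the line is sampled within that plane.
    center
        Pixel coordinates ``(y, x)`` or ``(z, y, x)`` of the chromocenter
        center (position 0 of the profile).
    direction
        In-plane direction ``(dy, dx)`` in physical (µm) space; normalised
        internally. Defaults to the image x-axis.
    half_length
        Half the profile length in µm; must be positive.
    channels
        Channel names to sample (default: all).

    The sampling step is half the smaller in-plane pixel pitch and identical
    for every channel; values are bilinearly interpolated.  Samples falling
    outside the image are trimmed and the profile flagged ``truncated``.
    """
    if half_length <= 0:
        raise ValueError("half_length must be positive")
    if channels is None:
        channels = image.channel_names
    for name in channels:
        image.channel(name)  # raises on unknown channel

    center = np.asarray(center, dtype=np.float64)
    source_plane: int | None = None
    if image.ndim == 3:
        if center.size != 3:
            raise ValueError("3D image requires a (z, y, x) center")
        source_plane = int(round(center[0]))
        if not 0 <= source_plane < image.shape[0]:
            raise ValueError(f"source plane {source_plane} outside the stack")
        center_yx = center[1:]
    else:
        if center.size != 2:
            raise ValueError("2D image requires a (y, x) center")
        center_yx = center

    d = np.asarray(direction, dtype=np.float64)
    if d.size != 2 or not np.any(d):
        raise ValueError("direction must be a non-zero in-plane (dy, dx) vector")
    d = d / np.linalg.norm(d)

    pitch_yx = np.asarray(image.voxel_size[-2:])
    step = image.in_plane_pitch() / 2.0
    n_half = int(np.floor(half_length / step))
    positions = np.arange(-n_half, n_half + 1) * step
    # physical displacement -> pixel displacement per axis
    coords_yx = center_yx[:, None] + (d[:, None] * positions[None, :]) / pitch_yx[:, None]

    in_y = (coords_yx[0] >= 0) & (coords_yx[0] <= image.shape[-2] - 1)
    in_x = (coords_yx[1] >= 0) & (coords_yx[1] <= image.shape[-1] - 1)
    keep = in_y & in_x
    truncated = not keep.all()
    if truncated:
        # keep the maximal contiguous in-bounds run containing position 0
        center_idx = n_half
        if not keep[center_idx]:
            raise ValueError("profile center lies outside the image")
        lo = center_idx
        while lo > 0 and keep[lo - 1]:
            lo -= 1
        hi = center_idx
        while hi < keep.size - 1 and keep[hi + 1]:
            hi += 1
        positions = positions[lo : hi + 1]
        coords_yx = coords_yx[:, lo : hi + 1]
        logger.warning("profile truncated to %d samples at the image border", positions.size)

    intensity = {}
    for name in channels:
        arr = image.channel(name)
        plane = arr[source_plane] if image.ndim == 3 else arr
        intensity[name] = ndimage.map_coordinates(plane, coords_yx, order=1, mode="nearest")

    start = tuple(coords_yx[:, 0])
    end = tuple(coords_yx[:, -1])
    return LineProfile(
        positions=positions,
        intensity=intensity,
        line_endpoints=(start, end),
        source_plane=source_plane,
        truncated=truncated,
    )


def delineate_chromocenter(
    profile: LineProfile, dapi_channel: str = "DAPI"
) -> ChromocenterSegment | None:
    """Delineate the chromocenter on the DAPI profile.

    The threshold is the arithmetic mean of the DAPI values over the whole
    profile.  The segment is the maximal contiguous run of samples strictly
    above the threshold that contains the global DAPI maximum.  Returns
    ``None`` ("no chromocenter") when no sample exceeds the mean — e.g. a
    flat profile — which is a valid result, not a failure.
    """
    dapi = profile.channel(dapi_channel)
    threshold = float(dapi.mean())
    above = dapi > threshold
    if not above.any():
        return None
    peak = int(np.argmax(dapi))
    if not above[peak]:  # cannot happen: the max always exceeds the mean unless flat
        return None
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < above.size - 1 and above[hi + 1]:
        hi += 1
    # count disjoint above-threshold runs other than the selected one
    runs = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))) == 1)
    n_ignored = len(runs) - 1
    if n_ignored:
        logger.info("ignored %d above-mean runs not containing the DAPI maximum", n_ignored)
    return ChromocenterSegment(
        start_index=int(lo),
        end_index=int(hi),
        threshold=threshold,
        peak_index=peak,
        n_ignored_runs=n_ignored,
    )


def pcc_enrichment(
    profile: LineProfile,
    segment: ChromocenterSegment,
    marker_channel: str,
    dapi_channel: str = "DAPI",
    metadata: Mapping[str, str] | None = None,
) -> PCCRecord:
    """Pearson correlation between DAPI and a marker over the segment.

    Requires at least 3 samples in the segment.  Zero variance of either
    channel over the segment yields an ``undefined`` record (``pcc`` NaN),
    reported rather than silently 0, and excluded from summaries.
    """
    if len(segment) < 3:
        raise ValueError(f"segment has {len(segment)} samples; need at least 3")
    dapi = profile.channel(dapi_channel)[segment.slice]
    marker = profile.channel(marker_channel)[segment.slice]
    meta = dict(metadata or {})
    if dapi.std() == 0 or marker.std() == 0:
        return PCCRecord(pcc=float("nan"), marker=marker_channel, undefined=True, **meta)
    pcc = float(np.corrcoef(dapi, marker)[0, 1])
    pcc = min(1.0, max(-1.0, pcc))
    return PCCRecord(pcc=pcc, marker=marker_channel, **meta)


def summarize_pcc(
    records: Iterable[PCCRecord],
    group_by: Sequence[str] = ("stage", "lineage", "marker"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution summary per group plus a long-format table for violins.

    Returns ``(summary, long)``: ``summary`` has one row per group with n,
    median, quartiles, min, max and the number of undefined records
    excluded; ``long`` has one row per valid chromocenter, ready for violin
    plotting.  Empty groups are omitted (they have no rows to begin with).
    """
    rows = [r.to_row() for r in records]
    if not rows:
        raise ValueError("summarize_pcc requires at least one record")
    df = pd.DataFrame(rows)
    group_by = list(group_by)
    n_undef = df.groupby(group_by, observed=True)["undefined"].sum()
    valid = df[~df["undefined"]].drop(columns="undefined")
    if valid.empty:
        logger.warning("all %d records undefined; empty summary", len(df))
        summary = pd.DataFrame(
            columns=group_by + ["n", "median", "q1", "q3", "min", "max", "n_undefined"]
        )
        return summary, valid

    g = valid.groupby(group_by, observed=True)["pcc"]
    summary = g.agg(
        n="count",
        median="median",
        q1=lambda s: s.quantile(0.25),
        q3=lambda s: s.quantile(0.75),
        min="min",
        max="max",
    ).reset_index()
    undef = n_undef.rename("n_undefined").reset_index()
    summary = summary.merge(undef, on=group_by, how="left")
    summary["n_undefined"] = summary["n_undefined"].fillna(0).astype(int)
    return summary, valid.reset_index(drop=True)
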
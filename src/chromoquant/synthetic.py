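"""Synthetic microscopy images and sequencing reads with known ground truth.

Real inputs for this kind of analysis are confocal/apotome stacks of embryo
nuclei and public FASTQ archives; neither is convenient for automated tests.
This module generates stand-ins with planted, recorded truth:

* nuclei whose DAPI channel carries bright chromocenter foci and whose
  marker channel follows one of three enrichment modes — ``colocalized``
  (marker foci coincide with DAPI foci, the 16-cell-like pattern),
  ``cloudy`` (marker accumulates in and around the focus with a local dip at
  the DAPI peak, the 2-cell-like pattern), and ``diffuse`` (spatially
  uniform marker, the post-implantation-like pattern);
* nuclei with a planted number of FISH transcription foci;
* FASTQ files with a planted fraction of reads carrying major-satellite
  motifs, optionally bisulfite-converted with planted per-cytosine
  methylation states.

Everything is deterministic under ``(spec, seed)``: one root seed is split
into named substreams, and the truth sidecar records every planted object.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from chromoquant.image import ImageStack, LabeledMask
from chromoquant.satellites import SATELLITE_MOTIFS

__all__ = [
    "SyntheticNucleusSpec",
    "SyntheticFociSpec",
    "SyntheticReadSpec",
    "NucleusTruth",
    "FociTruth",
    "ReadTruth",
    "GenerationError",
    "generate_nucleus_image",
    "generate_fish_image",
    "generate_fastq",
]

MarkerMode = Literal["colocalized", "cloudy", "diffuse"]


class GenerationError(RuntimeError):
    """Raised when a spec cannot be realised (e.g. foci cannot be placed)."""


def _rng_streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    """Named independent substreams from one root seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# --------------------------------------------------------------------------
# Nucleus images with chromocenters
# --------------------------------------------------------------------------


@dataclass
class SyntheticNucleusSpec:
    """Parameters of one synthetic nucleus image.

    Defaults describe a single 2D confocal section of a mouse pre-implantation
    blastomere nucleus at 63x: 0.1 µm pixels, a 5 µm nucleus containing a few
    chromocenters of ~1 µm radius whose DAPI peak is three-fold brighter than
    the nucleoplasm. ``noise_sd`` is additive Gaussian detector noise in
    intensity counts; ``poisson_scale > 0`` adds a shot-noise component with
    variance proportional to the signal.
    """

    image_shape: tuple[int, ...] = (160, 160)
    voxel_size: tuple[float, ...] = (0.1, 0.1)
    bit_depth: int = 16
    nucleus_radius: float = 5.0
    n_chromocenters: int = 4
    chromocenter_radius_range: tuple[float, float] = (0.7, 1.2)
    dapi_focus_contrast: float = 3.0
    marker_mode: MarkerMode = "colocalized"
    cloudy_ring_width: float = 0.8
    # Radial position of the cloudy shell as a fraction of the focus radius.
    # At 0.4 the cloud stays concentrated in and around the DAPI-dense core:
    # the midline marker profile is bimodal with a shallow dip at the DAPI
    # peak and the cross-profile PCC lands in the weakly-positive range of
    # the 2-cell-like phenotype, between the colocalized and diffuse modes.
    cloudy_shell_position: float = 0.4
    noise_sd: float = 200.0
    poisson_scale: float = 0.0
    nucleoplasm_level: float = 2000.0
    marker_baseline: float = 500.0
    marker_gain: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) not in (2, 3):
            raise ValueError("image_shape must be 2D or 3D")
        if len(self.voxel_size) != len(self.image_shape):
            raise ValueError("voxel_size must match image dimensionality")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if self.dapi_focus_contrast <= 1:
            raise ValueError("dapi_focus_contrast must exceed 1")
        if self.marker_mode not in ("colocalized", "cloudy", "diffuse"):
            raise ValueError(f"unknown marker_mode {self.marker_mode!r}")
        lo, hi = self.chromocenter_radius_range
        if not (0 < lo <= hi):
            raise ValueError("chromocenter_radius_range must be a positive interval")
        extent = [s * v / 2 for s, v in zip(self.image_shape, self.voxel_size)]
        if self.nucleus_radius > min(extent):
            raise ValueError(
                f"nucleus radius {self.nucleus_radius} µm does not fit in the "
                f"image half-extent {min(extent):.2f} µm"
            )
        peak = self.nucleoplasm_level * self.dapi_focus_contrast
        if peak + 5 * self.noise_sd > 2**self.bit_depth - 1:
            raise ValueError("intensities not representable at bit_depth")


@dataclass
class NucleusTruth:
    """Planted ground truth for one synthetic nucleus image."""

    nucleus_mask: np.ndarray
    nucleus_center_px: tuple[float, ...]
    centroids_px: list[tuple[float, ...]]
    centroids_um: list[tuple[float, ...]]
    radii_um: list[float]
    sigmas_um: list[float]
    marker_mode: str
    seed: int

    @property
    def n_chromocenters(self) -> int:
        return len(self.centroids_px)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (cpx, cum, r, s) in enumerate(
            zip(self.centroids_px, self.centroids_um, self.radii_um, self.sigmas_um)
        ):
            rows.append(
                {
                    "chromocenter_id": i,
                    **{f"center_px_{ax}": c for ax, c in zip("zyx"[-len(cpx):], cpx)},
                    **{f"center_um_{ax}": c for ax, c in zip("zyx"[-len(cum):], cum)},
                    "radius_um": r,
                    "sigma_um": s,
                    "marker_mode": self.marker_mode,
                    "seed": self.seed,
                }
            )
        return pd.DataFrame(rows)


def _coordinate_grid_um(shape, voxel_size):
    """Physical coordinates (µm) of every voxel center, origin at image center."""
    axes = [
        (np.arange(n, dtype=np.float64) - (n - 1) / 2) * v
        for n, v in zip(shape, voxel_size)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _place_foci(
    rng: np.random.Generator,
    n: int,
    nucleus_radius: float,
    radii: np.ndarray,
    max_attempts: int = 2000,
    ndim: int = 2,
) -> np.ndarray:
    """Rejection-sample non-overlapping focus centers inside the nucleus."""
    centers: list[np.ndarray] = []
    for i in range(n):
        r_i = radii[i]
        limit = nucleus_radius - r_i
        if limit <= 0:
            raise GenerationError(
                f"chromocenter radius {r_i:.2f} µm does not fit inside the nucleus"
            )
        for _ in range(max_attempts):
            c = rng.uniform(-limit, limit, size=ndim)
            if np.linalg.norm(c) > limit:
                continue
            if all(
                np.linalg.norm(c - cj) > r_i + radii[j] for j, cj in enumerate(centers)
            ):
                centers.append(c)
                break
        else:
            raise GenerationError(
                f"could not place chromocenter {i + 1}/{n} without overlap after "
                f"{max_attempts} attempts (nucleus_radius={nucleus_radius}, radii={radii})"
            )
    return np.array(centers).reshape(n, ndim)


def generate_nucleus_image(
    spec: SyntheticNucleusSpec,
) -> tuple[ImageStack, NucleusTruth]:
    """Render a DAPI + marker nucleus image with planted chromocenters.

    The DAPI channel is a uniform nucleoplasm plus one isotropic Gaussian per
    chromocenter (``sigma = radius / 2``) whose peak reaches
    ``dapi_focus_contrast`` times the nucleoplasm level.  The marker channel
    depends on ``marker_mode``:

    ``colocalized``
        an exact positive affine transform of the DAPI signal inside the
        nucleus, so the noiseless cross-profile PCC is 1;
    ``cloudy``
        per focus, a Gaussian shell centred at ``cloudy_shell_position``
        times the focus radius, giving a bimodal midline profile with a
        local minimum at the DAPI peak;
    ``diffuse``
        spatially uniform over the nucleus.

    Returns the image and a :class:`NucleusTruth` listing every planted
    centroid and radius. Deterministic in ``(spec, spec.seed)``.
    """
    streams = _rng_streams(spec.seed, ["geometry", "noise"])
    ndim = len(spec.image_shape)
    grid = _coordinate_grid_um(spec.image_shape, spec.voxel_size)
    r_nuc = np.sqrt(sum(g**2 for g in grid))
    nucleus_mask = r_nuc <= spec.nucleus_radius

    lo, hi = spec.chromocenter_radius_range
    radii = streams["geometry"].uniform(lo, hi, size=spec.n_chromocenters)
    centers = _place_foci(
        streams["geometry"], spec.n_chromocenters, spec.nucleus_radius, radii, ndim=ndim
    )

    amp = spec.nucleoplasm_level * (spec.dapi_focus_contrast - 1.0)
    dapi = np.zeros(spec.image_shape, dtype=np.float64)
    dapi[nucleus_mask] = spec.nucleoplasm_level
    foci_sum = np.zeros_like(dapi)
    shell_sum = np.zeros_like(dapi)
    sigmas = radii / 2.0
    for c, r_i, s_i in zip(centers, radii, sigmas):
        d2 = sum((g - ci) ** 2 for g, ci in zip(grid, c))
        foci_sum += np.exp(-d2 / (2 * s_i**2))
        if spec.marker_mode == "cloudy":
            d = np.sqrt(d2)
            s_shell = spec.cloudy_ring_width / 2.0
            rho = spec.cloudy_shell_position * r_i
            shell_sum += np.exp(-((d - rho) ** 2) / (2 * s_shell**2))
    dapi += amp * foci_sum * nucleus_mask

    marker = np.zeros_like(dapi)
    if spec.marker_mode == "colocalized":
        marker[nucleus_mask] = spec.marker_baseline + spec.marker_gain * (
            dapi[nucleus_mask] - spec.nucleoplasm_level
        )
    elif spec.marker_mode == "cloudy":
        marker[nucleus_mask] = (
            spec.marker_baseline + spec.marker_gain * amp * shell_sum[nucleus_mask]
        )
    else:  # diffuse
        marker[nucleus_mask] = spec.marker_baseline + spec.marker_gain * amp * 0.5

    vmax = float(2**spec.bit_depth - 1)
    channels = {}
    for name, clean in (("DAPI", dapi), ("marker", marker)):
        img = clean.copy()
        if spec.poisson_scale > 0:
            img = streams["noise"].poisson(
                np.maximum(img / spec.poisson_scale, 0)
            ).astype(np.float64) * spec.poisson_scale
        if spec.noise_sd > 0:
            img = img + streams["noise"].normal(0.0, spec.noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0, vmax)

    image = ImageStack(channels=channels, voxel_size=spec.voxel_size, bit_depth=spec.bit_depth)
    center_px = tuple((n - 1) / 2 for n in spec.image_shape)
    centroids_px = [
        tuple(cp + ci / v for cp, ci, v in zip(center_px, c, spec.voxel_size))
        for c in centers
    ]
    truth = NucleusTruth(
        nucleus_mask=nucleus_mask,
        nucleus_center_px=center_px,
        centroids_px=centroids_px,
        centroids_um=[tuple(c) for c in centers],
        radii_um=[float(r) for r in radii],
        sigmas_um=[float(s) for s in sigmas],
        marker_mode=spec.marker_mode,
        seed=spec.seed,
    )
    return image, truth


# --------------------------------------------------------------------------
# FISH foci images
# --------------------------------------------------------------------------


@dataclass
class SyntheticFociSpec:
    """Parameters for a FISH-foci image: one nucleus tile per planted count.

    ``n_foci_per_nucleus`` is the ground truth; each focus is an isotropic
    Gaussian spot of peak amplitude ``focus_amplitude`` (counts above the
    intracellular background) and width ``focus_sigma`` (µm).  Foci are kept
    at least ``4 * focus_sigma`` apart so that counts remain well defined.
    """

    n_foci_per_nucleus: Sequence[int] = (0, 1, 2, 3, 4, 5)
    focus_amplitude: float = 6000.0
    focus_sigma: float = 0.3
    noise_sd: float = 200.0
    nucleus_radius: float = 4.0
    tile_px: int = 96
    pixel_um: float = 0.1
    dapi_level: float = 3000.0
    fish_background: float = 500.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_foci_per_nucleus):
            raise ValueError("foci counts must be non-negative")
        if self.nucleus_radius * 2 >= self.tile_px * self.pixel_um:
            raise ValueError("nucleus does not fit in its tile")


@dataclass
class FociTruth:
    """Planted FISH foci, one row per focus, plus per-nucleus counts."""

    table: pd.DataFrame  # columns: nucleus_id, y_px, x_px
    counts: dict[int, int]


def generate_fish_image(
    spec: SyntheticFociSpec,
) -> tuple[ImageStack, LabeledMask, FociTruth]:
    """Render a DAPI + FISH image with the planted number of foci per nucleus.

    Nuclei are disks laid out on a grid of square tiles, labeled 1..n in the
    returned mask.  The FISH channel carries exactly the planted spots plus
    Gaussian noise; a warning is recorded (image still produced) when
    ``focus_amplitude < 5 * noise_sd``, the documented detectability bound.
    """
    if spec.noise_sd > 0 and spec.focus_amplitude < 5 * spec.noise_sd:
        warnings.warn(
            f"focus_amplitude {spec.focus_amplitude} is below 5x noise_sd "
            f"{spec.noise_sd}: planted foci may not be detectable",
            stacklevel=2,
        )
    streams = _rng_streams(spec.seed, ["geometry", "noise"])
    n_nuclei = len(spec.n_foci_per_nucleus)
    ncols = int(np.ceil(np.sqrt(n_nuclei)))
    nrows = int(np.ceil(n_nuclei / ncols))
    shape = (nrows * spec.tile_px, ncols * spec.tile_px)

    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    labels = np.zeros(shape, dtype=np.int32)
    dapi = np.zeros(shape, dtype=np.float64)
    fish = np.zeros(shape, dtype=np.float64)
    rows = []
    r_px = spec.nucleus_radius / spec.pixel_um
    sigma_px = spec.focus_sigma / spec.pixel_um
    min_sep_px = 4 * sigma_px

    for i, n_foci in enumerate(spec.n_foci_per_nucleus):
        cy = (i // ncols) * spec.tile_px + spec.tile_px / 2
        cx = (i % ncols) * spec.tile_px + spec.tile_px / 2
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        labels[disk] = i + 1
        dapi[disk] = spec.dapi_level
        fish[disk] = spec.fish_background
        # place foci with a minimum separation; margin keeps the whole spot inside
        placed: list[np.ndarray] = []
        limit = r_px - 3 * sigma_px
        if n_foci > 0 and limit <= 0:
            raise GenerationError("focus size incompatible with nucleus radius")
        for j in range(n_foci):
            for _ in range(2000):
                offset = streams["geometry"].uniform(-limit, limit, size=2)
                if np.linalg.norm(offset) > limit:
                    continue
                if all(np.linalg.norm(offset - p) > min_sep_px for p in placed):
                    placed.append(offset)
                    break
            else:
                raise GenerationError(
                    f"could not place focus {j + 1}/{n_foci} in nucleus {i + 1}"
                )
            fy, fx = cy + placed[-1][0], cx + placed[-1][1]
            fish += spec.focus_amplitude * np.exp(
                -((yy - fy) ** 2 + (xx - fx) ** 2) / (2 * sigma_px**2)
            )
            rows.append({"nucleus_id": i + 1, "y_px": fy, "x_px": fx})

    vmax = float(2**spec.bit_depth - 1)
    if spec.noise_sd > 0:
        dapi = dapi + streams["noise"].normal(0, spec.noise_sd, size=shape)
        fish = fish + streams["noise"].normal(0, spec.noise_sd, size=shape)
    image = ImageStack(
        channels={"DAPI": np.clip(dapi, 0, vmax), "FISH": np.clip(fish, 0, vmax)},
        voxel_size=(spec.pixel_um, spec.pixel_um),
        bit_depth=spec.bit_depth,
    )
    table = pd.DataFrame(rows, columns=["nucleus_id", "y_px", "x_px"])
    counts = {i + 1: int(n) for i, n in enumerate(spec.n_foci_per_nucleus)}
    return image, LabeledMask(labels, image.voxel_size), FociTruth(table, counts)


# --------------------------------------------------------------------------
# FASTQ with planted satellite reads
# --------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticReadSpec:
    """Parameters for a synthetic FASTQ file.

    Each read is independently satellite-bearing with probability
    ``satellite_fraction``; a satellite read embeds one of the eight
    major-satellite motifs verbatim (pre-conversion) at a uniformly chosen
    offset, with the remainder drawn from ``background_composition``.
    Background reads are rejection-sampled to be motif-free, so planted
    counts are exact truth.  In bisulfite mode every C is kept (methylated,
    probability ``methylation_rate``) or otherwise converted to T with
    probability ``conversion_efficiency``.
    """

    n_reads: int = 10_000
    read_length: int = 50
    satellite_fraction: float = 0.1
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    bisulfite: bool = False
    methylation_rate: float = 0.8
    conversion_efficiency: float = 0.99
    seed: int = 0

    def __post_init__(self) -> None:
        longest = max(len(m) for m in SATELLITE_MOTIFS)
        if self.read_length < longest:
            raise ValueError(
                f"read_length {self.read_length} < longest motif ({longest} bp); "
                "cannot embed a motif intact"
            )
        for name in ("satellite_fraction", "methylation_rate", "conversion_efficiency"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.background_composition) - 1.0) > 1e-9:
            raise ValueError("background_composition must sum to 1")


@dataclass
class ReadTruth:
    """Planted truth for one synthetic FASTQ file."""

    n_reads: int
    n_satellite_planted: int
    per_read: pd.DataFrame  # read_id, is_satellite, motif_index, offset
    # bisulfite site bookkeeping over planted motif occurrences
    n_motif_c_sites: int = 0
    n_motif_c_converted: int = 0
    n_c_total: int = 0
    n_c_converted: int = 0

    def to_frame(self) -> pd.DataFrame:
        return self.per_read


def _random_seq(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(_BASES[rng.choice(4, size=length, p=list(probs))])


def generate_fastq(spec: SyntheticReadSpec, path) -> ReadTruth:
    """Write a synthetic FASTQ file and return its planted truth.

    Quality strings are constant ``'I'`` (Phred 40); the downstream assays
    ignore qualities.  Deterministic in ``(spec, spec.seed)``.
    """
    streams = _rng_streams(spec.seed, ["assign", "background", "embed", "bisulfite"])
    motifs = list(SATELLITE_MOTIFS)
    is_sat = streams["assign"].random(spec.n_reads) < spec.satellite_fraction

    records = []
    rows = []
    n_motif_c_sites = n_motif_c_conv = n_c_total = n_c_conv = 0
    qual = [40] * spec.read_length
    for i in range(spec.n_reads):
        if is_sat[i]:
            m_idx = int(streams["embed"].integers(len(motifs)))
            motif = motifs[m_idx]
            offset = int(streams["embed"].integers(spec.read_length - len(motif) + 1))
            left = _random_seq(streams["embed"], offset, spec.background_composition)
            right = _random_seq(
                streams["embed"],
                spec.read_length - offset - len(motif),
                spec.background_composition,
            )
            seq = left + motif + right
        else:
            m_idx, offset = -1, -1
            for _ in range(1000):
                seq = _random_seq(
                    streams["background"], spec.read_length, spec.background_composition
                )
                if not any(m in seq for m in motifs):
                    break
            else:  # pragma: no cover
                raise GenerationError("could not draw a motif-free background read")

        if spec.bisulfite:
            chars = list(seq)
            c_positions = [p for p, b in enumerate(chars) if b == "C"]
            if c_positions:
                meth = streams["bisulfite"].random(len(c_positions)) < spec.methylation_rate
                conv = streams["bisulfite"].random(len(c_positions)) < spec.conversion_efficiency
                motif_c = set()
                if m_idx >= 0:
                    motif_c = {
                        offset + j for j, b in enumerate(motifs[m_idx]) if b == "C"
                    }
                for p, m_flag, c_flag in zip(c_positions, meth, conv):
                    converted = (not m_flag) and c_flag
                    if converted:
                        chars[p] = "T"
                    n_c_total += 1
                    n_c_conv += converted
                    if p in motif_c:
                        n_motif_c_sites += 1
                        n_motif_c_conv += converted
                seq = "".join(chars)

        rec = SeqRecord(Seq(seq), id=f"read_{i}", description="")
        rec.letter_annotations["phred_quality"] = qual
        records.append(rec)
        rows.append(
            {
                "read_id": f"read_{i}",
                "is_satellite": bool(is_sat[i]),
                "motif_index": m_idx,
                "offset": offset,
            }
        )

    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")

    return ReadTruth(
        n_reads=spec.n_reads,
        n_satellite_planted=int(is_sat.sum()),
        per_read=pd.DataFrame(rows),
        n_motif_c_sites=n_motif_c_sites,
        n_motif_c_converted=n_motif_c_conv,
        n_c_total=n_c_total,
        n_c_converted=n_c_conv,
    )
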
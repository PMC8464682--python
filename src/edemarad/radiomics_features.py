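"""The 253-feature bank: semantic pass-through, first-order histogram
statistics, LBP-TOP texture codes, and sparse 3D-GLCM features.

The bank deliberately works on the raw 16-bit gray levels — no rebinning or
gray-level reduction is applied anywhere.  The intensity histogram therefore
has 2**16 identity bins, and co-occurrence tables are held sparsely (only
observed gray-level pairs are stored) so that 65536x65536 matrices are never
materialized.

Feature blocks and canonical order
----------------------------------
* 11 semantic features (``sem_*``): clinical/visual descriptors passed
  through numerically encoded;
* 12 first-order features (``fo_*``): statistics of the ROI intensity
  histogram;
* 48 LBP-TOP features (``lbp_<variant>_<stat>``): the same 12 statistics
  applied to the concatenated three-orthogonal-plane code histograms of four
  local-binary-pattern variants (basic, rotation-invariant, uniform,
  rotation-invariant-uniform);
* 182 GLCM features (``glcm_<dir>_<stat>``): 7 statistics per each of the 26
  directed unit offsets of the 3D neighborhood (interpixel distance 1).

Total: 11 + 12 + 48 + 182 = 253.  Order and names are frozen in the
``feature_manifest.json`` shipped with the package.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from itertools import product
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .roi_geometry import EmptyMaskError, RoiMask, VoxelVolume, MAX_GRAY

logger = logging.getLogger(__name__)

__all__ = [
    "N_BINS",
    "GLCM_DIRECTIONS",
    "LBP_VARIANTS",
    "LBP_PLANES",
    "FIRST_ORDER_STATS",
    "GLCM_STATS",
    "SEMANTIC_FIELDS",
    "IntensityHistogram",
    "PairCountTable",
    "FeatureVector",
    "intensity_histogram",
    "first_order_features",
    "lbp_plane_codes",
    "lbp_top_features",
    "glcm_pairs",
    "glcm_features",
    "extract_all",
    "feature_names",
    "feature_manifest",
]

N_BINS = MAX_GRAY + 1  # 2**16 identity bins

#: the 26 directed unit offsets, lexicographic over (dz, dy, dx)
GLCM_DIRECTIONS: Tuple[Tuple[int, int, int], ...] = tuple(
    d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)
)

LBP_VARIANTS = ("basic", "ri", "u2", "riu2")
LBP_PLANES = ("XY", "XZ", "YZ")

FIRST_ORDER_STATS = (
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "energy",
    "entropy",
    "max",
    "max_position",
    "max_energy",
    "range",
    "n_rel_max",
    "rel_max_energy",
)

GLCM_STATS = (
    "autocorr",
    "covariance",
    "inertia",
    "abs_inertia",
    "inv_inertia",
    "energy",
    "entropy",
)

SEMANTIC_FIELDS = (
    "age",
    "menopause",
    "family_history",
    "hormone_therapy",
    "location",
    "stadiation",
    "margins",
    "dimensions",
    "morphology",
    "kinetic_curve",
    "edema_type",
)


# ---------------------------------------------------------------------------
# canonical feature names
# ---------------------------------------------------------------------------


def feature_names() -> List[str]:
    """The canonical ordered list of all 253 feature names."""
    names = [f"sem_{f}" for f in SEMANTIC_FIELDS]
    names += [f"fo_{s}" for s in FIRST_ORDER_STATS]
    for variant in LBP_VARIANTS:
        names += [f"lbp_{variant}_{s}" for s in FIRST_ORDER_STATS]
    for d in range(len(GLCM_DIRECTIONS)):
        names += [f"glcm_{d:02d}_{s}" for s in GLCM_STATS]
    return names


def feature_manifest() -> dict:
    """The frozen feature manifest shipped with the package."""
    with resources.files(__package__).joinpath("feature_manifest.json").open() as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# intensity histogram and first-order statistics
# ---------------------------------------------------------------------------


@dataclass
class IntensityHistogram:
    """Sparse identity-binned histogram over the 16-bit gray range.

    Only non-empty bins are stored: ``bin_values[k]`` is a gray level and
    ``counts[k]`` the number of ROI voxels at exactly that level.
    """

    bin_values: np.ndarray
    counts: np.ndarray
    n_bins: int = N_BINS

    def __post_init__(self) -> None:
        self.bin_values = np.asarray(self.bin_values, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.bin_values) != len(self.counts):
            raise ValueError("bin_values and counts must align")
        if np.any(self.counts <= 0):
            raise ValueError("stored bins must have positive counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.total


def intensity_histogram(volume: VoxelVolume, mask: RoiMask) -> IntensityHistogram:
    """Identity-binned histogram of the ROI intensities (no gray-level
    reduction: bin b counts voxels with intensity exactly b)."""
    mask.check_congruent(volume)
    vals = volume.intensities[mask.voxels]
    if vals.size == 0:
        raise EmptyMaskError("cannot build a histogram from an empty ROI")
    uniq, counts = np.unique(vals, return_counts=True)
    return IntensityHistogram(uniq.astype(np.int64), counts)


def _histogram_stats(bin_values: np.ndarray, probs: np.ndarray, window: int) -> Dict[str, float]:
    """The 12 first-order statistics of a normalized histogram.

    ``bin_values`` holds the value axis for the non-empty bins only (gray
    levels, or code-bin indices for LBP histograms); ``probs`` their masses.
    Empty bins between peaks are ignored for relative-maxima detection and
    a flat plateau of equal-mass neighbors counts as one maximum.
    """
    b = np.asarray(bin_values, dtype=float)
    p = np.asarray(probs, dtype=float)
    if b.size == 0:
        raise ValueError("empty histogram")
    order = np.argsort(b)
    b, p = b[order], p[order]

    mean = float(np.sum(b * p))
    var = float(np.sum((b - mean) ** 2 * p))
    sd = float(np.sqrt(var))
    if sd > 0:
        z = (b - mean) / sd
        skew = float(np.sum(z**3 * p))
        kurt = float(np.sum(z**4 * p))
    else:
        skew = 0.0
        kurt = 0.0
    energy = float(np.sum(p**2))
    pos = p[p > 0]
    entropy = float(-np.sum(pos * np.log2(pos)))
    pmax = float(p.max())
    max_pos = float(b[int(np.argmax(p))])  # ties -> smallest value (sorted)
    in_win = np.abs(b - max_pos) <= window
    max_energy = float(np.sum(p[in_win] ** 2))
    rng = float(b[-1] - b[0])

    # relative maxima: compress consecutive equal-mass runs of the non-empty
    # sequence to plateaus, then count plateaus strictly above both neighbors
    run_starts = [0]
    for i in range(1, len(p)):
        if p[i] != p[run_starts[-1]]:
            run_starts.append(i)
    run_vals = [p[i] for i in run_starts]
    n_runs = len(run_vals)
    peaks: List[int] = []
    for r in range(n_runs):
        left_ok = r == 0 or run_vals[r] > run_vals[r - 1]
        right_ok = r == n_runs - 1 or run_vals[r] > run_vals[r + 1]
        if left_ok and right_ok:
            peaks.append(r)
    n_rel_max = float(len(peaks))
    if peaks:
        covered = np.zeros_like(p, dtype=bool)
        for r in peaks:
            start = run_starts[r]
            end = run_starts[r + 1] if r + 1 < n_runs else len(p)
            for i in range(start, end):
                covered |= np.abs(b - b[i]) <= window
        rel_max_energy = float(np.sum(p[covered] ** 2))
    else:  # pragma: no cover - peaks is never empty for a valid histogram
        rel_max_energy = 0.0

    return {
        "mean": mean,
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "entropy": entropy,
        "max": pmax,
        "max_position": max_pos,
        "max_energy": max_energy,
        "range": rng,
        "n_rel_max": n_rel_max,
        "rel_max_energy": rel_max_energy,
    }


def first_order_features(hist: IntensityHistogram, window: int = 5) -> Dict[str, float]:
    """The 12 first-order statistics of an ROI intensity histogram.

    ``window`` is the half-width, in gray levels, of the neighborhoods used
    by the two "energy around a maximum" statistics.
    """
    if hist.total == 0:
        raise ValueError("empty histogram")
    stats = _histogram_stats(hist.bin_values, hist.probabilities, window)
    return {f"fo_{k}": v for k, v in stats.items()}


# ---------------------------------------------------------------------------
# LBP-TOP
# ---------------------------------------------------------------------------

# axis indices in the (z, y, x) array convention
_AXIS = {"X": 2, "Y": 1, "Z": 0}

#: counter-clockwise 3x3 ring starting at +first-in-plane-axis
_RING = ((1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1))


def _rotate8(code: int, k: int) -> int:
    return ((code >> k) | (code << (8 - k))) & 0xFF


@lru_cache(maxsize=None)
def _variant_tables() -> Dict[str, Tuple[np.ndarray, int]]:
    """code -> histogram-bin maps for the four LBP variants."""
    codes = np.arange(256)
    tables: Dict[str, Tuple[np.ndarray, int]] = {"basic": (codes.copy(), 256)}

    ri_min = np.array([min(_rotate8(c, k) for k in range(8)) for c in range(256)])
    ri_classes = np.unique(ri_min)  # 36 classes
    tables["ri"] = (np.searchsorted(ri_classes, ri_min), len(ri_classes))

    transitions = np.array(
        [bin((c ^ _rotate8(c, 1)) & 0xFF).count("1") for c in range(256)]
    )
    uniform = transitions <= 2  # 58 uniform patterns
    uniform_codes = codes[uniform]
    u2_map = np.full(256, len(uniform_codes))  # non-uniform pooled in last bin
    u2_map[uniform] = np.searchsorted(uniform_codes, codes[uniform])
    tables["u2"] = (u2_map, len(uniform_codes) + 1)

    popcount = np.array([bin(c).count("1") for c in range(256)])
    riu2_map = np.where(uniform, popcount, 9)  # 0..8 uniform, 9 pooled
    tables["riu2"] = (riu2_map, 10)
    return tables


def lbp_variant_n_bins(variant: str) -> int:
    return _variant_tables()[variant][1]


def _basic_plane_codes(intensities: np.ndarray, plane: str) -> tuple[np.ndarray, np.ndarray]:
    """8-bit LBP codes for every voxel with a full in-plane 3x3 neighborhood.

    Returns (codes, valid) full-grid arrays; ``valid`` marks voxels whose 8
    in-plane neighbors all exist in the grid (neighbors are taken from the
    grid regardless of ROI membership).  Bit k is set iff neighbor_k >= center.
    """
    ax1 = _AXIS[plane[0]]
    ax2 = _AXIS[plane[1]]
    vol = intensities.astype(np.int64)
    codes = np.zeros(vol.shape, dtype=np.uint16)
    for k, (d1, d2) in enumerate(_RING):
        # value at v + delta == roll(vol, -delta)[v]
        nb = np.roll(np.roll(vol, -d1, axis=ax1), -d2, axis=ax2)
        codes |= ((nb >= vol).astype(np.uint16)) << k
    valid = np.ones(vol.shape, dtype=bool)
    for ax in (ax1, ax2):
        idx_lo = [slice(None)] * 3
        idx_hi = [slice(None)] * 3
        idx_lo[ax] = 0
        idx_hi[ax] = vol.shape[ax] - 1
        valid[tuple(idx_lo)] = False
        valid[tuple(idx_hi)] = False
    return codes, valid


def lbp_plane_codes(
    volume: VoxelVolume, mask: RoiMask, plane: str, variant: str = "basic"
) -> np.ndarray:
    """Per-voxel LBP codes of the ROI in one orthogonal plane.

    Codes are computed on the classic 8-neighbor 3x3 ring (radius 1, no
    interpolation), bit k set iff neighbor_k >= center, ring order starting
    at the +first-in-plane-axis neighbor and proceeding counter-clockwise.
    ROI voxels whose in-plane neighborhood leaves the grid are skipped.
    Returns the 1D array of (variant-mapped) codes, one per coded ROI voxel.
    """
    if plane not in LBP_PLANES:
        raise ValueError(f"plane must be one of {LBP_PLANES}, got {plane!r}")
    if variant not in LBP_VARIANTS:
        raise ValueError(f"variant must be one of {LBP_VARIANTS}, got {variant!r}")
    mask.check_congruent(volume)
    if mask.count() == 0:
        raise EmptyMaskError("cannot compute LBP codes on an empty ROI")
    codes, valid = _basic_plane_codes(volume.intensities, plane)
    sel = codes[mask.voxels & valid]
    table, _ = _variant_tables()[variant]
    return table[sel]


def lbp_top_features(volume: VoxelVolume, mask: RoiMask, window: int = 5) -> Dict[str, float]:
    """The 48 LBP-TOP features.

    Per variant, the code histograms of the three orthogonal planes are
    concatenated (XY, then XZ, then YZ), normalized, and summarized by the
    same 12 statistics as the first-order block, with the concatenated bin
    index as the value axis.  4 variants x 12 statistics = 48 features.
    """
    mask.check_congruent(volume)
    if mask.count() == 0:
        raise EmptyMaskError("cannot compute LBP-TOP features on an empty ROI")
    plane_codes = {}
    for plane in LBP_PLANES:
        codes, valid = _basic_plane_codes(volume.intensities, plane)
        plane_codes[plane] = codes[mask.voxels & valid]
    if all(c.size == 0 for c in plane_codes.values()):
        raise EmptyMaskError(
            "no ROI voxel has a complete in-plane neighborhood in any plane"
        )
    out: Dict[str, float] = {}
    tables = _variant_tables()
    for variant in LBP_VARIANTS:
        table, n_bins = tables[variant]
        hists = [
            np.bincount(table[plane_codes[p]], minlength=n_bins) for p in LBP_PLANES
        ]
        concat = np.concatenate(hists)
        nz = np.nonzero(concat)[0]
        probs = concat[nz] / concat.sum()
        stats = _histogram_stats(nz.astype(float), probs, window)
        for s in FIRST_ORDER_STATS:
            out[f"lbp_{variant}_{s}"] = stats[s]
    return out


# ---------------------------------------------------------------------------
# 3D GLCM
# ---------------------------------------------------------------------------


@dataclass
class PairCountTable:
    """Sparse directed co-occurrence table for one unit displacement.

    ``levels_i[k], levels_j[k] -> counts[k]`` stores the number of ordered
    ROI voxel pairs (v, v+direction) with gray levels (i, j).  Raw 16-bit
    gray values index the table; only observed pairs are stored.
    """

    direction: Tuple[int, int, int]
    levels_i: np.ndarray
    levels_j: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.direction not in GLCM_DIRECTIONS:
            raise ValueError(f"invalid GLCM direction {self.direction}")
        self.levels_i = np.asarray(self.levels_i, dtype=np.int64)
        self.levels_j = np.asarray(self.levels_j, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts <= 0):
            raise ValueError("stored pairs must have positive counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.total


def glcm_pairs(volume: VoxelVolume, mask: RoiMask, direction: Tuple[int, int, int]) -> PairCountTable:
    """Directed co-occurrence counts at interpixel distance 1.

    Counts ordered gray-level pairs (I(v), I(v+d)) over voxels v with both
    v and v+d inside the ROI.  No symmetrization: the opposite direction is
    its own table.  Thin ROIs may produce an empty table.
    """
    mask.check_congruent(volume)
    if mask.count() == 0:
        raise EmptyMaskError("cannot build a co-occurrence table on an empty ROI")
    d = tuple(int(c) for c in direction)
    if d not in GLCM_DIRECTIONS:
        raise ValueError(f"direction must be one of the 26 unit offsets, got {direction}")
    vol = volume.intensities
    shape = vol.shape
    src = []
    dst = []
    for dim, dd in enumerate(d):
        n = shape[dim]
        if dd >= 0:
            src.append(slice(0, n - dd))
            dst.append(slice(dd, n))
        else:
            src.append(slice(-dd, n))
            dst.append(slice(0, n + dd))
    src, dst = tuple(src), tuple(dst)
    both = mask.voxels[src] & mask.voxels[dst]
    a = vol[src][both].astype(np.int64)
    b = vol[dst][both].astype(np.int64)
    if a.size == 0:
        return PairCountTable(d, np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.int64))
    key = a * N_BINS + b
    uniq, counts = np.unique(key, return_counts=True)
    return PairCountTable(d, uniq // N_BINS, uniq % N_BINS, counts)


def _glcm_stats(table: PairCountTable) -> Dict[str, float]:
    if table.total == 0:
        return {s: 0.0 for s in GLCM_STATS}
    i = table.levels_i.astype(float)
    j = table.levels_j.astype(float)
    p = table.probabilities
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    diff = i - j
    return {
        "autocorr": float(np.sum(i * j * p)),
        "covariance": float(np.sum((i - mu_i) * (j - mu_j) * p)),
        "inertia": float(np.sum(diff**2 * p)),
        "abs_inertia": float(np.sum(np.abs(diff) * p)),
        "inv_inertia": float(np.sum(p / (1.0 + diff**2))),
        "energy": float(np.sum(p**2)),
        "entropy": float(-np.sum(p * np.log2(p))),
    }


def glcm_features(volume: VoxelVolume, mask: RoiMask) -> Dict[str, float]:
    """The 182 GLCM features: 7 statistics per each of the 26 directions,
    direction-major in the canonical lexicographic direction order.

    An empty table (possible for thin ROIs) contributes zeros for all 7
    statistics of its direction, with a logged warning.
    """
    mask.check_congruent(volume)
    if mask.count() == 0:
        raise EmptyMaskError("cannot compute GLCM features on an empty ROI")
    out: Dict[str, float] = {}
    for idx, d in enumerate(GLCM_DIRECTIONS):
        table = glcm_pairs(volume, mask, d)
        if table.total == 0:
            logger.warning(
                "empty co-occurrence table for direction %s; features set to 0", d
            )
        stats = _glcm_stats(table)
        for s in GLCM_STATS:
            out[f"glcm_{idx:02d}_{s}"] = stats[s]
    return out


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------


@dataclass
class FeatureVector:
    """Ordered named map of the 253 per-lesion features."""

    values: Dict[str, float]

    def __post_init__(self) -> None:
        expected = feature_names()
        got = list(self.values)
        if got != expected:
            raise ValueError(
                f"feature vector must have the 253 canonical entries in order; "
                f"got {len(got)} entries"
            )
        arr = np.array(list(self.values.values()), dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = [k for k, v in self.values.items() if not np.isfinite(v)]
            raise ValueError(f"non-finite feature values: {bad}")

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    def radiomic(self) -> Dict[str, float]:
        return {k: v for k, v in self.values.items() if not k.startswith("sem_")}

    def semantic(self) -> Dict[str, float]:
        return {k: v for k, v in self.values.items() if k.startswith("sem_")}


def extract_all(volume: VoxelVolume, mask: RoiMask, record, window: int = 5) -> FeatureVector:
    """Extract the full 253-entry feature vector for one lesion.

    ``record`` is a :class:`~edemarad.model_pipeline.LesionRecord` (or any
    object with a ``semantic_values()`` mapping); the mask is expected to be
    the convex-hull-refined ROI.
    """
    sem = record.semantic_values() if hasattr(record, "semantic_values") else dict(record)
    values: Dict[str, float] = {}
    for f in SEMANTIC_FIELDS:
        if f not in sem or sem[f] is None:
            raise ValueError(f"missing semantic value: {f!r}")
        values[f"sem_{f}"] = float(sem[f])
    hist = intensity_histogram(volume, mask)
    values.update(first_order_features(hist, window=window))
    try:
        values.update(lbp_top_features(volume, mask, window=window))
    except EmptyMaskError:
        # 1-voxel / border-only ROIs: no codable voxel in any plane
        logger.warning("no codable LBP voxels; LBP block set to 0")
        for variant in LBP_VARIANTS:
            for s in FIRST_ORDER_STATS:
                values[f"lbp_{variant}_{s}"] = 0.0
    values.update(glcm_features(volume, mask))
    return FeatureVector(values)
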
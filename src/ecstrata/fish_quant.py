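"""smRNA-FISH spot co-localization on binary channel masks.

Mirrors a CellProfiler-style counting pipeline: spots are detected as
8-connected components independently in each channel, every object is
expanded by a 5-pixel-diameter disk (morphological dilation; a
centroid-stamped disk is available behind a flag), and transitively
overlapping expanded objects across channels form composite cells that
are classified by the set of channels present.  ROI label masks split
counts between crypt and villus compartments, and a puncta-size metric
quantifies depletion of a target channel.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from networkx.utils import UnionFind
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .errors import ValidationError
from .stats_core import TestResult, t_test_unpaired


@dataclass
class ChannelMask:
    """Binary spot mask for one fluorescence channel."""

    pixels: np.ndarray
    channel: str
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValidationError("channel mask must be a 2-D array")


@dataclass
class RoiMask:
    """Integer ROI label mask; 0 means outside all ROIs."""

    labels: np.ndarray
    semantics: dict[int, str] = field(default_factory=lambda: {1: "crypt", 2: "villus"})

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels).astype(int)
        if self.labels.ndim != 2:
            raise ValidationError("ROI mask must be a 2-D array")


@dataclass
class FishObject:
    rows: np.ndarray
    cols: np.ndarray
    centroid: tuple[float, float]
    size: int
    channel: str
    roi: int | None = None


@dataclass
class ObjectSet:
    channel: str
    objects: list[FishObject]
    shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.objects)


@dataclass
class Composite:
    """A composite cell: a transitively overlapping group of expanded
    objects, possibly spanning channels."""

    members: list[FishObject]
    channels: frozenset[str]
    roi: int | None = None


@dataclass
class ColocResult:
    composites: list[Composite]
    class_counts: dict[frozenset, int]
    channels: tuple[str, ...]

    def count(self, *channels: str) -> int:
        """Number of composite cells positive for at least these channels."""
        want = frozenset(channels)
        return sum(1 for c in self.composites if want <= c.channels)


def detect_objects(mask: ChannelMask, min_size: int = 1) -> ObjectSet:
    """8-connected components of true pixels with size >= min_size."""
    lab = cc_label(mask.pixels, connectivity=2)
    objs: list[FishObject] = []
    slices = ndimage.find_objects(lab)
    for idx, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        rows, cols = np.nonzero(lab[sl] == idx)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        if rows.size < min_size:
            continue
        objs.append(
            FishObject(
                rows=rows,
                cols=cols,
                centroid=(float(rows.mean()), float(cols.mean())),
                size=int(rows.size),
                channel=mask.channel,
            )
        )
    return ObjectSet(mask.channel, objs, mask.pixels.shape)


def _expanded_pixels(
    obj: FishObject, shape: tuple[int, int], diameter: int, mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of the object after expansion."""
    radius = diameter // 2
    if mode == "centroid":
        r0, c0 = (int(round(v)) for v in obj.centroid)
        rr, cc = np.nonzero(disk(radius))
        rr = rr + r0 - radius
        cc = cc + c0 - radius
    else:  # dilate the full pixel set
        rmin, rmax = obj.rows.min(), obj.rows.max()
        cmin, cmax = obj.cols.min(), obj.cols.max()
        h = rmax - rmin + 1 + 2 * radius
        w = cmax - cmin + 1 + 2 * radius
        patch = np.zeros((h, w), dtype=bool)
        patch[obj.rows - rmin + radius, obj.cols - cmin + radius] = True
        dil = ndimage.binary_dilation(patch, structure=disk(radius))
        rr, cc = np.nonzero(dil)
        rr = rr + rmin - radius
        cc = cc + cmin - radius
    keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
    return rr[keep], cc[keep]


def colocalize(
    object_sets: list[ObjectSet],
    expansion_diameter_px: int = 5,
    expansion_mode: str = "dilate",
) -> ColocResult:
    """Group expanded objects into composite cells and classify them.

    Objects (from any channel, including the same one — a cell emits
    several spots per channel) whose expanded pixel sets intersect are
    merged transitively; each resulting composite is classified by its
    set of channels.
    """
    if len(object_sets) < 2:
        raise ValidationError("co-localization needs at least 2 channels")
    if expansion_diameter_px < 1:
        raise ValidationError("expansion diameter must be >= 1 pixel")
    shapes = {os.shape for os in object_sets}
    if len(shapes) != 1:
        raise ValidationError("all channels must share one frame shape")
    shape = shapes.pop()

    nodes: list[FishObject] = [o for os in object_sets for o in os.objects]
    uf = UnionFind(range(len(nodes)))
    pixel_owner: dict[int, list[int]] = defaultdict(list)
    for i, obj in enumerate(nodes):
        rr, cc = _expanded_pixels(obj, shape, expansion_diameter_px, expansion_mode)
        for flat in np.unique(rr * shape[1] + cc):
            pixel_owner[int(flat)].append(i)
    for owners in pixel_owner.values():
        for other in owners[1:]:
            uf.union(owners[0], other)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(nodes)):
        groups[uf[i]].append(i)

    composites: list[Composite] = []
    class_counts: dict[frozenset, int] = defaultdict(int)
    for members in groups.values():
        objs = [nodes[i] for i in members]
        channels = frozenset(o.channel for o in objs)
        composites.append(Composite(objs, channels))
        class_counts[channels] += 1
    return ColocResult(
        composites, dict(class_counts), tuple(os.channel for os in object_sets)
    )


def partition_rois(
    coloc: ColocResult,
    roi: RoiMask,
    reference_channel: str | None = None,
) -> pd.DataFrame:
    """Assign composites to ROIs and tabulate counts/fractions per ROI.

    A composite belongs to the ROI containing the majority of its
    pre-dilation pixels (ties go to the smaller ROI label; label 0 means
    outside and is excluded from fractions).  Fractions are
    double-positive composites (reference + other channel) over
    reference-positive composites, per ROI.
    """
    for comp in coloc.composites:
        votes: dict[int, int] = defaultdict(int)
        for obj in comp.members:
            labels, counts = np.unique(roi.labels[obj.rows, obj.cols], return_counts=True)
            for lab, cnt in zip(labels, counts):
                votes[int(lab)] += int(cnt)
        best = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        comp.roi = best[0][0]
        for obj in comp.members:
            obj.roi = comp.roi

    reference = reference_channel or coloc.channels[0]
    rows = []
    roi_labels = sorted({c.roi for c in coloc.composites} | set(roi.semantics))
    for lab in roi_labels:
        comps = [c for c in coloc.composites if c.roi == lab]
        n_ref = sum(1 for c in comps if reference in c.channels)
        row = {
            "roi": lab,
            "roi_name": roi.semantics.get(lab, "outside"),
            "n_composites": len(comps),
            f"n_{reference}_pos": n_ref,
        }
        for ch in coloc.channels:
            if ch == reference:
                continue
            n_double = sum(
                1 for c in comps if reference in c.channels and ch in c.channels
            )
            row[f"n_{reference}_{ch}_double"] = n_double
            row[f"frac_{ch}_in_{reference}"] = (
                n_double / n_ref if (n_ref and lab != 0) else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_roi_fractions(fractions_a, fractions_b) -> TestResult:
    """Unpaired t-test contrasting per-image positive fractions between two
    ROIs (crypt vs villus)."""
    return t_test_unpaired(np.asarray(fractions_a), np.asarray(fractions_b))


@dataclass
class DepletionMetrics:
    n_double_positive: int
    n_target_single: int
    n_reference_single: int
    target_sizes: np.ndarray
    mean_target_size: float
    total_target_size: int


def quantify_depletion(
    reference: ObjectSet,
    target: ObjectSet,
    expansion_diameter_px: int = 5,
) -> DepletionMetrics:
    """Count double/single-positive puncta between a reference channel
    (e.g. Tph1) and a target channel (e.g. Piezo2) and summarize the
    target's signal intensity by puncta size in pixels."""
    if reference.shape != target.shape:
        raise ValidationError("channels must share one frame shape")
    sizes = np.array([o.size for o in target.objects], dtype=float)
    if len(reference) == 0 or len(target) == 0:
        return DepletionMetrics(
            0, len(target), len(reference), sizes,
            float(sizes.mean()) if sizes.size else 0.0, int(sizes.sum()),
        )
    coloc = colocalize([reference, target], expansion_diameter_px)
    n_double = 0
    n_t_single = 0
    n_r_single = 0
    for comp in coloc.composites:
        if reference.channel in comp.channels and target.channel in comp.channels:
            n_double += sum(1 for o in comp.members if o.channel == target.channel)
        elif target.channel in comp.channels:
            n_t_single += sum(1 for o in comp.members if o.channel == target.channel)
        else:
            n_r_single += sum(1 for o in comp.members if o.channel == reference.channel)
    return DepletionMetrics(
        n_double, n_t_single, n_r_single, sizes,
        float(sizes.mean()) if sizes.size else 0.0, int(sizes.sum()),
    )


def read_mask_txt(path, channel: str) -> ChannelMask:
    """Read a plain-text 0/1 grid as a channel mask."""
    return ChannelMask(np.loadtxt(path, dtype=int), channel)


def read_roi_txt(path, semantics: dict[int, str] | None = None) -> RoiMask:
    arr = np.loadtxt(path, dtype=int)
    return RoiMask(arr, semantics or {1: "crypt", 2: "villus"})
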
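"""Regional EdU-intensity mapping and cell-density measurement.

The duct is imaged as an 8-bit multi-channel z-stack (epithelial marker,
EdU, nuclei).  The stack is split into roof and floor halves, projected to
2D, and the duct outline (binarized from the marker channel) is partitioned
into a 20 (along the duct, from the apex) x 10 (mediolateral, from the
medial side) grid of quadrilateral regions by joining equidistant marks on
the medial and lateral perimeter curves.  Mean EdU intensity per region
(normalized by 255) maps local proliferation; nuclear counts in five
mediolateral sections give cell densities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label
from skimage.morphology import closing, disk

__all__ = [
    "LabeledVolume",
    "DuctPartition",
    "RegionIntensityMap",
    "split_roof_floor",
    "project",
    "binarize_duct",
    "duct_perimeter",
    "build_partition",
    "region_means",
    "cell_density",
]


@dataclass
class LabeledVolume:
    """Co-registered z-stack channels (8-bit) with voxel calibration."""

    marker: np.ndarray          # (Z, H, W) epithelial marker
    edu: np.ndarray             # (Z, H, W)
    nuclei: np.ndarray | None = None
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)  # z, y, x µm

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker)
        self.edu = np.asarray(self.edu)
        if self.marker.ndim != 3 or self.marker.shape != self.edu.shape:
            raise ValueError("marker and edu must be matching (Z, H, W) stacks")
        if self.nuclei is not None:
            self.nuclei = np.asarray(self.nuclei)
            if self.nuclei.shape != self.marker.shape:
                raise ValueError("nuclei stack must match the other channels")


def split_roof_floor(stack: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a z-stack at the middle z into (roof, floor) substacks.

    With an odd slice count the middle slice goes to the floor half.
    """
    stack = np.asarray(stack)
    z = stack.shape[0]
    if z < 2:
        raise ValueError("need at least 2 z slices to split")
    mid = z // 2
    return stack[:mid], stack[mid:]


def project(
    stack: np.ndarray,
    method: str = "max",
    duct_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Project a (Z, H, W) stack to 2D by max, sum, or in-duct mean.

    ``mean_within_duct`` averages only the z-samples inside the per-slice
    duct mask, so the denominator varies with local epithelial thickness;
    columns with no in-duct sample are NaN.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (Z, H, W)")
    if method == "max":
        return stack.max(axis=0)
    if method == "sum":
        return stack.sum(axis=0)
    if method == "mean_within_duct":
        if duct_mask is None:
            raise ValueError("mean_within_duct requires a duct mask")
        m = np.asarray(duct_mask, dtype=bool)
        if m.ndim == 2:
            m = np.broadcast_to(m, stack.shape)
        if m.shape != stack.shape:
            raise ValueError("mask shape must match the stack")
        cnt = m.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(cnt > 0, (stack * m).sum(axis=0) / np.maximum(cnt, 1), np.nan)
        return out
    raise ValueError(f"unknown projection method: {method!r}")


def binarize_duct(marker: np.ndarray, closing_radius: int = 3) -> np.ndarray:
    """Duct mask: Otsu threshold, closing, hole fill, largest component."""
    img = np.asarray(marker, dtype=float)
    if img.max() == img.min():
        raise ValueError("constant image cannot be binarized")
    mask = img > threshold_otsu(img)
    mask = closing(mask, disk(closing_radius))
    mask = ndimage.binary_fill_holes(mask)
    lab = label(mask)
    if lab.max() == 0:
        raise ValueError("no foreground found")
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == sizes.argmax()


def duct_perimeter(mask: np.ndarray) -> np.ndarray:
    """Closed boundary polyline of the duct mask, (n, 2) as (row, col)."""
    contours = find_contours(np.asarray(mask, dtype=float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    return max(contours, key=len)


@dataclass
class DuctPartition:
    """20x10 curvilinear region grid between the duct's perimeter curves."""

    nodes: np.ndarray             # (21, 11, 2) grid nodes (row, col)
    medial_curve: np.ndarray      # (n, 2) apex -> medial end
    lateral_curve: np.ndarray     # (m, 2) apex -> lateral end
    mask: np.ndarray              # duct mask the partition was built on

    @property
    def n_along(self) -> int:
        return self.nodes.shape[0] - 1

    @property
    def n_across(self) -> int:
        return self.nodes.shape[1] - 1

    def region_polygon(self, a: int, m: int) -> np.ndarray:
        q = np.array([
            self.nodes[a, m], self.nodes[a, m + 1],
            self.nodes[a + 1, m + 1], self.nodes[a + 1, m],
        ])
        return q

    def label_pixels(self) -> np.ndarray:
        """Assign every duct pixel to a region.

        Returns an integer map (-1 outside): pixels are tested against the
        region quadrilaterals in (along, across) index order, so shared-edge
        pixels belong to the lower-index region; in-mask pixels missed by the
        straight-edged quads (rasterization slack along the curved perimeter)
        are attached to the nearest region centroid, and pixels beyond the
        base chord remain unassigned.
        """
        H, W = self.mask.shape
        labels = np.full((H, W), -1, dtype=int)
        rows, cols = np.nonzero(self.mask)
        pix = np.column_stack([rows, cols]).astype(float)
        unassigned = np.ones(len(pix), dtype=bool)
        for a in range(self.n_along):
            for m in range(self.n_across):
                if not unassigned.any():
                    break
                quad = self.region_polygon(a, m)
                path = MplPath(quad[:, ::-1])  # (x=col, y=row)
                cand = np.nonzero(unassigned)[0]
                inside = path.contains_points(pix[cand][:, ::-1], radius=1e-9)
                hit = cand[inside]
                labels[rows[hit], cols[hit]] = a * self.n_across + m
                unassigned[hit] = False
        if unassigned.any():
            centroids = np.array([
                self.region_polygon(a, m).mean(axis=0)
                for a in range(self.n_along) for m in range(self.n_across)
            ])
            # longest quad edge bounds the rasterization slack
            slack = 0.0
            for a in range(self.n_along):
                for m in range(self.n_across):
                    q = self.region_polygon(a, m)
                    e = np.linalg.norm(np.diff(np.vstack([q, q[:1]]), axis=0), axis=1)
                    slack = max(slack, e.max())
            left = np.nonzero(unassigned)[0]
            d = np.linalg.norm(pix[left][:, None, :] - centroids[None], axis=2)
            nearest = d.argmin(axis=1)
            ok = d[np.arange(len(left)), nearest] <= slack
            labels[rows[left[ok]], cols[left[ok]]] = nearest[ok]
        return labels


def _cyclic_arc(perim: np.ndarray, i_from: int, i_to: int, forward: bool) -> np.ndarray:
    n = len(perim)
    if forward:
        idx = np.arange(i_from, i_from + (i_to - i_from) % n + 1) % n
    else:
        idx = np.arange(i_from, i_from - (i_from - i_to) % n - 1, -1) % n
    return perim[idx]


def build_partition(
    mask: np.ndarray,
    landmarks: dict,
    n_along: int = 20,
    n_across: int = 10,
    tolerance: float = 10.0,
) -> DuctPartition:
    """Partition the duct between landmark points into the region grid.

    ``landmarks`` holds ``apex``, ``medial_end`` and ``lateral_end`` as
    (row, col); each must lie within ``tolerance`` px of the mask perimeter.
    The perimeter is split at the apex into the medial and lateral curves,
    ``n_along`` equidistant marks are placed on each, corresponding marks
    are joined and each chord is divided into ``n_across`` segments.
    """
    mask = np.asarray(mask, dtype=bool)
    perim = duct_perimeter(mask)
    if np.allclose(perim[0], perim[-1]):
        perim = perim[:-1]

    def nearest_index(pt) -> int:
        pt = np.asarray(pt, dtype=float)
        d = np.linalg.norm(perim - pt, axis=1)
        if d.min() > tolerance:
            raise ValueError(
                f"landmark {tuple(np.round(pt, 1))} is {d.min():.1f} px from the "
                f"perimeter (tolerance {tolerance})"
            )
        return int(d.argmin())

    i_apex = nearest_index(landmarks["apex"])
    i_med = nearest_index(landmarks["medial_end"])
    i_lat = nearest_index(landmarks["lateral_end"])
    # walk forward from the apex: whichever end is reached first bounds that arc
    fwd_to_med = (i_med - i_apex) % len(perim)
    fwd_to_lat = (i_lat - i_apex) % len(perim)
    if fwd_to_med < fwd_to_lat:
        medial = _cyclic_arc(perim, i_apex, i_med, forward=True)
        lateral = _cyclic_arc(perim, i_apex, i_lat, forward=False)
    else:
        medial = _cyclic_arc(perim, i_apex, i_med, forward=False)
        lateral = _cyclic_arc(perim, i_apex, i_lat, forward=True)

    def marks(curve: np.ndarray, n: int) -> np.ndarray:
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(curve, axis=0), axis=1))])
        s = np.linspace(0.0, arc[-1], n + 1)
        return np.column_stack([
            np.interp(s, arc, curve[:, 0]),
            np.interp(s, arc, curve[:, 1]),
        ])

    med_marks = marks(medial, n_along)
    lat_marks = marks(lateral, n_along)
    frac = np.linspace(0.0, 1.0, n_across + 1)
    nodes = (med_marks[:, None, :] * (1 - frac)[None, :, None]
             + lat_marks[:, None, :] * frac[None, :, None])
    return DuctPartition(nodes=nodes, medial_curve=medial, lateral_curve=lateral, mask=mask)


@dataclass
class RegionIntensityMap:
    """Mean EdU intensity per region, normalized to [0, 1]."""

    values: np.ndarray        # (n_along, n_across), NaN where empty
    counts: np.ndarray        # per-region pixel counts
    empty: np.ndarray         # bool flags


def region_means(edu_image: np.ndarray, partition: DuctPartition) -> RegionIntensityMap:
    """Mean 8-bit EdU intensity per region, divided by 255."""
    img = np.asarray(edu_image, dtype=float)
    if img.shape != partition.mask.shape:
        raise ValueError("EdU image must match the partition mask shape")
    labels = partition.label_pixels()
    n = partition.n_along * partition.n_across
    vals = np.full(n, np.nan)
    counts = np.zeros(n, dtype=int)
    flat = labels.ravel()
    sel = flat >= 0
    counts_all = np.bincount(flat[sel], minlength=n)
    sums = np.bincount(flat[sel], weights=img.ravel()[sel], minlength=n)
    nonzero = counts_all > 0
    vals[nonzero] = sums[nonzero] / counts_all[nonzero] / 255.0
    counts = counts_all
    shape = (partition.n_along, partition.n_across)
    return RegionIntensityMap(
        values=vals.reshape(shape),
        counts=counts.reshape(shape),
        empty=~nonzero.reshape(shape),
    )


def cell_density(
    points: np.ndarray,
    bounds: tuple[float, float] | None = None,
    n_sections: int = 5,
    axis: int = 0,
    section_areas: np.ndarray | None = None,
    extent_other: float | None = None,
) -> pd.DataFrame:
    """Cell densities in equal sections along the mediolateral axis.

    ``points`` are nucleus positions (n, 2) in µm; the chosen ``axis``
    coordinate is divided into ``n_sections`` equal intervals between
    ``bounds`` (defaults to the data range).  Section areas may be supplied
    explicitly, or derived as section width times ``extent_other`` (defaults
    to the cross-axis data range).  Returns a table with section centers,
    counts, areas and densities (cells/µm²); empty sections are flagged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    coord = pts[:, axis]
    other = pts[:, 1 - axis]
    lo, hi = bounds if bounds is not None else (coord.min(), coord.max())
    if hi <= lo:
        raise ValueError("degenerate axis bounds")
    edges = np.linspace(lo, hi, n_sections + 1)
    width = edges[1] - edges[0]
    if section_areas is None:
        h = extent_other if extent_other is not None else (other.max() - other.min())
        if h <= 0:
            raise ValueError("cannot derive section areas from degenerate extent")
        section_areas = np.full(n_sections, width * h)
    section_areas = np.asarray(section_areas, dtype=float)
    counts = np.histogram(coord, bins=edges)[0]
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = counts / section_areas
    return pd.DataFrame({
        "section": np.arange(n_sections),
        "position": centers,
        "count": counts,
        "area": section_areas,
        "density": dens,
        "empty": counts == 0,
    })
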
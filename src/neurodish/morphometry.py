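"""Neuron morphometry: SWC I/O, Sholl analysis, outgrowth/soma summaries,
and synaptic-puncta detection and colocalization.

Sholl analysis counts how many neurite segments cross concentric circles
(default 10 um spacing) centered on the soma; together with total neuritic
outgrowth and soma area it summarizes arbor complexity.  Synapse density is
quantified as one-to-one colocalized pre/post puncta pairs per 50 um of
neurite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.feature import blob_log

__all__ = [
    "NeuronMorphology",
    "ShollProfile",
    "PunctaField",
    "read_swc",
    "write_swc",
    "sholl_profile",
    "morpho_summary",
    "detect_puncta",
    "colocalize_and_density",
]

SOMA_TYPE = 1


@dataclass
class NeuronMorphology:
    """SWC-style neuron reconstruction.

    ``nodes`` is a DataFrame with columns id, type, x, y, z, radius, parent
    (um; parent -1 marks the root).  Exactly one root of soma type is
    required, every parent must precede its child, and the graph must be
    acyclic (guaranteed by the ordering constraint).
    """

    nodes: pd.DataFrame

    def __post_init__(self) -> None:
        req = ["id", "type", "x", "y", "z", "radius", "parent"]
        if list(self.nodes.columns) != req:
            self.nodes = self.nodes[req]
        self.nodes = self.nodes.reset_index(drop=True)
        roots = self.nodes.index[self.nodes["parent"] == -1].tolist()
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        if int(self.nodes.iloc[roots[0]]["type"]) != SOMA_TYPE:
            raise ValueError("root node must be of soma type (1)")
        ids = self.nodes["id"].to_numpy()
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        seen = set()
        for row in self.nodes.itertuples(index=False):
            if row.parent != -1 and row.parent not in seen:
                raise ValueError(
                    f"node {row.id}: parent {row.parent} does not precede it")
            seen.add(row.id)
        xyz = self.nodes[["x", "y", "z"]].to_numpy()
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite coordinates")

    @classmethod
    def from_rows(cls, rows) -> "NeuronMorphology":
        df = pd.DataFrame(rows, columns=["id", "type", "x", "y", "z",
                                         "radius", "parent"])
        return cls(nodes=df)

    @property
    def root(self) -> pd.Series:
        return self.nodes[self.nodes["parent"] == -1].iloc[0]

    def soma_center(self) -> np.ndarray:
        return self.root[["x", "y", "z"]].to_numpy(dtype=float)

    def segments(self, exclude_soma_internal: bool = True) -> np.ndarray:
        """(n_seg, 2, 3) array of parent->child coordinate pairs."""
        df = self.nodes
        idx = {int(i): k for k, i in enumerate(df["id"].to_numpy())}
        xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
        types = df["type"].to_numpy()
        segs = []
        for k, row in enumerate(df.itertuples(index=False)):
            if row.parent == -1:
                continue
            p = idx[int(row.parent)]
            if exclude_soma_internal and types[k] == SOMA_TYPE \
                    and types[p] == SOMA_TYPE:
                continue
            segs.append((xyz[p], xyz[k]))
        return np.array(segs) if segs else np.empty((0, 2, 3))


@dataclass
class ShollProfile:
    """Intersection counts on a grid of concentric radii (um)."""

    radii_um: np.ndarray
    intersections: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.radii_um,
                             "intersections": self.intersections})


@dataclass
class PunctaField:
    """Pre/post 2-D puncta point sets (um) along a neurite polyline."""

    pre_points_um: np.ndarray
    post_points_um: np.ndarray
    neurite_path_um: np.ndarray

    def __post_init__(self) -> None:
        self.pre_points_um = np.asarray(self.pre_points_um,
                                        dtype=float).reshape(-1, 2)
        self.post_points_um = np.asarray(self.post_points_um,
                                         dtype=float).reshape(-1, 2)
        self.neurite_path_um = np.asarray(self.neurite_path_um, dtype=float)
        if self.neurite_length_um <= 0:
            raise ValueError("neurite path must have positive length")
        for pts in (self.pre_points_um, self.post_points_um):
            if pts.size and not np.all(np.isfinite(pts)):
                raise ValueError("non-finite puncta coordinates")

    @property
    def neurite_length_um(self) -> float:
        d = np.diff(self.neurite_path_um, axis=0)
        return float(np.sqrt((d ** 2).sum(axis=1)).sum())


def read_swc(path) -> NeuronMorphology:
    """Parse an SWC file; malformed topology is rejected with line numbers."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields, "
                                 f"got {len(parts)}")
            try:
                rows.append((int(parts[0]), int(parts[1]), float(parts[2]),
                             float(parts[3]), float(parts[4]),
                             float(parts[5]), int(parts[6])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    seen = set()
    for lineno_rel, row in enumerate(rows, start=1):
        nid, parent = row[0], row[6]
        if parent != -1 and parent not in seen:
            raise ValueError(
                f"{path}: node {nid} (data line {lineno_rel}) references "
                f"parent {parent} before it is defined")
        seen.add(nid)
    return NeuronMorphology.from_rows(rows)


def write_swc(morph: NeuronMorphology, path) -> None:
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for row in morph.nodes.itertuples(index=False):
            fh.write(f"{int(row.id)} {int(row.type)} {row.x:.6f} {row.y:.6f} "
                     f"{row.z:.6f} {row.radius:.6f} {int(row.parent)}\n")


def sholl_profile(morph: NeuronMorphology, step_um: float = 10.0,
                  use_3d: bool = False) -> ShollProfile:
    """Count neurite crossings of concentric circles around the soma.

    For each radius r = step, 2 step, ... a segment is counted when its
    endpoint distances from the soma straddle r (boundary inclusive on the
    far endpoint: min(d) < r <= max(d)).  Distances are in the x-y
    projection by default, matching 2-D tracings; set ``use_3d`` for
    spherical shells.
    """
    segs = morph.segments(exclude_soma_internal=True)
    center = morph.soma_center()
    dims = slice(None) if use_3d else slice(0, 2)
    if segs.shape[0] == 0:
        return ShollProfile(radii_um=np.array([step_um]),
                            intersections=np.array([0]))
    d0 = np.linalg.norm(segs[:, 0, dims] - center[dims], axis=1)
    d1 = np.linalg.norm(segs[:, 1, dims] - center[dims], axis=1)
    lo, hi = np.minimum(d0, d1), np.maximum(d0, d1)
    rmax = hi.max()
    radii = np.arange(step_um, rmax + step_um, step_um)
    counts = np.array([int(np.count_nonzero((lo < r) & (r <= hi)))
                       for r in radii])
    return ShollProfile(radii_um=radii, intersections=counts)


def morpho_summary(morph: NeuronMorphology) -> dict:
    """Total outgrowth (um), primary-neurite count, and soma area (um^2).

    Outgrowth sums segment lengths excluding soma-internal segments;
    primary neurites are the root's children; soma area is pi r^2 from the
    root radius.
    """
    segs = morph.segments(exclude_soma_internal=True)
    if segs.shape[0]:
        lengths = np.linalg.norm(segs[:, 1] - segs[:, 0], axis=1)
        outgrowth = float(lengths.sum())
    else:
        outgrowth = 0.0
    root_id = int(morph.root["id"])
    n_primary = int((morph.nodes["parent"] == root_id).sum())
    soma_area = float(np.pi * morph.root["radius"] ** 2)
    return {"total_outgrowth_um": outgrowth,
            "n_primary_neurites": n_primary,
            "soma_area_um2": soma_area}


def detect_puncta(image: np.ndarray, pixel_size_um: float,
                  psf_sigma_um: float = 0.15,
                  threshold: float = 0.1) -> np.ndarray:
    """Detect puncta as scale-matched Laplacian-of-Gaussian maxima.

    Returns an (n, 2) array of (x, y) centers in um, refined to subpixel
    precision by local intensity centroids.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel size metadata required (um/pixel > 0)")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    rng_ = img.max() - img.min()
    if rng_ == 0:
        return np.empty((0, 2))
    norm = (img - img.min()) / rng_
    sig = psf_sigma_um / pixel_size_um
    blobs = blob_log(norm, min_sigma=sig * 0.8, max_sigma=sig * 1.5,
                     num_sigma=3, threshold=threshold)
    centers = []
    r = max(int(round(2 * sig)), 1)
    for by, bx, _s in blobs:
        y0, y1 = int(max(by - r, 0)), int(min(by + r + 1, img.shape[0]))
        x0, x1 = int(max(bx - r, 0)), int(min(bx + r + 1, img.shape[1]))
        patch = norm[y0:y1, x0:x1]
        w = patch - patch.min()
        if w.sum() == 0:
            cy, cx = by, bx
        else:
            yy, xx = np.mgrid[y0:y1, x0:x1]
            cy = (yy * w).sum() / w.sum()
            cx = (xx * w).sum() / w.sum()
        centers.append((cx * pixel_size_um, cy * pixel_size_um))
    return np.array(centers) if centers else np.empty((0, 2))


def colocalize_and_density(pre: np.ndarray, post: np.ndarray,
                           neurite_length_um: float,
                           max_dist_um: float = 0.5):
    """One-to-one greedy nearest-neighbor colocalization and density/50 um.

    Candidate pre/post pairs within ``max_dist_um`` are matched greedily by
    ascending distance (ties broken by point index), each point used at most
    once.  Density is pairs x 50 / neurite length.

    Returns
    -------
    n_pairs : int
    density_per_50um : float
    pairs : list of (pre_idx, post_idx)
    """
    if neurite_length_um <= 0:
        raise ValueError("neurite length must be positive")
    pre = np.asarray(pre, dtype=float).reshape(-1, 2)
    post = np.asarray(post, dtype=float).reshape(-1, 2)
    pairs = []
    if len(pre) and len(post):
        tree = cKDTree(post)
        cand = []
        for i, p in enumerate(pre):
            for j in tree.query_ball_point(p, max_dist_um):
                cand.append((float(np.linalg.norm(p - post[j])), i, j))
        cand.sort()
        used_pre, used_post = set(), set()
        for d, i, j in cand:
            if i in used_pre or j in used_post:
                continue
            used_pre.add(i)
            used_post.add(j)
            pairs.append((i, j))
    density = len(pairs) * 50.0 / neurite_length_um
    return len(pairs), density, pairs
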
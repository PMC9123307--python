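"""Sholl analysis on SWC trees, spine classification, vesicle binning."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError

__all__ = [
    "NeuronTree",
    "ShollProfile",
    "SpineRecord",
    "SpineClassParams",
    "sholl",
    "classify_spines",
    "spine_density",
    "bin_vesicle_distances",
]

SWC_COLUMNS = ["id", "type", "x", "y", "z", "radius", "parent"]


@dataclass(frozen=True)
class NeuronTree:
    """SWC morphology: node table plus the soma origin used for Sholl.

    Multi-point somata (several type-1 nodes) are collapsed to their
    centroid for the distance origin; the root remains the tree root.
    """

    nodes: pd.DataFrame
    soma_xyz: np.ndarray

    @classmethod
    def from_swc(cls, nodes: pd.DataFrame) -> "NeuronTree":
        df = nodes[SWC_COLUMNS].copy()
        if df.empty:
            raise ContractError("empty SWC table")
        roots = df[df["parent"] == -1]
        if len(roots) != 1:
            raise ContractError(f"expected a single root, found {len(roots)}")
        ids = set(df["id"])
        seen: set[int] = set()
        for _, row in df.iterrows():
            p = int(row["parent"])
            if p != -1:
                if p not in ids:
                    raise ContractError(f"node {int(row['id'])} has unknown "
                                        f"parent {p}")
                if p not in seen:
                    raise ContractError("parent must precede child in SWC")
            seen.add(int(row["id"]))
        soma_pts = df[df["type"] == 1][["x", "y", "z"]].to_numpy()
        if len(soma_pts) == 0:
            soma_pts = roots[["x", "y", "z"]].to_numpy()
        return cls(nodes=df, soma_xyz=soma_pts.mean(axis=0))

    def edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Edge endpoint coordinates (parent_xyz, child_xyz), soma-origin."""
        df = self.nodes
        pos = {int(r["id"]): np.array([r["x"], r["y"], r["z"]])
               for _, r in df.iterrows()}
        p0, p1 = [], []
        for _, r in df.iterrows():
            par = int(r["parent"])
            if par == -1:
                continue
            p0.append(pos[par])
            p1.append(pos[int(r["id"])])
        if not p0:
            return (np.empty((0, 3)), np.empty((0, 3)))
        return np.array(p0) - self.soma_xyz, np.array(p1) - self.soma_xyz

    def total_length(self) -> float:
        a, b = self.edges()
        return float(np.linalg.norm(b - a, axis=1).sum())

    def n_branch_points(self) -> int:
        counts = self.nodes["parent"].value_counts()
        return int((counts[counts.index != -1] >= 2).sum())


@dataclass(frozen=True)
class ShollProfile:
    radii_um: np.ndarray
    crossings: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius_um": self.radii_um,
                             "crossings": self.crossings})


def sholl(tree: NeuronTree, step_um: float = 6.0,
          max_radius_um: float = 720.0) -> ShollProfile:
    """Count dendritic crossings of concentric spheres around the soma.

    For each radius, a straight edge contributes the exact number of
    intersections of the segment with the sphere (0, 1, or 2 — an edge
    approaching and receding can cross twice); an endpoint lying exactly
    on the sphere counts once (the crossing is attributed to the edge
    ending there). Radii run ``step, 2*step, ..., floor(max/step)*step``.
    """
    if step_um <= 0 or max_radius_um <= 0:
        raise ContractError("step and max radius must be positive")
    n_radii = int(np.floor(max_radius_um / step_um))
    radii = step_um * np.arange(1, n_radii + 1)
    a, b = tree.edges()
    if len(a) == 0:
        raise ContractError("tree has no edges")

    v = b - a
    aa = (v * v).sum(axis=1)                      # |v|^2 per edge
    bb = 2.0 * (a * v).sum(axis=1)
    a2 = (a * a).sum(axis=1)
    crossings = np.zeros(n_radii, dtype=np.int64)
    degenerate = aa < 1e-24

    for i, r in enumerate(radii):
        cc = a2 - r * r
        disc = bb * bb - 4.0 * aa * cc
        valid = (~degenerate) & (disc >= 0.0)
        sq = np.sqrt(np.where(valid, disc, 0.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            t1 = (-bb - sq) / (2.0 * aa)
            t2 = (-bb + sq) / (2.0 * aa)
        in1 = valid & (t1 > 0.0) & (t1 <= 1.0)
        in2 = valid & (t2 > 0.0) & (t2 <= 1.0)
        tangent = valid & (disc == 0.0)
        count = (in1.astype(np.int64) + in2.astype(np.int64)
                 - (tangent & in1 & in2).astype(np.int64))
        crossings[i] = count.sum()
    return ShollProfile(radii_um=radii, crossings=crossings)


@dataclass(frozen=True)
class SpineRecord:
    length_um: float
    head_diameter_um: float | None = None
    neck_diameter_um: float | None = None

    def __post_init__(self):
        if self.length_um <= 0:
            raise ContractError("spine length must be positive")
        for d in (self.head_diameter_um, self.neck_diameter_um):
            if d is not None and d < 0:
                raise ContractError("diameters must be >= 0")


@dataclass(frozen=True)
class SpineClassParams:
    """Stand-in rule set for a commercial classifier's defaults.

    Precedence: rejected (over-length) > mushroom > stubby > filopodia >
    long/thin. Thresholds configurable; rules documented, not published.
    """

    max_length_um: float = 4.0
    stubby_max_length_um: float = 1.0
    mushroom_head_neck_ratio: float = 2.0
    filopodia_min_length_um: float = 2.0
    min_end_diameter_um: float = 0.2


def classify_spines(records: list[SpineRecord],
                    params: SpineClassParams | None = None) -> list[str]:
    """Assign exactly one label per spine record.

    Labels: ``stubby``, ``mushroom``, ``long/thin``, ``filopodia``, or
    ``rejected`` (length above the 4 um maximum, or end diameter below
    the 0.2 um minimum).
    """
    params = params or SpineClassParams()
    labels = []
    for rec in records:
        head, neck = rec.head_diameter_um, rec.neck_diameter_um
        if rec.length_um > params.max_length_um:
            labels.append("rejected")
        elif head is not None and head < params.min_end_diameter_um:
            labels.append("rejected")
        elif (head is not None and neck is not None and neck > 0
              and head > params.mushroom_head_neck_ratio * neck):
            labels.append("mushroom")
        elif rec.length_um < params.stubby_max_length_um:
            labels.append("stubby")
        elif (rec.length_um > params.filopodia_min_length_um
              and (head is None or neck is None or head <= neck)):
            labels.append("filopodia")
        else:
            labels.append("long/thin")
    return labels


def spine_density(n_spines: int, dendrite_length_um: float) -> float:
    """Spines per micrometre of dendrite."""
    if dendrite_length_um <= 0:
        raise ContractError("dendrite length must be positive")
    if n_spines < 0:
        raise ContractError("spine count must be >= 0")
    return n_spines / dendrite_length_um


def bin_vesicle_distances(distances_nm, bin_width_nm: float = 50.0,
                          max_nm: float = 500.0) -> np.ndarray:
    """Histogram vesicle distances from the synaptic cleft.

    Bins are half-open ``[0, w), [w, 2w), ...`` with the last bin closed
    at ``max_nm``; counts sum to the number of distances <= max_nm.
    """
    if bin_width_nm <= 0:
        raise ContractError("bin width must be positive")
    d = np.asarray(distances_nm, dtype=np.float64)
    if d.size and d.min() < 0:
        raise ContractError("distances must be >= 0")
    edges = np.arange(0.0, max_nm + bin_width_nm / 2, bin_width_nm)
    counts, _ = np.histogram(d, bins=edges)
    return counts
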
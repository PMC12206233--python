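"""ROI atlases: subnetwork membership tables for connectome construction.

The reference parcellation is a set of 300 spherical, non-overlapping ROIs,
of which four large-scale subnetworks are analysed: the somatomotor network
(SMN, 51 ROIs), the default mode network (DMN, 65), the frontoparietal
network (FPN, 36) and the attention network (ATN, 27); the remaining ROIs
carry no subnetwork label and enter only the whole-brain ("global") graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AtlasError

#: Subnetworks analysed at the single-network level, in reporting order.
SUBNETWORKS = ("SMN", "DMN", "FPN", "ATN")

#: Analysis levels: the whole-brain graph plus each subnetwork.
NETWORK_LEVELS = ("global",) + SUBNETWORKS

#: Reference subnetwork sizes for the 300-ROI parcellation.
REFERENCE_SIZES = {"SMN": 51, "DMN": 65, "FPN": 36, "ATN": 27}
REFERENCE_N_ROIS = 300

#: Label for ROIs outside every analysed subnetwork.
UNLABELLED = "none"


@dataclass(frozen=True)
class ROIAtlas:
    """Ordered ROI table binding row indices to subnetwork labels.

    Parameters
    ----------
    roi_ids : tuple of str
        Unique ROI identifiers, in matrix row order.
    networks : tuple of str
        One subnetwork label per ROI (``"none"`` for unlabelled ROIs).
        A single label per ROI makes subnetworks non-overlapping by
        construction; duplicate ROI ids are rejected.
    coordinates : ndarray of shape (n_rois, 3), optional
        MNI coordinates in mm. Purely descriptive.
    """

    roi_ids: tuple
    networks: tuple
    coordinates: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if len(self.roi_ids) != len(self.networks):
            raise AtlasError("roi_ids and networks must have equal length")
        if len(set(self.roi_ids)) != len(self.roi_ids):
            raise AtlasError("duplicate ROI ids in atlas")
        unknown = set(self.networks) - set(SUBNETWORKS) - {UNLABELLED}
        if unknown:
            raise AtlasError(f"unknown subnetwork labels: {sorted(unknown)}")
        if self.coordinates is not None and len(self.coordinates) != len(self.roi_ids):
            raise AtlasError("coordinate table length mismatch")

    @property
    def n_rois(self) -> int:
        return len(self.roi_ids)

    def members(self, network: str) -> np.ndarray:
        """Row indices of the ROIs belonging to ``network``.

        ``"global"`` returns every ROI. Unknown labels raise ``KeyError``.
        """
        if network == "global":
            return np.arange(self.n_rois)
        if network not in SUBNETWORKS:
            raise KeyError(f"unknown network label: {network!r}")
        labels = np.asarray(self.networks)
        return np.flatnonzero(labels == network)

    def network_size(self, network: str) -> int:
        return len(self.members(network))

    def to_frame(self) -> pd.DataFrame:
        coords = (
            self.coordinates
            if self.coordinates is not None
            else np.full((self.n_rois, 3), np.nan)
        )
        return pd.DataFrame(
            {
                "roi_id": list(self.roi_ids),
                "x": coords[:, 0],
                "y": coords[:, 1],
                "z": coords[:, 2],
                "network": list(self.networks),
            }
        )


def synthetic_atlas(sizes: dict | None = None, n_rois: int | None = None,
                    seed: int = 12345) -> ROIAtlas:
    """Synthetic stand-in for the 300-ROI reference parcellation.

    Produces an atlas with the reference subnetwork sizes (SMN 51, DMN 65,
    FPN 36, ATN 27 of 300 ROIs) by default; ``sizes``/``n_rois`` allow
    scaled-down variants for fast tests. Coordinates are arbitrary points in
    a brain-sized box and carry no anatomical meaning.
    """
    sizes = dict(REFERENCE_SIZES if sizes is None else sizes)
    n_rois = REFERENCE_N_ROIS if n_rois is None else n_rois
    n_labelled = sum(sizes.values())
    if n_labelled > n_rois:
        raise AtlasError("subnetwork sizes exceed total ROI count")
    labels = []
    for net, size in sizes.items():
        labels.extend([net] * size)
    labels.extend([UNLABELLED] * (n_rois - n_labelled))
    rng = np.random.default_rng(seed)
    coords = rng.uniform([-70, -105, -60], [70, 70, 80], size=(n_rois, 3))
    roi_ids = tuple(f"ROI{i + 1:03d}" for i in range(n_rois))
    return ROIAtlas(roi_ids=roi_ids, networks=tuple(labels),
                    coordinates=np.round(coords, 1))


def write_atlas(atlas: ROIAtlas, path) -> None:
    """Write the atlas as a tab-separated table (roi_id, x, y, z, network)."""
    atlas.to_frame().to_csv(path, sep="\t", index=False)


def read_atlas(path) -> ROIAtlas:
    """Read an atlas from a tab-separated table (roi_id, x, y, z, network)."""
    df = pd.read_csv(path, sep="\t", dtype={"roi_id": str})
    required = {"roi_id", "network"}
    if not required.issubset(df.columns):
        raise AtlasError(f"atlas table must contain columns {sorted(required)}")
    coords = None
    if {"x", "y", "z"}.issubset(df.columns):
        coords = df[["x", "y", "z"]].to_numpy(float)
    return ROIAtlas(
        roi_ids=tuple(df["roi_id"]),
        networks=tuple(df["network"]),
        coordinates=coords,
    )
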
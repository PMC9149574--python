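"""Map flattened feature importances back to atlas regions and export them.

Features are flattened ROI-major (all T time points of ROI 0, then ROI 1,
...), so feature f corresponds to (roi, t) = (f // T, f % T).  A region's
importance is the L1 mass of the skip weights over its time points — the
natural aggregate for a model whose feature-selection layer is theta.  The
bundled AAL-90 table carries region ids (1..90), names, abbreviations and
*approximate* MNI centroid coordinates (user-replaceable; only the node
export needs them).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import ExportError, InputError

__all__ = [
    "AtlasTable",
    "RegionRanking",
    "load_aal90",
    "feature_to_roi",
    "roi_importance",
    "selection_frequency",
    "top_regions",
    "export_node_file",
]


@dataclass
class AtlasTable:
    """Region lookup: ids contiguous 1..R, names, abbreviations, coordinates."""

    table: pd.DataFrame  # columns: id, name, abbreviation, x, y, z (xyz optional)

    def __post_init__(self) -> None:
        ids = self.table["id"].to_numpy()
        R = len(ids)
        if sorted(ids.tolist()) != list(range(1, R + 1)):
            raise InputError("atlas ids must be unique and contiguous 1..R")

    @property
    def R(self) -> int:
        return len(self.table)

    @property
    def has_coordinates(self) -> bool:
        return {"x", "y", "z"}.issubset(self.table.columns)

    def name_of(self, region_id: int) -> str:
        return str(self.table.set_index("id").loc[region_id, "name"])


def load_aal90() -> AtlasTable:
    """The bundled AAL 90-region table (approximate centroids)."""
    with resources.files("mmlassonet.data").joinpath("aal90.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return AtlasTable(table=df)


def feature_to_roi(feature_index: int, T: int, R: int) -> tuple[int, int]:
    """Invert ROI-major flattening: f = roi*T + t -> (roi, t), 0-based."""
    if not 0 <= feature_index < T * R:
        raise InputError(
            f"feature_index {feature_index} out of range for T={T}, R={R}"
        )
    return feature_index // T, feature_index % T


def roi_importance(theta: np.ndarray, T: int, R: int) -> np.ndarray:
    """Per-ROI importance: sum_t |theta[roi*T + t]|.  Conserves ||theta||_1."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != T * R:
        raise InputError(f"theta length {theta.shape[0]} != T*R = {T * R}")
    return np.abs(theta).reshape(R, T).sum(axis=1)


def selection_frequency(thetas: list[np.ndarray], T: int, R: int) -> np.ndarray:
    """Fraction of models in which each ROI has any active skip weight.

    An alternative importance rule to the L1 mass: aggregate over repeated
    fits (e.g. one theta per repeat) and rank regions by how consistently
    they are selected.
    """
    if not thetas:
        raise InputError("selection_frequency needs at least one theta vector")
    hits = np.zeros(R)
    for theta in thetas:
        theta = np.asarray(theta, dtype=float)
        if theta.shape[0] != T * R:
            raise InputError(f"theta length {theta.shape[0]} != T*R = {T * R}")
        hits += (np.abs(theta).reshape(R, T) > 0).any(axis=1)
    return hits / len(thetas)


@dataclass
class RegionRanking:
    """(region id, importance) sorted by non-increasing importance."""

    entries: list[tuple[int, float]]
    provenance: str = ""

    def region_ids(self) -> list[int]:
        return [rid for rid, _ in self.entries]

    def to_frame(self, atlas: AtlasTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame(self.entries, columns=["id", "importance"])
        if atlas is not None:
            df = df.merge(atlas.table[["id", "name", "abbreviation"]], on="id")
            df = df[["id", "name", "abbreviation", "importance"]]
        return df


def top_regions(
    scores: np.ndarray, atlas: AtlasTable | None = None, k: int = 15,
    provenance: str = "",
) -> RegionRanking:
    """Top-k regions by importance; ties broken toward the lower region id.

    ``scores`` is indexed by 0-based ROI; region ids in the ranking are
    1-based (atlas convention).
    """
    scores = np.asarray(scores, dtype=float)
    R = scores.shape[0]
    if atlas is not None and atlas.R != R:
        raise InputError(f"atlas has {atlas.R} regions but scores has {R}")
    if k > R:
        raise InputError(f"k={k} exceeds region count {R}")
    if (scores < 0).any():
        raise InputError("importance scores must be >= 0")
    # stable sort on -score keeps lower ids first among ties
    order = np.argsort(-scores, kind="stable")[:k]
    entries = [(int(i) + 1, float(scores[i])) for i in order]
    return RegionRanking(entries=entries, provenance=provenance)


def export_node_file(ranking: RegionRanking, atlas: AtlasTable, path) -> Path:
    """Write a whitespace-delimited .node text file for brain-network viewers.

    One line per ranked region: x y z color size label.  Size is the
    importance max-normalised to 1; color is the rank bucket (1 = top
    third, 2 = middle, 3 = bottom).
    """
    if not atlas.has_coordinates:
        raise ExportError("atlas table has no x/y/z coordinates; cannot export")
    path = Path(path)
    idx = atlas.table.set_index("id")
    max_imp = max((imp for _, imp in ranking.entries), default=0.0)
    if max_imp <= 0:
        max_imp = 1.0
    n = len(ranking.entries)
    lines = []
    for rank, (rid, imp) in enumerate(ranking.entries):
        row = idx.loc[rid]
        color = 1 + (3 * rank) // max(n, 1)
        size = imp / max_imp
        lines.append(
            f"{row['x']:g}\t{row['y']:g}\t{row['z']:g}\t{color}\t{size:.6f}\t{row['abbreviation']}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
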
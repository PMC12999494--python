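"""Imaging-mass-cytometry single-cell spatial stack.

From cell and nucleus segmentation masks: derive cytoplasm masks by set
subtraction, map subcellular compartments to their parent cell by centroid
containment, extract per-compartment marker intensities, gate markers into
positivity flags and lineages, classify tissue regions into marker-high/low,
and profile each cell's neighborhood (lineage composition within a radius of
1.5x the average cell diameter).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import regionprops

from .datatypes import LabelImage

logger = logging.getLogger("atf6scope.spatial")

DEFAULT_RADIUS_FACTOR = 1.5
COMPARTMENTS = ("cell", "nucleus", "cytoplasm")


def derive_cytoplasm(cells: LabelImage, nuclei: LabelImage) -> LabelImage:
    """Cytoplasm mask = cell pixels minus all nucleus pixels.

    Labels are inherited from the cell image; a cell fully covered by nuclei
    yields no cytoplasm object.
    """
    if cells.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: {cells.shape} vs {nuclei.shape}")
    cyto = np.where(nuclei.labels > 0, 0, cells.labels)
    return LabelImage(labels=cyto)


def _object_table(image: LabelImage) -> pd.DataFrame:
    """Per-object centroid (row, col), area and an anchor pixel.

    The anchor is the pixel-rounded centroid when that pixel belongs to the
    object, else the member pixel nearest the centroid (non-convex objects).
    """
    rows = []
    for prop in regionprops(image.labels):
        cr, cc = prop.centroid
        anchor = (int(round(cr)), int(round(cc)))
        coords = prop.coords
        member = (coords[:, 0] == anchor[0]) & (coords[:, 1] == anchor[1])
        if not member.any():
            d2 = (coords[:, 0] - cr) ** 2 + (coords[:, 1] - cc) ** 2
            anchor = tuple(coords[np.argmin(d2)])
        rows.append((prop.label, cr, cc, int(prop.area), anchor[0], anchor[1]))
    return pd.DataFrame(
        rows,
        columns=["label", "centroid_row", "centroid_col", "area", "anchor_row", "anchor_col"],
    ).set_index("label")


def _assign_by_centroid(
    parents: LabelImage, children: pd.DataFrame, child_image: LabelImage
) -> dict[int, int]:
    """Map parent cell label -> child label by centroid containment.

    If several child centroids land in one cell, the child with the largest
    pixel overlap with that cell wins; the rest stay unassigned.
    """
    candidates: dict[int, list[int]] = {}
    for child_label, row in children.iterrows():
        parent = int(parents.labels[int(row["anchor_row"]), int(row["anchor_col"])])
        if parent == 0:
            logger.debug("object %d centroid on background; unassigned", child_label)
            continue
        candidates.setdefault(parent, []).append(int(child_label))
    assignment: dict[int, int] = {}
    for parent, kids in candidates.items():
        if len(kids) == 1:
            assignment[parent] = kids[0]
            continue
        in_parent = parents.labels == parent
        overlaps = [(np.sum(in_parent & (child_image.labels == k)), k) for k in kids]
        overlaps.sort(reverse=True)
        assignment[parent] = overlaps[0][1]
        logger.debug(
            "cell %d had %d candidate objects; kept %d", parent, len(kids), assignment[parent]
        )
    return assignment


def map_compartments(
    cells: LabelImage, nuclei: LabelImage, cytoplasm: LabelImage | None = None
) -> pd.DataFrame:
    """Map nuclei (and cytoplasm) to parent cells by centroid containment.

    Every cell emits one record (indexed by cell id) with centroid, area and
    the assigned nucleus/cytoplasm ids and areas (NaN when unassigned). A
    nucleus whose centroid pixel lies on background remains unassigned.
    """
    if cells.shape != nuclei.shape:
        raise ValueError(f"shape mismatch: {cells.shape} vs {nuclei.shape}")
    if cytoplasm is None:
        cytoplasm = derive_cytoplasm(cells, nuclei)
    if cytoplasm.shape != cells.shape:
        raise ValueError("cytoplasm shape mismatch")

    cell_tab = _object_table(cells)
    nuc_tab = _object_table(nuclei)
    cyto_tab = _object_table(cytoplasm)
    nuc_of = _assign_by_centroid(cells, nuc_tab, nuclei)
    cyto_of = _assign_by_centroid(cells, cyto_tab, cytoplasm)

    records = pd.DataFrame(
        {
            "centroid_row": cell_tab["centroid_row"],
            "centroid_col": cell_tab["centroid_col"],
            "area_px": cell_tab["area"],
        },
        index=cell_tab.index,
    )
    records.index.name = "cell_id"
    records["nucleus_id"] = pd.Series(nuc_of).reindex(records.index)
    records["cytoplasm_id"] = pd.Series(cyto_of).reindex(records.index)
    records["nucleus_area_px"] = records["nucleus_id"].map(nuc_tab["area"])
    records["cytoplasm_area_px"] = records["cytoplasm_id"].map(cyto_tab["area"])
    n_unassigned = nuc_tab.index.difference(pd.Index(nuc_of.values())).size
    if n_unassigned:
        logger.info("%d nucleus object(s) left unassigned", n_unassigned)
    return records


def extract_intensities(
    planes: dict[str, np.ndarray],
    records: pd.DataFrame,
    compartment_images: dict[str, LabelImage],
) -> pd.DataFrame:
    """Mean marker intensity per compartment per cell.

    ``planes`` maps marker name -> 2-D intensity image; ``compartment_images``
    maps 'cell'/'nucleus'/'cytoplasm' -> label image. Adds columns
    ``{marker}_{compartment}`` to a copy of ``records``.
    """
    out = records.copy()
    id_col = {"cell": None, "nucleus": "nucleus_id", "cytoplasm": "cytoplasm_id"}
    for compartment, image in compartment_images.items():
        if compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {compartment!r}")
        labels = image.labels
        max_label = int(labels.max()) if labels.size else 0
        counts = np.bincount(labels.ravel(), minlength=max_label + 1)
        for marker, plane in planes.items():
            plane = np.asarray(plane, dtype=float)
            if plane.shape != labels.shape:
                raise ValueError(f"plane {marker!r} shape mismatch in {compartment}")
            sums = np.bincount(labels.ravel(), weights=plane.ravel(), minlength=max_label + 1)
            with np.errstate(invalid="ignore"):
                means = sums / counts
            col = id_col[compartment]
            ids = out.index.to_numpy() if col is None else out[col].to_numpy()
            vals = np.full(len(out), np.nan)
            ok = np.isfinite(ids.astype(float))
            idx = ids[ok].astype(int)
            vals[ok] = means[idx]
            out[f"{marker}_{compartment}"] = vals
    return out


def gate_markers(
    records: pd.DataFrame,
    gates: dict[tuple[str, str], float],
    lineage_rules: list[tuple[str, dict[str, bool]]] | None = None,
) -> pd.DataFrame:
    """Threshold marker intensities into positivity flags and lineages.

    ``gates`` maps (marker, compartment) -> threshold; a cell is positive when
    its mean intensity is >= the threshold (boundary inclusive). Lineages come
    from an ordered rule list [(lineage, {marker: wanted_flag})]; the first
    rule whose flags all match wins, else 'other'.
    """
    out = records.copy()
    for (marker, compartment), threshold in gates.items():
        col = f"{marker}_{compartment}"
        if col not in out.columns:
            raise ValueError(f"gate references unknown column {col!r}")
        if not np.isfinite(threshold):
            raise ValueError(f"non-finite gate for {col!r}")
        out[f"{marker}_pos"] = out[col] >= threshold
    if lineage_rules is not None:
        lineage = pd.Series("other", index=out.index, name="lineage")
        unmatched = pd.Series(True, index=out.index)
        for name, wanted in lineage_rules:
            mask = unmatched.copy()
            for marker, flag in wanted.items():
                col = f"{marker}_pos"
                if col not in out.columns:
                    raise ValueError(f"lineage rule {name!r} references ungated {marker!r}")
                mask &= out[col] == flag
            lineage[mask] = name
            unmatched &= ~mask
        out["lineage"] = lineage
    return out


def classify_tissue(
    records: pd.DataFrame,
    flag_col: str,
    region_col: str = "region",
    absolute_cutoff: float | None = None,
) -> pd.DataFrame:
    """Classify tissue regions into marker-high vs marker-low.

    Computes each region's fraction of flag-positive cells. By default a
    region is 'hi' when its fraction exceeds the across-region median
    (ties to 'low'); ``absolute_cutoff`` switches to a fixed fraction rule.
    """
    if region_col not in records.columns:
        raise ValueError(f"missing region column {region_col!r}")
    sizes = records.groupby(region_col).size()
    if (sizes == 0).any():
        raise ValueError("region with zero cells")
    frac = records.groupby(region_col)[flag_col].mean()
    if absolute_cutoff is not None:
        label = np.where(frac > absolute_cutoff, "hi", "low")
    else:
        if len(frac) < 2:
            raise ValueError("median rule needs at least 2 regions")
        label = np.where(frac > frac.median(), "hi", "low")
    return pd.DataFrame({"positive_fraction": frac, "class": label})


def neighborhood_profile(
    records: pd.DataFrame,
    radius_factor: float = DEFAULT_RADIUS_FACTOR,
    lineage_col: str = "lineage",
) -> tuple[pd.DataFrame, float]:
    """Lineage composition of each cell's neighborhood.

    The radius is ``radius_factor`` times the mean equivalent-circle diameter
    2*sqrt(area/pi) over cells in the image; neighbors are cells whose
    centroid lies within that radius (boundary inclusive), excluding the cell
    itself. Returns per-cell neighbor counts and lineage frequencies plus the
    radius used.
    """
    if lineage_col not in records.columns or records[lineage_col].isna().all():
        raise ValueError("no labelled cells")
    diam = 2.0 * np.sqrt(records["area_px"].to_numpy(dtype=float) / np.pi)
    radius = float(radius_factor * diam.mean())
    xy = records[["centroid_row", "centroid_col"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    neighbor_lists = tree.query_ball_point(xy, r=radius)

    lineages = sorted(records[lineage_col].dropna().unique())
    lin_arr = records[lineage_col].to_numpy()
    rows = []
    for i, nbrs in enumerate(neighbor_lists):
        nbrs = [j for j in nbrs if j != i]
        freqs = {f"freq_{lin}": 0.0 for lin in lineages}
        if nbrs:
            vals, counts = np.unique(lin_arr[nbrs], return_counts=True)
            for v, c in zip(vals, counts):
                freqs[f"freq_{v}"] = c / len(nbrs)
        rows.append({"n_neighbors": len(nbrs), **freqs})
    profile = pd.DataFrame(rows, index=records.index)
    profile["neighbor_ids"] = [
        [int(records.index[j]) for j in nbrs if j != i]
        for i, nbrs in enumerate(neighbor_lists)
    ]
    return profile, radius


def neighborhood_summary(
    records: pd.DataFrame, profile: pd.DataFrame, lineage_col: str = "lineage"
) -> pd.DataFrame:
    """Mean lineage frequency around each index lineage (per tissue class if present)."""
    freq_cols = [c for c in profile.columns if c.startswith("freq_")]
    merged = profile[freq_cols + ["n_neighbors"]].join(records[[lineage_col]])
    merged = merged[merged["n_neighbors"] > 0]
    return merged.groupby(lineage_col)[freq_cols].mean()
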